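"""Cross-dataset integration: spec, RAI, composite scores, TS, and the
noribo / ribo / trans catalog, with enrichment and group-comparison statistics.

For a lncRNA expressed in x of M selected datasets, spec = (M-x)/(M-1)
measures tissue specificity (0 ubiquitous, 1 specific).  RAI is the mean
association sign over the expressed datasets, in [-1, 1].  The composite
RAI*(1-spec) ranks broadly expressed lncRNAs by the consistency of their
ribosomal association; its 5th/95th percentiles delimit high-confidence
ribosome-free (noribo) and ribosome-associated (ribo) lncRNAs.  The
translation score TS sums per-dataset level weights (A0..A3 ->
-1, -0.5, 0.5, 1) over the datasets where the lncRNA is associated; the top
5% of TS within the ribo class are relabelled trans (putatively translated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .errors import DataError

LEVEL_WEIGHTS = (-1.0, -0.5, 0.5, 1.0)  # A0..A3
CATALOG_PERCENTILES = (5.0, 95.0)
TRANS_TOP_FRACTION = 0.05


@dataclass
class CatalogEntry:
    transcript_id: str
    biotype: str
    states: dict[str, str]  # dataset_id -> "N" | "F" | "A0".."A3"
    spec: float | None = None
    rai: float | None = None
    composite_ubiq: float | None = None  # RAI * (1 - spec)
    composite_spec: float | None = None  # RAI * spec
    ts: float | None = None
    cls: str = "other"  # noribo | ribo | trans | other


@dataclass(frozen=True)
class Contingency2x2:
    """(supported-in-class, unsupported-in-class, supported-elsewhere,
    unsupported-elsewhere)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("Contingency2x2: negative cell")
        if self.a + self.b + self.c + self.d < 1:
            raise DataError("Contingency2x2: empty table")


@dataclass
class EnrichmentResult:
    """One-sided Fisher test plus the enrichment ratio.

    ``ratio`` is the relative risk (a/(a+b)) / (c/(c+d)) — the per-class
    support rate over the support rate outside the class.  The
    conditional-MLE odds ratio of the noncentral hypergeometric model is
    available as :attr:`odds_ratio` (computed on demand).
    """

    table: Contingency2x2
    ratio: float
    p_value: float

    @cached_property
    def odds_ratio(self) -> float:
        t = self.table
        if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
            return float("nan")
        res = _odds_ratio(np.array([[t.a, t.b], [t.c, t.d]]), kind="conditional")
        return float(res.statistic)


def tissue_specificity(x: int, m: int) -> float:
    """(M - x) / (M - 1): 0 for ubiquitous, 1 for single-dataset expression."""
    if m < 2:
        raise DataError(f"tissue_specificity requires M >= 2 datasets, got M={m}")
    if not 1 <= x <= m:
        raise DataError(f"expressed-count x={x} outside [1, {m}]")
    return (m - x) / (m - 1)


def rai(x_flags: Sequence[int], y_flags: Sequence[int]) -> float:
    """Mean association sign over expressed datasets: sum x*y / sum x."""
    x = np.asarray(x_flags, dtype=float)
    y = np.asarray(y_flags, dtype=float)
    if x.shape != y.shape:
        raise DataError("rai: x and y must align")
    denom = x.sum()
    if denom < 1:
        raise DataError("rai undefined: transcript unexpressed in every dataset")
    return float((x * y).sum() / denom)


def composite_scores(rai_value: float, spec_value: float) -> tuple[float, float]:
    """(RAI * (1 - spec), RAI * spec)."""
    return rai_value * (1.0 - spec_value), rai_value * spec_value


def classify_catalog(
    scores: Sequence[float],
    percentiles: tuple[float, float] = CATALOG_PERCENTILES,
) -> list[str]:
    """noribo below the 5th percentile, ribo above the 95th, other between.

    Strict inequalities at both thresholds (ties fall to the middle class).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 20:
        raise DataError(f"classify_catalog: need >= 20 scored lncRNAs, got {arr.size}")
    low, high = np.percentile(arr, percentiles)
    return [
        "noribo" if s < low else ("ribo" if s > high else "other") for s in arr
    ]


def translation_score(
    levels: Sequence[int],
    weights: tuple[float, float, float, float] = LEVEL_WEIGHTS,
) -> float:
    """Sum of level weights over the associated datasets."""
    if len(levels) == 0:
        raise DataError("translation_score undefined: no associated dataset")
    if any(not 0 <= a <= 3 for a in levels):
        raise DataError(f"translation levels must be in 0..3, got {levels}")
    return float(sum(weights[a] for a in levels))


def select_trans(
    ts_values: Sequence[float],
    top_fraction: float = TRANS_TOP_FRACTION,
) -> list[bool]:
    """Flag ribo-class lncRNAs with TS strictly above the (1 - top_fraction)
    percentile of ribo-class TS values."""
    arr = np.asarray(ts_values, dtype=float)
    if arr.size == 0:
        return []
    threshold = np.percentile(arr, 100.0 * (1.0 - top_fraction))
    return [bool(v > threshold) for v in arr]


def enrichment_test(
    table: Contingency2x2 | tuple[int, int, int, int],
    alternative: str = "greater",
) -> EnrichmentResult:
    """One-sided Fisher's exact test plus the enrichment ratio for a 2x2 table."""
    if not isinstance(table, Contingency2x2):
        table = Contingency2x2(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        ratio = float("nan")
    else:
        in_rate = a / (a + b)
        out_rate = c / (c + d)
        ratio = float("inf") if out_rate == 0 and in_rate > 0 else (
            float("nan") if out_rate == 0 else in_rate / out_rate
        )
    if min(a + b, c + d, a + c, b + d) == 0:
        return EnrichmentResult(table=table, ratio=ratio, p_value=1.0)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(table=table, ratio=ratio, p_value=float(p))


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "welch",
) -> tuple[float, float, tuple[float, float]]:
    """Two-sided t comparison of two groups: Welch's or pooled two-sample t.

    Returns (statistic, p_value, (mean_a, mean_b)).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("compare_groups: each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise DataError("compare_groups: both groups are degenerate (zero variance)")
    if method not in ("welch", "pooled"):
        raise DataError(f"unknown method {method!r}")
    res = sps.ttest_ind(a, b, equal_var=(method == "pooled"))
    return float(res.statistic), float(res.pvalue), (float(a.mean()), float(b.mean()))


# ---------------------------------------------------------------------------
# Catalog driver


def build_catalog(
    lnc_info: Sequence[tuple[str, str]],  # (transcript_id, biotype)
    dataset_ids: Sequence[str],
    expressed: Mapping[str, Mapping[str, bool]],  # dataset -> tid -> expressed
    associated: Mapping[str, Mapping[str, bool]],  # dataset -> tid -> associated
    levels: Mapping[str, Mapping[str, int]],  # dataset -> tid -> A-level
    min_datasets: int = 1,
    percentiles: tuple[float, float] = CATALOG_PERCENTILES,
    trans_top_fraction: float = TRANS_TOP_FRACTION,
) -> list[CatalogEntry]:
    """Integrate per-dataset association and translation calls into the catalog."""
    m = len(dataset_ids)
    if m < 2:
        raise DataError(
            f"catalog integration needs >= 2 selected datasets (spec denominator M-1); got M={m}"
        )
    entries: list[CatalogEntry] = []
    for tid, biotype in lnc_info:
        states: dict[str, str] = {}
        x_flags: list[int] = []
        y_flags: list[int] = []
        assoc_levels: list[int] = []
        for ds in dataset_ids:
            is_expr = expressed[ds].get(tid, False)
            if not is_expr:
                states[ds] = "N"
                x_flags.append(0)
                y_flags.append(0)
                continue
            x_flags.append(1)
            if associated[ds].get(tid, False):
                level = levels[ds].get(tid, 0)
                states[ds] = f"A{level}"
                y_flags.append(1)
                assoc_levels.append(level)
            else:
                states[ds] = "F"
                y_flags.append(-1)
        entry = CatalogEntry(transcript_id=tid, biotype=biotype, states=states)
        x = sum(x_flags)
        if x >= 1:
            entry.spec = tissue_specificity(x, m)
            entry.rai = rai(x_flags, y_flags)
            entry.composite_ubiq, entry.composite_spec = composite_scores(
                entry.rai, entry.spec
            )
            if assoc_levels:
                entry.ts = translation_score(assoc_levels)
        entries.append(entry)

    scored = [
        e
        for e in entries
        if e.composite_ubiq is not None and sum(1 for s in e.states.values() if s != "N") >= min_datasets
    ]
    labels = classify_catalog([e.composite_ubiq for e in scored], percentiles)
    for e, label in zip(scored, labels):
        e.cls = label
    ribo = [e for e in scored if e.cls == "ribo" and e.ts is not None]
    for e, is_trans in zip(ribo, select_trans([e.ts for e in ribo], trans_top_fraction)):
        if is_trans:
            e.cls = "trans"
    return entries


def enrichment_by_class(
    entries: Sequence[CatalogEntry],
    supported_ids: set[str] | frozenset[str],
    classes: Sequence[str] = ("trans", "ribo", "noribo", "other"),
) -> dict[str, EnrichmentResult]:
    """Per-class enrichment of externally supported lncRNAs (one-vs-rest)."""
    results = {}
    for cls in classes:
        in_cls = [e.transcript_id in supported_ids for e in entries if e.cls == cls]
        out_cls = [e.transcript_id in supported_ids for e in entries if e.cls != cls]
        results[cls] = enrichment_test(
            Contingency2x2(
                a=sum(in_cls),
                b=len(in_cls) - sum(in_cls),
                c=sum(out_cls),
                d=len(out_cls) - sum(out_cls),
            )
        )
    return results


def write_catalog(
    entries: Sequence[CatalogEntry],
    dataset_ids: Sequence[str],
    path: str | Path,
) -> None:
    def fmt(v: float | None) -> str:
        return "" if v is None else f"{v:.6g}"

    with open(path, "w") as fh:
        cols = ["transcript_id", "biotype", *dataset_ids, "spec", "RAI",
                "RAI_x_1_minus_spec", "RAI_x_spec", "TS", "class"]
        fh.write("\t".join(cols) + "\n")
        for e in entries:
            row = [e.transcript_id, e.biotype]
            row.extend(e.states.get(ds, "N") for ds in dataset_ids)
            row.extend(
                [fmt(e.spec), fmt(e.rai), fmt(e.composite_ubiq), fmt(e.composite_spec),
                 fmt(e.ts), e.cls]
            )
            fh.write("\t".join(row) + "\n")
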