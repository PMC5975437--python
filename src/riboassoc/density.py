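"""Ribosome density and the empirical 3'UTR percentile cutoff.

ribosome_density = ribo_count / (RPKM * region_length): weighted footprint
count over a region, normalized by transcript expression and region length.
Because a terminating ribosome leaves the transcript at the stop codon,
3'UTRs of expressed mRNAs approximate the ribosome-free noise floor; the
90th percentile of their density distribution is the per-dataset cutoff.  A
transcript at or above the cutoff is ribosome-associated; mRNAs are judged
on their CDS density, lncRNAs on the whole transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignments import (
    ExpressionTable,
    FootprintAlignment,
    index_by_transcript,
    weighted_region_count,
)
from .errors import DataError
from .transcriptome import TranscriptModel

EXPRESSION_THRESHOLD = 1.0  # RPKM


@dataclass
class TranscriptDatasetStats:
    transcript_id: str
    dataset_id: str
    rpkm: float
    expressed: bool
    ribo_count: float
    density: float
    associated: bool | None = None  # defined only if expressed


def ribosome_density(ribo_count: float, rpkm: float, region_length: int) -> float:
    if region_length < 1:
        raise DataError(f"region length must be >= 1, got {region_length}")
    if rpkm <= 0:
        raise DataError("ribosome density undefined at zero RPKM; filter to expressed first")
    return ribo_count / (rpkm * region_length)


def expressed_mask(
    expression: ExpressionTable | Mapping[str, float],
    threshold: float = EXPRESSION_THRESHOLD,
) -> dict[str, bool]:
    """True iff RPKM >= threshold (inclusive)."""
    rpkm = expression.rpkm if isinstance(expression, ExpressionTable) else expression
    return {tid: value >= threshold for tid, value in rpkm.items()}


def utr3_density_cutoff(utr3_densities: Sequence[float], percentile: float = 90.0) -> float:
    """Linear-interpolation (type-7) percentile of the 3'UTR density sample."""
    if len(utr3_densities) == 0:
        raise DataError("utr3_density_cutoff: empty density vector")
    return float(np.percentile(np.asarray(utr3_densities, dtype=float), percentile))


def classify_association(density: float, cutoff: float) -> bool:
    """Ribosome-associated iff density >= cutoff (the cutoff itself included)."""
    return density >= cutoff


def dataset_density_stats(
    transcripts: Sequence[TranscriptModel],
    ribo_alignments: Iterable[FootprintAlignment],
    expression: ExpressionTable,
    dataset_id: str,
    lnc_ids: set[str] | frozenset[str],
    rpkm_min: float = EXPRESSION_THRESHOLD,
    utr3_percentile: float = 90.0,
    min_utr3_length: int = 30,
) -> tuple[dict[str, TranscriptDatasetStats], float]:
    """Per-dataset association calls for mRNAs (CDS density) and lncRNAs
    (whole-transcript density) against the 3'UTR-derived cutoff.

    Returns the per-transcript stats and the cutoff used.
    """
    by_tid = index_by_transcript(ribo_alignments)
    expressed = expressed_mask(expression, rpkm_min)

    utr3_densities = []
    for t in transcripts:
        if not t.is_coding or t.utr3_span is None:
            continue
        if not expressed.get(t.transcript_id, False):
            continue
        lo, hi = t.utr3_span
        if hi - lo < min_utr3_length:
            continue
        count = weighted_region_count(by_tid.get(t.transcript_id, ()), t.transcript_id, (lo, hi))
        utr3_densities.append(
            ribosome_density(count, expression.get(t.transcript_id), hi - lo)
        )
    if not utr3_densities:
        raise DataError(f"{dataset_id}: no expressed mRNA 3'UTRs to derive a cutoff from")
    cutoff = utr3_density_cutoff(utr3_densities, utr3_percentile)

    stats: dict[str, TranscriptDatasetStats] = {}
    for t in transcripts:
        tid = t.transcript_id
        if not (t.is_coding or tid in lnc_ids):
            continue
        rpkm = expression.get(tid)
        is_expr = expressed.get(tid, False)
        region = t.cds_span if t.is_coding else (0, t.length)
        count = weighted_region_count(by_tid.get(tid, ()), tid, region)
        if is_expr:
            dens = ribosome_density(count, rpkm, region[1] - region[0])
            assoc = classify_association(dens, cutoff)
        else:
            dens, assoc = 0.0, None
        stats[tid] = TranscriptDatasetStats(
            transcript_id=tid,
            dataset_id=dataset_id,
            rpkm=rpkm,
            expressed=is_expr,
            ribo_count=count,
            density=dens,
            associated=assoc,
        )
    return stats, cutoff


def write_density_stats(
    stats: Mapping[str, TranscriptDatasetStats],
    path: str | Path,
    cutoff: float | None = None,
) -> None:
    with open(path, "w") as fh:
        if cutoff is not None:
            fh.write(f"# utr3_density_cutoff={cutoff:.6g}\n")
        fh.write("transcript_id\trpkm\texpressed\tribo_count\tdensity\tassociated\n")
        for tid in sorted(stats):
            s = stats[tid]
            assoc = "" if s.associated is None else str(int(s.associated))
            fh.write(
                f"{tid}\t{s.rpkm:.6g}\t{int(s.expressed)}\t{s.ribo_count:.6g}\t"
                f"{s.density:.6g}\t{assoc}\n"
            )
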