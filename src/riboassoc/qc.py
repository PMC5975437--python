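"""Footprint length histograms, the dist metric, and dataset selection.

dist(P, Q) = 1/2 * sum_l |P(l) - Q(l)| compares the footprint length
distribution on CDSs (P) with that on lncRNAs (Q); it is half the L1
distance (total variation) and lies in [0, 1].  A usable dataset must have
RNA- and Ribo-seq mapping rates above ``rate_min`` and dist below
``dist_max``; within a tissue only the dataset with the smallest dist is
retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignments import FootprintAlignment
from .errors import DataError, NoFootprintsError

_NORM_TOL = 1e-6


@dataclass
class LengthHistogram:
    """Normalized footprint length -> frequency distribution."""

    freqs: dict[int, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.freqs.values()):
            raise DataError("LengthHistogram: negative frequency")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > _NORM_TOL:
            raise DataError(f"LengthHistogram: frequencies sum to {total}, not 1")

    @property
    def support(self) -> set[int]:
        return set(self.freqs)

    def __getitem__(self, length: int) -> float:
        return self.freqs.get(length, 0.0)

    def restricted(self, lo: int, hi: int) -> "LengthHistogram":
        """Restrict to lengths in [lo, hi] and renormalize."""
        kept = {l: f for l, f in self.freqs.items() if lo <= l <= hi}
        total = sum(kept.values())
        if total <= 0:
            raise NoFootprintsError(f"no footprints with length in [{lo}, {hi}]")
        return LengthHistogram({l: f / total for l, f in kept.items()})


@dataclass
class DatasetProfile:
    dataset_id: str
    tissue: str
    mapping_rate_rna: float
    mapping_rate_ribo: float
    dist_value: float
    selected: bool = False


def length_distribution(
    alignments: Iterable[FootprintAlignment],
    regions: Mapping[str, tuple[int, int]],
) -> LengthHistogram:
    """Weighted, normalized read-length histogram over alignments whose 5' end
    falls inside the per-transcript regions."""
    if not regions:
        raise DataError("length_distribution: empty region set")
    freqs: dict[int, float] = {}
    total = 0.0
    for a in alignments:
        region = regions.get(a.transcript_id)
        if region is None or not region[0] <= a.five_prime < region[1]:
            continue
        freqs[a.read_length] = freqs.get(a.read_length, 0.0) + a.weight
        total += a.weight
    if total <= 0:
        raise NoFootprintsError("no footprints in the requested regions")
    return LengthHistogram({l: f / total for l, f in freqs.items()})


def distribution_distance(p: LengthHistogram, q: LengthHistogram) -> float:
    """Half the L1 distance between two normalized length distributions."""
    support = p.support | q.support
    return 0.5 * sum(abs(p[l] - q[l]) for l in support)


def select_datasets(
    profiles: Sequence[DatasetProfile],
    rate_min: float = 0.30,
    dist_max: float = 0.15,
) -> list[DatasetProfile]:
    """Apply the three selection criteria; at most one dataset per tissue survives.

    A profile passes iff both mapping rates are strictly greater than
    ``rate_min`` and its dist value is strictly below ``dist_max``; among
    passing profiles of one tissue the smallest dist wins (ties broken by
    dataset_id).
    """
    passing: dict[str, DatasetProfile] = {}
    for prof in profiles:
        prof.selected = False
        ok = (
            prof.mapping_rate_rna > rate_min
            and prof.mapping_rate_ribo > rate_min
            and prof.dist_value < dist_max
        )
        if not ok:
            continue
        best = passing.get(prof.tissue)
        if best is None or (prof.dist_value, prof.dataset_id) < (best.dist_value, best.dataset_id):
            passing[prof.tissue] = prof
    for prof in passing.values():
        prof.selected = True
    return list(profiles)


def write_profiles(profiles: Sequence[DatasetProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("dataset_id\ttissue\tmapping_rate_rna\tmapping_rate_ribo\tdist\tselected\n")
        for p in profiles:
            fh.write(
                f"{p.dataset_id}\t{p.tissue}\t{p.mapping_rate_rna:.4f}\t"
                f"{p.mapping_rate_ribo:.4f}\t{p.dist_value:.4f}\t{int(p.selected)}\n"
            )
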