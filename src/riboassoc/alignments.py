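"""Transcriptome alignment ingestion, contaminant removal, multimap weighting, RPKM.

A multimapped read is never counted more than once: its unit of evidence is
split over its N placements with weights proportional to the expression
(RPKM) of the target transcripts, w(i) = RPKM(i) / sum_n RPKM(n).  When every
target has zero RPKM the weight is uniform 1/N.  Expression itself is
quantified by a simple weighted RPKM (uniform split of multimapped reads,
one pass); an optional second pass re-derives weights from the first-pass
RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .errors import DataError


@dataclass(slots=True)
class FootprintAlignment:
    """One read-to-transcript placement (sense strand)."""

    read_id: str
    transcript_id: str
    five_prime: int  # 0-based transcript position of the read's 5' end
    read_length: int
    n_hits: int = 1
    weight: float = 1.0


@dataclass
class ExpressionTable:
    """Per-transcript RPKM plus the weighted mapped-read total behind it."""

    rpkm: dict[str, float]
    total_mapped: float

    def get(self, transcript_id: str, default: float = 0.0) -> float:
        return self.rpkm.get(transcript_id, default)

    def write(self, path: str | Path, counts: Mapping[str, float] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(f"# total_mapped={self.total_mapped:.6g}\n")
            fh.write("transcript_id\tcount\trpkm\n")
            for tid in sorted(self.rpkm):
                c = counts.get(tid, float("nan")) if counts else float("nan")
                fh.write(f"{tid}\t{c:.6g}\t{self.rpkm[tid]:.6g}\n")

    @classmethod
    def read(cls, path: str | Path) -> "ExpressionTable":
        total = 0.0
        rpkm: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "total_mapped=" in line:
                        total = float(line.split("total_mapped=")[1])
                    continue
                if line.startswith("transcript_id"):
                    continue
                tid, _, value = line.rstrip("\n").split("\t")
                rpkm[tid] = float(value)
        return cls(rpkm=rpkm, total_mapped=total)


def load_alignments(
    source: str | Path | Iterable,
    transcript_lengths: Mapping[str, int],
    max_hits: int = 100,
) -> list[FootprintAlignment]:
    """Load sense-strand transcriptome alignments from SAM/BAM.

    Reads with more than ``max_hits`` distinct alignments (NH tag honored when
    present) are dropped entirely; antisense and unmapped records are skipped.
    A reference name absent from ``transcript_lengths`` is a hard error.
    """
    if isinstance(source, (str, Path)):
        mode = "rb" if str(source).endswith(".bam") else "r"
        handle = pysam.AlignmentFile(str(source), mode, check_sq=False)
        records: Iterable = handle
    else:
        handle = None
        records = source

    per_read: dict[str, list[FootprintAlignment]] = {}
    total_hits: dict[str, int] = {}
    for rec in records:
        if rec.is_unmapped:
            continue
        tid = rec.reference_name
        if tid not in transcript_lengths:
            raise DataError(f"alignment reference {tid!r} absent from the transcript table")
        nh = rec.get_tag("NH") if rec.has_tag("NH") else None
        name = rec.query_name
        total_hits[name] = max(total_hits.get(name, 0) + 1, nh or 0)
        if rec.is_reverse:
            continue  # strand-specific protocol: antisense placements excluded
        length = rec.query_length or rec.infer_query_length() or rec.reference_length
        aln = FootprintAlignment(
            read_id=name,
            transcript_id=tid,
            five_prime=rec.reference_start,
            read_length=int(length),
        )
        if not 0 <= aln.five_prime < transcript_lengths[tid]:
            raise DataError(f"read {name}: 5' end {aln.five_prime} outside {tid}")
        per_read.setdefault(name, []).append(aln)
    if handle is not None:
        handle.close()

    kept: list[FootprintAlignment] = []
    for name, alns in per_read.items():
        if total_hits[name] > max_hits:
            continue
        n = len(alns)
        for aln in alns:
            aln.n_hits = n
            aln.weight = 1.0 / n
        kept.extend(alns)
    return kept


def remove_contaminants(
    alignments: Sequence[FootprintAlignment],
    contaminant_ids: set[str] | frozenset[str],
) -> list[FootprintAlignment]:
    """Drop every read having at least one placement on a contaminant transcript."""
    if not contaminant_ids:
        return list(alignments)
    bad_reads = {a.read_id for a in alignments if a.transcript_id in contaminant_ids}
    out = [a for a in alignments if a.read_id not in bad_reads]
    for read_id, group in _group_by_read(out).items():
        n = len(group)
        for a in group:
            a.n_hits = n
    return out


def multimap_weights(hit_rpkms: Sequence[float]) -> np.ndarray:
    """Split one read over its N placements proportionally to target RPKM."""
    if len(hit_rpkms) == 0:
        raise DataError("multimap_weights: empty RPKM vector")
    arr = np.asarray(hit_rpkms, dtype=float)
    if np.any(arr < 0):
        raise DataError("multimap_weights: negative RPKM")
    total = arr.sum()
    if total == 0:
        return np.full(arr.shape, 1.0 / arr.size)
    return arr / total


def assign_weights(
    alignments: Sequence[FootprintAlignment],
    expression: ExpressionTable | Mapping[str, float],
) -> None:
    """Set expression-proportional weights on every multi-placement read, in place."""
    get = expression.get if isinstance(expression, ExpressionTable) else (
        lambda tid, default=0.0: expression.get(tid, default)
    )
    for group in _group_by_read(alignments).values():
        if len(group) == 1:
            group[0].weight = 1.0
            continue
        w = multimap_weights([get(a.transcript_id) for a in group])
        for a, wi in zip(group, w):
            a.weight = float(wi)


def weighted_counts(alignments: Iterable[FootprintAlignment]) -> dict[str, float]:
    counts: dict[str, float] = {}
    for a in alignments:
        counts[a.transcript_id] = counts.get(a.transcript_id, 0.0) + a.weight
    return counts


def compute_rpkm(
    weighted: Mapping[str, float],
    lengths: Mapping[str, int],
    total_mapped: float,
) -> ExpressionTable:
    """RPKM = count / (length/1e3 * total/1e6).  Transcripts absent from
    ``weighted`` get RPKM 0."""
    if total_mapped <= 0:
        raise DataError(f"compute_rpkm: total_mapped must be positive, got {total_mapped}")
    rpkm = {
        tid: weighted.get(tid, 0.0) / ((length / 1e3) * (total_mapped / 1e6))
        for tid, length in lengths.items()
    }
    return ExpressionTable(rpkm=rpkm, total_mapped=total_mapped)


def quantify(
    alignments: Sequence[FootprintAlignment],
    lengths: Mapping[str, int],
    iterate: bool = False,
) -> ExpressionTable:
    """Simple weighted RPKM from alignments.

    One pass: multimapped reads are split uniformly, counts summed, RPKM
    computed.  With ``iterate=True`` a second pass re-derives the multimap
    weights from the first-pass RPKM before the final count (off by default).
    """
    if not alignments:
        raise DataError("quantify: no alignments")
    for group in _group_by_read(alignments).values():
        for a in group:
            a.weight = 1.0 / len(group)
    total = float(len(_group_by_read(alignments)))
    table = compute_rpkm(weighted_counts(alignments), lengths, total)
    if iterate:
        assign_weights(alignments, table)
        table = compute_rpkm(weighted_counts(alignments), lengths, total)
    return table


def weighted_region_count(
    alignments: Iterable[FootprintAlignment],
    transcript_id: str,
    region: tuple[int, int],
) -> float:
    """Sum of weights of alignments whose 5' end lies in ``region`` (half-open)."""
    lo, hi = region
    if lo > hi:
        raise DataError(f"inverted region {region}")
    return sum(
        a.weight
        for a in alignments
        if a.transcript_id == transcript_id and lo <= a.five_prime < hi
    )


def index_by_transcript(
    alignments: Iterable[FootprintAlignment],
) -> dict[str, list[FootprintAlignment]]:
    index: dict[str, list[FootprintAlignment]] = {}
    for a in alignments:
        index.setdefault(a.transcript_id, []).append(a)
    return index


def _group_by_read(
    alignments: Iterable[FootprintAlignment],
) -> dict[str, list[FootprintAlignment]]:
    groups: dict[str, list[FootprintAlignment]] = {}
    for a in alignments:
        groups.setdefault(a.read_id, []).append(a)
    return groups
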