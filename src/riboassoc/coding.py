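"""Coding-potential metrics for putative ORFs: FLOSS, RRS, Framescore.

Three orthogonal signatures of a translating ORF:

* FLOSS — the footprint length histogram of the transcript matches the CDS
  reference; reported here as 1 - total variation, so 1 is CDS-like.
* RRS — ribosome occupancy drops sharply after the stop codon; the
  ORF/downstream Ribo-seq density ratio, normalized by the same RNA-seq
  ratio, is mapped to [0, 1] by x/(1+x).
* Framescore — the 5' ends of footprints in a translated ORF are 3-periodic;
  KL divergence between the ORF frame distribution and the pooled CDS
  reference, oriented as frame_sim = exp(-KL) so higher is more coding-like.

Each metric is calibrated on translating CDSs: the cutoff is the 10th
percentile of the CDS score distribution, so ~90% of mRNAs pass each filter,
and a lncRNA ORF passes iff its score >= cutoff (inclusive).  The number of
filters passed (maximized over a transcript's ORFs) is the translation
level A0-A3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignments import FootprintAlignment
from .errors import DataError, NoFootprintsError
from .qc import LengthHistogram, distribution_distance
from .transcriptome import PutativeORF, TranscriptModel, find_putative_orfs

DEFAULT_LENGTH_WINDOW = (25, 35)  # nt, ribosome-footprint-sized
CODING_PERCENTILE = 10.0

_NORM_TOL = 1e-6


@dataclass
class FrameDistribution:
    """Proportion of footprint 5' ends in each of the three codon frames."""

    p: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.p):
            raise DataError("FrameDistribution: negative entry")
        if abs(sum(self.p) - 1.0) > _NORM_TOL:
            raise DataError(f"FrameDistribution: entries sum to {sum(self.p)}, not 1")


@dataclass
class CodingAssessment:
    transcript_id: str
    dataset_id: str
    best_orf: PutativeORF | None
    floss_score: float
    rrs_scaled: float
    frame_kl: float
    frame_sim: float
    passes: tuple[bool, bool, bool]  # (FLOSS, RRS, Frame)
    level: int  # 0..3


def floss(transcript_hist: LengthHistogram, cds_reference_hist: LengthHistogram) -> float:
    """1 - total variation between transcript and CDS length histograms.

    Both histograms must already be restricted to the footprint length window
    and renormalized (see :meth:`LengthHistogram.restricted`).
    """
    return 1.0 - distribution_distance(transcript_hist, cds_reference_hist)


def rrs(
    ribo_orf: float,
    ribo_down: float,
    rna_orf: float,
    rna_down: float,
    lengths: tuple[int, int, int, int],
) -> float:
    """Scaled ribosome release score.

    ``lengths`` are (ribo ORF, ribo downstream, RNA ORF, RNA downstream)
    region lengths in nt.  A +1-read pseudocount is applied to each count;
    raw = (ribo ORF density / ribo downstream density) /
          (RNA ORF density / RNA downstream density), scaled to raw/(1+raw).
    """
    if any(l < 1 for l in lengths):
        raise DataError(f"rrs: zero-length region in {lengths}")
    lro, lrd, lno, lnd = lengths
    ribo_ratio = ((ribo_orf + 1) / lro) / ((ribo_down + 1) / lrd)
    rna_ratio = ((rna_orf + 1) / lno) / ((rna_down + 1) / lnd)
    raw = ribo_ratio / rna_ratio
    return raw / (1.0 + raw)


def frame_distribution(
    alignments: Iterable[FootprintAlignment],
    orf: PutativeORF,
) -> FrameDistribution:
    """Add-one-smoothed frame distribution of weighted 5' ends inside the ORF."""
    counts = [1.0, 1.0, 1.0]  # one pseudo-read per frame
    for a in alignments:
        if orf.start <= a.five_prime < orf.end:
            counts[(a.five_prime - orf.start) % 3] += a.weight
    total = sum(counts)
    return FrameDistribution(tuple(c / total for c in counts))


def framescore(p: FrameDistribution, q: FrameDistribution) -> float:
    """Kullback-Leibler divergence sum_i P(i) ln(P(i)/Q(i)), natural log."""
    if any(qi <= 0 for qi in q.p):
        raise DataError("framescore: reference frame distribution must be strictly positive")
    return float(
        sum(pi * math.log(pi / qi) for pi, qi in zip(p.p, q.p) if pi > 0)
    )


def frame_similarity(kl: float) -> float:
    """exp(-KL): strictly decreasing bijection of the Framescore onto (0, 1]."""
    return math.exp(-kl)


def coding_cutoffs(
    cds_scores: Mapping[str, Sequence[float]] | tuple[Sequence[float], ...],
    percentile: float = CODING_PERCENTILE,
) -> tuple[float, float, float]:
    """Per-metric cutoffs: the 10th percentile (type-7) of translating-CDS scores.

    Scores must be oriented so that higher means more coding-like (FLOSS as
    1-TV, RRS scaled, Framescore as frame_sim).  A lncRNA ORF passes a
    filter iff its score >= cutoff.
    """
    if isinstance(cds_scores, Mapping):
        vectors = (cds_scores["floss"], cds_scores["rrs"], cds_scores["frame"])
    else:
        vectors = tuple(cds_scores)
    if len(vectors) != 3:
        raise DataError("coding_cutoffs: expected three score vectors")
    cutoffs = []
    for vec in vectors:
        arr = np.asarray(vec, dtype=float)
        if arr.size < 10:
            raise DataError(f"coding_cutoffs: need >= 10 CDS scores, got {arr.size}")
        cutoffs.append(float(np.percentile(arr, percentile)))
    return tuple(cutoffs)


def translation_level(pass_triples: Sequence[tuple[bool, bool, bool]]) -> int:
    """Maximum number of coding filters passed over a transcript's ORFs (0 if none)."""
    if not pass_triples:
        return 0
    return max(sum(triple) for triple in pass_triples)


# ---------------------------------------------------------------------------
# Per-dataset driver


def cds_reference_length_hist(
    transcripts: Sequence[TranscriptModel],
    ribo_by_tid: Mapping[str, list[FootprintAlignment]],
    mrna_ids: Iterable[str],
    window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
) -> LengthHistogram:
    """Footprint length histogram pooled over the CDSs of the given mRNAs."""
    spans = {t.transcript_id: t.cds_span for t in transcripts}
    freqs: dict[int, float] = {}
    total = 0.0
    for tid in mrna_ids:
        span = spans.get(tid)
        if span is None:
            continue
        for a in ribo_by_tid.get(tid, ()):
            if span[0] <= a.five_prime < span[1]:
                freqs[a.read_length] = freqs.get(a.read_length, 0.0) + a.weight
                total += a.weight
    if total <= 0:
        raise NoFootprintsError("no CDS footprints to build the reference length histogram")
    return LengthHistogram({l: f / total for l, f in freqs.items()}).restricted(*window)


def cds_reference_frame_dist(
    transcripts: Sequence[TranscriptModel],
    ribo_by_tid: Mapping[str, list[FootprintAlignment]],
    mrna_ids: Iterable[str],
) -> FrameDistribution:
    """Pooled, add-one-smoothed frame distribution over the CDSs of the given mRNAs."""
    spans = {t.transcript_id: t.cds_span for t in transcripts}
    counts = [1.0, 1.0, 1.0]
    for tid in mrna_ids:
        span = spans.get(tid)
        if span is None:
            continue
        for a in ribo_by_tid.get(tid, ()):
            if span[0] <= a.five_prime < span[1]:
                counts[(a.five_prime - span[0]) % 3] += a.weight
    total = sum(counts)
    return FrameDistribution(tuple(c / total for c in counts))


def _transcript_length_hist(
    alns: Sequence[FootprintAlignment], window: tuple[int, int]
) -> LengthHistogram:
    freqs: dict[int, float] = {}
    total = 0.0
    for a in alns:
        freqs[a.read_length] = freqs.get(a.read_length, 0.0) + a.weight
        total += a.weight
    if total <= 0:
        raise NoFootprintsError("transcript has no footprints")
    return LengthHistogram({l: f / total for l, f in freqs.items()}).restricted(*window)


def _region_count(alns: Iterable[FootprintAlignment], lo: int, hi: int) -> float:
    return sum(a.weight for a in alns if lo <= a.five_prime < hi)


def calibration_scores(
    transcripts: Sequence[TranscriptModel],
    ribo_by_tid: Mapping[str, list[FootprintAlignment]],
    rna_by_tid: Mapping[str, list[FootprintAlignment]],
    mrna_ids: Iterable[str],
    reference_hist: LengthHistogram,
    reference_frames: FrameDistribution,
    window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
) -> dict[str, list[float]]:
    """FLOSS / RRS / frame_sim score vectors over translating CDSs.

    The CDS plays the role of the ORF; the annotated 3'UTR is the RRS
    downstream region (mRNAs without a 3'UTR contribute no RRS score).
    """
    by_id = {t.transcript_id: t for t in transcripts}
    scores: dict[str, list[float]] = {"floss": [], "rrs": [], "frame": []}
    for tid in mrna_ids:
        t = by_id.get(tid)
        if t is None or t.cds_span is None:
            continue
        ribo = ribo_by_tid.get(tid, [])
        try:
            hist = _transcript_length_hist(ribo, window)
        except NoFootprintsError:
            continue
        scores["floss"].append(floss(hist, reference_hist))
        cds_orf = PutativeORF(tid, t.cds_span[0], t.cds_span[1])
        kl = framescore(frame_distribution(ribo, cds_orf), reference_frames)
        scores["frame"].append(frame_similarity(kl))
        if t.utr3_span is not None and t.utr3_span[1] > t.utr3_span[0]:
            rna = rna_by_tid.get(tid, [])
            (c0, c1), (u0, u1) = t.cds_span, t.utr3_span
            scores["rrs"].append(
                rrs(
                    _region_count(ribo, c0, c1),
                    _region_count(ribo, u0, u1),
                    _region_count(rna, c0, c1),
                    _region_count(rna, u0, u1),
                    (c1 - c0, u1 - u0, c1 - c0, u1 - u0),
                )
            )
    return scores


def assess_lncrna(
    transcript: TranscriptModel,
    ribo_alns: Sequence[FootprintAlignment],
    rna_alns: Sequence[FootprintAlignment],
    reference_hist: LengthHistogram,
    reference_frames: FrameDistribution,
    cutoffs: tuple[float, float, float],
    dataset_id: str,
    window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
    orfs: Sequence[PutativeORF] | None = None,
) -> CodingAssessment:
    """Score every putative ORF of a ribosome-associated lncRNA and keep the
    one passing the most filters."""
    tid = transcript.transcript_id
    if orfs is None:
        orfs = find_putative_orfs(transcript.sequence, tid)
    empty = CodingAssessment(
        transcript_id=tid,
        dataset_id=dataset_id,
        best_orf=None,
        floss_score=float("nan"),
        rrs_scaled=float("nan"),
        frame_kl=float("nan"),
        frame_sim=float("nan"),
        passes=(False, False, False),
        level=0,
    )
    if not orfs:
        return empty
    try:
        hist = _transcript_length_hist(ribo_alns, window)
    except NoFootprintsError:
        return empty
    floss_score = floss(hist, reference_hist)
    c_floss, c_rrs, c_frame = cutoffs

    best: CodingAssessment | None = None
    for orf in orfs:
        down_len = transcript.length - orf.end
        if down_len < 1:
            continue  # downstream region undefined for this ORF
        score_rrs = rrs(
            _region_count(ribo_alns, orf.start, orf.end),
            _region_count(ribo_alns, orf.end, transcript.length),
            _region_count(rna_alns, orf.start, orf.end),
            _region_count(rna_alns, orf.end, transcript.length),
            (orf.length, down_len, orf.length, down_len),
        )
        kl = framescore(frame_distribution(ribo_alns, orf), reference_frames)
        sim = frame_similarity(kl)
        passes = (floss_score >= c_floss, score_rrs >= c_rrs, sim >= c_frame)
        cand = CodingAssessment(
            transcript_id=tid,
            dataset_id=dataset_id,
            best_orf=orf,
            floss_score=floss_score,
            rrs_scaled=score_rrs,
            frame_kl=kl,
            frame_sim=sim,
            passes=passes,
            level=sum(passes),
        )
        if best is None or cand.level > best.level:
            best = cand
    return best if best is not None else empty


def write_assessments(
    assessments: Mapping[str, CodingAssessment],
    path: str | Path,
    cutoffs: tuple[float, float, float] | None = None,
) -> None:
    with open(path, "w") as fh:
        if cutoffs is not None:
            fh.write(
                f"# cutoffs floss={cutoffs[0]:.6g} rrs={cutoffs[1]:.6g} "
                f"frame_sim={cutoffs[2]:.6g}\n"
            )
        fh.write(
            "transcript_id\torf_start\torf_end\tfloss_score\trrs_scaled\t"
            "frame_kl\tframe_sim\tpass_floss\tpass_rrs\tpass_frame\tlevel\n"
        )
        for tid in sorted(assessments):
            a = assessments[tid]
            orf = a.best_orf
            fh.write(
                "\t".join(
                    [
                        tid,
                        "" if orf is None else str(orf.start),
                        "" if orf is None else str(orf.end),
                        f"{a.floss_score:.6g}",
                        f"{a.rrs_scaled:.6g}",
                        f"{a.frame_kl:.6g}",
                        f"{a.frame_sim:.6g}",
                        str(int(a.passes[0])),
                        str(int(a.passes[1])),
                        str(int(a.passes[2])),
                        str(a.level),
                    ]
                )
                + "\n"
            )
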