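"""Synthetic transcriptomes and Ribo-seq / RNA-seq alignments with ground truth.

The generator emulates the statistical structure the classification method
assumes:

* mRNAs with 5'UTR / CDS / 3'UTR architecture; CDS footprints are
  3-periodic, footprint-length distributed, and drop off sharply after the
  stop codon (3'UTR coverage = ``stop_dropoff`` of CDS coverage).
* translated lncRNAs carry one active ORF with the same translating
  signature; associated-untranslated lncRNAs carry uniform, aperiodic
  ribosome-protected coverage; free lncRNAs carry only background drawn
  from the same rate law as mRNA 3'UTRs, so the 90th-percentile cutoff has
  its intended operating point.
* contaminant (rRNA-like) transcripts soak up a fraction of footprints and
  cross-map onto lncRNAs; a fraction of all reads multimaps onto a second
  transcript; a small fraction of records is antisense noise.

A "study" is one transcriptome observed in several datasets (tissues) that
differ in sequencing depth, periodicity, and which transcripts are expressed
at what level — the between-dataset heterogeneity the cross-dataset
integration (spec, RAI, TS) exists to resolve.  Reads are emitted as
already-aligned SAM; there is no sequencing-error model, since the method's
scope starts at alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .transcriptome import STOP_CODONS, TranscriptModel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]
_STOPS = sorted(STOP_CODONS)

RNA_READ_LENGTH = 36
CONTAMINANT_RPKM = 300.0
CONTAMINANT_LENGTH = 120
CONTAMINANT_CROSSMAP = 0.3


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic-data generator."""

    n_mrna: int = 150
    n_lnc_associated_translated: int = 100
    n_lnc_associated_untranslated: int = 100
    n_lnc_free: int = 100
    n_datasets: int = 8
    # footprint length law (nt), clipped to the window
    footprint_mean: float = 29.0
    footprint_sd: float = 1.5
    footprint_min: int = 25
    footprint_max: int = 35
    periodicity_strength: float = 0.90  # fraction of in-ORF 5' ends forced to frame 0
    stop_dropoff: float = 0.10  # downstream-to-ORF coverage ratio; also background rate
    untranslated_coverage: float = 0.5  # coverage of associated-untranslated lncRNAs
    rna_depth: float = 5.0  # expected RNA-seq reads per transcript per RPKM per kb
    ribo_depth: float = 10.0  # expected Ribo-seq reads per RPKM per kb of covered region
    rpkm_low: float = 8.0  # base expression drawn log-uniform in [low, high]
    rpkm_high: float = 150.0
    contaminant_fraction: float = 0.05  # target fraction of Ribo-seq reads from contaminants
    n_contaminants: int = 2
    multimap_rate: float = 0.05
    antisense_rate: float = 0.02
    mrna_expressed_prob: float = 0.95  # per-dataset expression probability for mRNAs
    # lncRNA per-dataset expression probability ~ Beta(alpha, beta); mean 1/3
    # mirrors the tissue-specific expression of real lncRNAs
    lnc_breadth_alpha: float = 1.0
    lnc_breadth_beta: float = 2.0
    expression_sd: float = 0.4  # lognormal sd of per-dataset expression variation
    dataset_depth_low: float = 0.5  # per-dataset depth multiplier ~ log-uniform
    dataset_depth_high: float = 2.0
    dataset_periodicity_low: float = 0.80
    dataset_periodicity_high: float = 0.95
    seed: int = 0


@dataclass
class TranscriptTruth:
    is_mrna: bool
    is_associated: bool
    is_translated: bool
    active_orf: tuple[int, int] | None
    base_rpkm: float
    breadth: float = 1.0  # per-dataset expression probability
    is_contaminant: bool = False


@dataclass(slots=True)
class SamRead:
    """One emitted alignment record (may share its qname with a multimap twin)."""

    qname: str
    flag: int
    transcript_id: str
    pos: int  # 0-based
    length: int
    n_hits: int = 1


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, n)]).decode()


def _random_orf_seq(rng: np.random.Generator, length: int) -> str:
    """ATG + non-stop/non-ATG codons + stop; ``length`` a multiple of 3 >= 9."""
    n_mid = length // 3 - 2
    mid = "".join(rng.choice(_NONSTOP_CODONS, n_mid)) if n_mid > 0 else ""
    return "ATG" + mid + str(rng.choice(_STOPS))


def _embed_orf(rng: np.random.Generator, length: int, orf_len: int) -> tuple[str, int, int]:
    """Random sequence of ``length`` with one guaranteed putative ORF.

    The three bases upstream of the ORF are forced to TAA so that ORF
    enumeration anchors the ORF exactly at the embedded ATG.
    """
    start = int(rng.integers(20, length - orf_len - 30))
    seq = _random_seq(rng, length)
    orf = _random_orf_seq(rng, orf_len)
    seq = seq[: start - 3] + "TAA" + orf + seq[start + orf_len :]
    return seq, start, start + orf_len


def simulate_transcriptome(
    config: SimulationConfig,
    seed=None,
) -> tuple[list[TranscriptModel], dict[str, TranscriptTruth]]:
    """Generate mRNAs, three lncRNA classes, and contaminant transcripts."""
    rng = _rng(config.seed if seed is None else seed)
    transcripts: list[TranscriptModel] = []
    truth: dict[str, TranscriptTruth] = {}

    def base_rpkm() -> float:
        return float(np.exp(rng.uniform(np.log(config.rpkm_low), np.log(config.rpkm_high))))

    for i in range(config.n_mrna):
        utr5 = int(rng.integers(60, 151))
        cds = 3 * int(rng.integers(100, 301))
        utr3 = int(rng.integers(120, 401))
        seq = _random_seq(rng, utr5) + _random_orf_seq(rng, cds) + _random_seq(rng, utr3)
        tid = f"MRNA{i:04d}"
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=f"GENE_M{i:04d}",
                biotype="protein_coding",
                sequence=seq,
                utr5_span=(0, utr5),
                cds_span=(utr5, utr5 + cds),
                utr3_span=(utr5 + cds, utr5 + cds + utr3),
            )
        )
        truth[tid] = TranscriptTruth(
            is_mrna=True,
            is_associated=True,
            is_translated=True,
            active_orf=(utr5, utr5 + cds),
            base_rpkm=base_rpkm(),
            breadth=config.mrna_expressed_prob,
        )

    lnc_classes = (
        ("LNCT", config.n_lnc_associated_translated, True, True),
        ("LNCU", config.n_lnc_associated_untranslated, True, False),
        ("LNCF", config.n_lnc_free, False, False),
    )
    for prefix, count, assoc, translated in lnc_classes:
        for i in range(count):
            if translated:
                # mRNA-like architecture: known translated lncRNAs carry a
                # substantial ORF with a 5' leader and a 3' trailer
                leader = int(rng.integers(30, 151))
                orf_len = 3 * int(rng.integers(84, 268))
                trailer = int(rng.integers(120, 401))
                seq = (
                    _random_seq(rng, leader - 3)
                    + "TAA"
                    + _random_orf_seq(rng, orf_len)
                    + _random_seq(rng, trailer)
                )
                start, end = leader, leader + orf_len
            else:
                length = int(rng.integers(300, 701))
                orf_len = 3 * int(rng.integers(10, 31))
                seq, start, end = _embed_orf(rng, length, orf_len)
            tid = f"{prefix}{i:04d}"
            biotype = str(rng.choice(["lincRNA", "antisense", "processed_transcript"]))
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=f"GENE_{tid}",
                    biotype=biotype,
                    sequence=seq,
                )
            )
            truth[tid] = TranscriptTruth(
                is_mrna=False,
                is_associated=assoc,
                is_translated=translated,
                active_orf=(start, end) if translated else None,
                base_rpkm=base_rpkm(),
                breadth=float(rng.beta(config.lnc_breadth_alpha, config.lnc_breadth_beta)),
            )

    for i in range(config.n_contaminants):
        tid = f"CONTAM{i:02d}"
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=f"GENE_{tid}",
                biotype="rRNA",
                sequence=_random_seq(rng, CONTAMINANT_LENGTH),
            )
        )
        truth[tid] = TranscriptTruth(
            is_mrna=False,
            is_associated=False,
            is_translated=False,
            active_orf=None,
            base_rpkm=CONTAMINANT_RPKM,
            breadth=1.0,
            is_contaminant=True,
        )
    return transcripts, truth


# ---------------------------------------------------------------------------
# Read generation


class _ReadFactory:
    def __init__(
        self,
        rng: np.random.Generator,
        config: SimulationConfig,
        lengths_by_tid: Mapping[str, int],
        multimap_pool: Sequence[str],
        prefix: str,
    ):
        self.rng = rng
        self.cfg = config
        self.lengths = lengths_by_tid
        self.pool = list(multimap_pool)
        self.prefix = prefix
        self.counter = 0
        self.reads: list[SamRead] = []

    def emit(self, tid: str, pos: int, length: int) -> None:
        rng, cfg = self.rng, self.cfg
        qname = f"{self.prefix}{self.counter:08d}"
        self.counter += 1
        flag = 16 if rng.random() < cfg.antisense_rate else 0
        placements = [(tid, pos)]
        if self.pool and rng.random() < cfg.multimap_rate:
            other = self.pool[int(rng.integers(0, len(self.pool)))]
            if other != tid:
                hi = max(1, self.lengths[other] - length)
                placements.append((other, int(rng.integers(0, hi))))
        for t, p in placements:
            self.reads.append(
                SamRead(qname=qname, flag=flag, transcript_id=t, pos=p,
                        length=length, n_hits=len(placements))
            )

    def crossmap(self, tid: str, pos: int, length: int, second_tid: str) -> None:
        """Emit a contaminant read that also maps onto ``second_tid``."""
        qname = f"{self.prefix}{self.counter:08d}"
        self.counter += 1
        hi = max(1, self.lengths[second_tid] - length)
        second_pos = int(self.rng.integers(0, hi))
        for t, p in ((tid, pos), (second_tid, second_pos)):
            self.reads.append(
                SamRead(qname=qname, flag=0, transcript_id=t, pos=p,
                        length=length, n_hits=2)
            )


def _footprint_lengths(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    raw = np.rint(rng.normal(cfg.footprint_mean, cfg.footprint_sd, n))
    return np.clip(raw, cfg.footprint_min, cfg.footprint_max).astype(int)


def _uniform_region(
    factory: _ReadFactory, tid: str, tx_len: int, lo: int, hi: int, lam: float
) -> None:
    rng, cfg = factory.rng, factory.cfg
    if hi - lo < 3 or lam <= 0:
        return
    n = int(rng.poisson(lam))
    if n == 0:
        return
    lengths = _footprint_lengths(rng, cfg, n)
    positions = rng.integers(lo, hi, n)
    positions = np.minimum(positions, np.maximum(tx_len - lengths, 0))
    for p, l in zip(positions, lengths):
        factory.emit(tid, int(p), int(l))


def _periodic_orf(
    factory: _ReadFactory,
    tid: str,
    tx_len: int,
    orf: tuple[int, int],
    lam: float,
    periodicity: float,
) -> None:
    rng, cfg = factory.rng, factory.cfg
    start, end = orf
    n_codons = (end - start) // 3 - 1  # exclude the stop codon
    if n_codons < 1 or lam <= 0:
        return
    n = int(rng.poisson(lam))
    if n == 0:
        return
    codons = rng.integers(0, n_codons, n)
    in_frame = rng.random(n) < periodicity + (1 - periodicity) / 3
    frames = np.where(in_frame, 0, rng.integers(1, 3, n))
    lengths = _footprint_lengths(rng, cfg, n)
    positions = start + 3 * codons + frames
    positions = np.minimum(positions, np.maximum(tx_len - lengths, 0))
    for p, l in zip(positions, lengths):
        factory.emit(tid, int(p), int(l))


def simulate_ribo_reads(
    transcripts: Sequence[TranscriptModel],
    truth: Mapping[str, TranscriptTruth],
    config: SimulationConfig,
    seed=None,
    expression: Mapping[str, float] | None = None,
    periodicity: float | None = None,
    depth_mult: float = 1.0,
    read_prefix: str = "ribo_",
) -> list[SamRead]:
    """Generate Ribo-seq footprint alignments for one dataset.

    ``expression`` maps transcript id to the realized RPKM in this dataset
    (0 or missing = unexpressed); by default every transcript is expressed at
    its base RPKM.  Deterministic given the seed.
    """
    rng = _rng(config.seed if seed is None else seed)
    ps = config.periodicity_strength if periodicity is None else periodicity
    if expression is None:
        expression = {tid: t.base_rpkm for tid, t in truth.items()}
    lengths_by_tid = {t.transcript_id: t.length for t in transcripts}
    pool = [tid for tid, r in expression.items() if r > 0 and not truth[tid].is_contaminant]
    factory = _ReadFactory(rng, config, lengths_by_tid, pool, read_prefix)
    depth = config.ribo_depth * depth_mult

    expected_signal = 0.0
    for t in transcripts:
        tid = t.transcript_id
        info = truth[tid]
        if info.is_contaminant:
            continue
        rpkm = expression.get(tid, 0.0)
        if rpkm <= 0:
            continue
        rate = rpkm * depth / 1e3  # expected reads per nt of fully covered region
        if info.is_translated and info.active_orf is not None:
            start, end = info.active_orf
            _periodic_orf(factory, tid, t.length, (start, end), rate * (end - start), ps)
            _uniform_region(factory, tid, t.length, 0, start,
                            rate * start * config.stop_dropoff)
            _uniform_region(factory, tid, t.length, end, t.length,
                            rate * (t.length - end) * config.stop_dropoff)
            expected_signal += rate * ((end - start) + (t.length - end + start) * config.stop_dropoff)
        elif info.is_associated:
            lam = rate * t.length * config.untranslated_coverage
            _uniform_region(factory, tid, t.length, 0, t.length, lam)
            expected_signal += lam
        else:
            lam = rate * t.length * config.stop_dropoff
            _uniform_region(factory, tid, t.length, 0, t.length, lam)
            expected_signal += lam

    contams = [t for t in transcripts if truth[t.transcript_id].is_contaminant]
    if contams and config.contaminant_fraction > 0:
        cf = config.contaminant_fraction
        lam_total = expected_signal * cf / (1 - cf)
        lnc_pool = [
            tid for tid in pool
            if not truth[tid].is_mrna and expression.get(tid, 0.0) > 0
        ]
        for t in contams:
            n = int(rng.poisson(lam_total / len(contams)))
            lengths = _footprint_lengths(rng, config, n)
            positions = rng.integers(0, max(1, t.length - config.footprint_max), n)
            for p, l in zip(positions, lengths):
                if lnc_pool and rng.random() < CONTAMINANT_CROSSMAP:
                    other = lnc_pool[int(rng.integers(0, len(lnc_pool)))]
                    factory.crossmap(t.transcript_id, int(p), int(l), other)
                else:
                    factory.emit(t.transcript_id, int(p), int(l))
    return factory.reads


def simulate_rna_reads(
    transcripts: Sequence[TranscriptModel],
    truth: Mapping[str, TranscriptTruth],
    config: SimulationConfig,
    seed=None,
    expression: Mapping[str, float] | None = None,
    depth_mult: float = 1.0,
    read_prefix: str = "rna_",
) -> list[SamRead]:
    """Uniform-coverage RNA-seq alignments, counts proportional to RPKM."""
    rng = _rng(config.seed if seed is None else seed)
    if expression is None:
        expression = {tid: t.base_rpkm for tid, t in truth.items()}
    lengths_by_tid = {t.transcript_id: t.length for t in transcripts}
    pool = [tid for tid, r in expression.items() if r > 0]
    factory = _ReadFactory(rng, config, lengths_by_tid, pool, read_prefix)
    for t in transcripts:
        tid = t.transcript_id
        rpkm = expression.get(tid, 0.0)
        if rpkm <= 0:
            continue
        lam = rpkm * (t.length / 1e3) * config.rna_depth * depth_mult
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        read_len = min(RNA_READ_LENGTH, t.length)
        positions = rng.integers(0, max(1, t.length - read_len + 1), n)
        for p in positions:
            factory.emit(tid, int(p), read_len)
    return factory.reads


def write_sam(
    reads: Sequence[SamRead],
    transcripts: Sequence[TranscriptModel],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for t in transcripts:
            fh.write(f"@SQ\tSN:{t.transcript_id}\tLN:{t.length}\n")
        for r in reads:
            fh.write(
                f"{r.qname}\t{r.flag}\t{r.transcript_id}\t{r.pos + 1}\t255\t"
                f"{r.length}M\t*\t0\t0\t*\t*\tNH:i:{r.n_hits}\n"
            )


# ---------------------------------------------------------------------------
# Genome + annotation emission (so the full GTF/FASTA path can be exercised)


def write_genome_annotation(
    transcripts: Sequence[TranscriptModel],
    genome_path: str | Path,
    gtf_path: str | Path,
    seed=None,
) -> None:
    """Lay each transcript out on its own chromosome (1-3 exons, random
    introns and flanks, ~30% minus strand) and write genome FASTA + GTF."""
    rng = _rng(0 if seed is None else seed)
    with open(genome_path, "w") as fa, open(gtf_path, "w") as gtf:
        for t in transcripts:
            chrom = f"chr_{t.transcript_id}"
            strand = "-" if rng.random() < 0.3 else "+"
            n_exons = int(rng.integers(1, 4)) if t.length >= 90 else 1
            cuts = sorted(rng.choice(np.arange(30, t.length - 29), n_exons - 1, replace=False)) if n_exons > 1 else []
            bounds = [0, *map(int, cuts), t.length]
            flank = _random_seq(rng, 20)
            pieces = [flank]
            segmap: list[tuple[int, int, int]] = []  # (tx offset, genomic start, end)
            gpos = len(flank)
            for k in range(n_exons):
                lo, hi = bounds[k], bounds[k + 1]
                pieces.append(t.sequence[lo:hi])
                segmap.append((lo, gpos, gpos + (hi - lo)))
                gpos += hi - lo
                if k < n_exons - 1:
                    intron = _random_seq(rng, int(rng.integers(40, 81)))
                    pieces.append(intron)
                    gpos += len(intron)
            pieces.append(_random_seq(rng, 20))
            layout = "".join(pieces)
            chrom_len = len(layout)

            def to_genomic(lo: int, hi: int) -> list[tuple[int, int]]:
                out = []
                for t_off, gs, ge in segmap:
                    seg_len = ge - gs
                    a, b = max(lo, t_off), min(hi, t_off + seg_len)
                    if a < b:
                        out.append((gs + (a - t_off), gs + (b - t_off)))
                return out

            def flip(iv: tuple[int, int]) -> tuple[int, int]:
                return (chrom_len - iv[1], chrom_len - iv[0])

            if strand == "-":
                from Bio.Seq import Seq

                chrom_seq = str(Seq(layout).reverse_complement())
            else:
                chrom_seq = layout
            fa.write(f">{chrom}\n")
            for i in range(0, chrom_len, 70):
                fa.write(chrom_seq[i : i + 70] + "\n")

            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_type "{t.biotype}";'
            )

            def feature(ftype: str, iv: tuple[int, int]) -> str:
                g = flip(iv) if strand == "-" else iv
                return (
                    f"{chrom}\tsim\t{ftype}\t{g[0] + 1}\t{g[1]}\t.\t{strand}\t.\t{attrs}\n"
                )

            for lo, hi in [(s[1], s[2]) for s in segmap]:
                gtf.write(feature("exon", (lo, hi)))
            if t.cds_span is not None:
                c0, c1 = t.cds_span
                for iv in to_genomic(c0, c1 - 3):
                    gtf.write(feature("CDS", iv))
                for iv in to_genomic(c1 - 3, c1):
                    gtf.write(feature("stop_codon", iv))


# ---------------------------------------------------------------------------
# Whole-study emission


def simulate_study(
    config: SimulationConfig,
    outdir: str | Path,
    seed: int | None = None,
) -> dict:
    """Simulate one multi-dataset study and write every pipeline input.

    Returns a manifest dict (paths, dataset descriptors, truth), also
    serialized as ``run.yaml`` + ``truth.tsv`` under ``outdir``.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 1])
    transcripts, truth = simulate_transcriptome(config, seed=np.random.default_rng([seed, 2]))
    write_genome_annotation(
        transcripts, outdir / "genome.fa", outdir / "annotation.gtf",
        seed=np.random.default_rng([seed, 3]),
    )
    contaminant_ids = [tid for tid, info in truth.items() if info.is_contaminant]
    (outdir / "contaminants.txt").write_text("".join(f"{c}\n" for c in contaminant_ids))

    ids = [t.transcript_id for t in transcripts]
    n_ds = config.n_datasets
    # realized per-dataset expression (RPKM; 0 = unexpressed)
    expr: list[dict[str, float]] = [dict() for _ in range(n_ds)]
    for tid in ids:
        info = truth[tid]
        flags = rng.random(n_ds) < info.breadth
        if info.is_contaminant:
            flags[:] = True
        if not flags.any():
            flags[int(rng.integers(0, n_ds))] = True
        for d in range(n_ds):
            if flags[d]:
                expr[d][tid] = info.base_rpkm * float(
                    np.exp(rng.normal(0.0, config.expression_sd))
                )

    datasets = []
    for d in range(n_ds):
        ds_id = f"D{d + 1}"
        mult = float(np.exp(rng.uniform(np.log(config.dataset_depth_low),
                                        np.log(config.dataset_depth_high))))
        ps = float(rng.uniform(config.dataset_periodicity_low,
                               config.dataset_periodicity_high))
        ribo = simulate_ribo_reads(
            transcripts, truth, config,
            seed=np.random.default_rng([seed, 10 + d]),
            expression=expr[d], periodicity=ps, depth_mult=mult,
            read_prefix=f"{ds_id}_ribo_",
        )
        rna = simulate_rna_reads(
            transcripts, truth, config,
            seed=np.random.default_rng([seed, 100 + d]),
            expression=expr[d], depth_mult=mult, read_prefix=f"{ds_id}_rna_",
        )
        ribo_path, rna_path = outdir / f"ribo_{ds_id}.sam", outdir / f"rna_{ds_id}.sam"
        write_sam(ribo, transcripts, ribo_path)
        write_sam(rna, transcripts, rna_path)
        datasets.append(
            {
                "id": ds_id,
                "tissue": f"tissue{d + 1:02d}",
                "ribo": ribo_path.name,
                "rna": rna_path.name,
                "mapping_rate_ribo": round(float(rng.uniform(0.5, 0.9)), 4),
                "mapping_rate_rna": round(float(rng.uniform(0.5, 0.9)), 4),
            }
        )

    with open(outdir / "truth.tsv", "w") as fh:
        ds_cols = "\t".join(f"rpkm_D{d + 1}" for d in range(n_ds))
        fh.write(
            "transcript_id\tis_mrna\tis_associated\tis_translated\t"
            f"orf_start\torf_end\tbase_rpkm\t{ds_cols}\n"
        )
        for tid in ids:
            info = truth[tid]
            orf = info.active_orf or ("", "")
            row = [
                tid, str(int(info.is_mrna)), str(int(info.is_associated)),
                str(int(info.is_translated)), str(orf[0]), str(orf[1]),
                f"{info.base_rpkm:.4f}",
            ]
            row.extend(f"{expr[d].get(tid, 0.0):.4f}" for d in range(n_ds))
            fh.write("\t".join(row) + "\n")

    manifest = {
        "annotation": "annotation.gtf",
        "genome": "genome.fa",
        "contaminants": "contaminants.txt",
        "outdir": "results",
        "seed": int(seed),
        "datasets": datasets,
    }
    with open(outdir / "run.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    manifest["_dir"] = str(outdir)
    manifest["_truth"] = truth
    manifest["_expression"] = expr
    return manifest
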