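"""End-to-end orchestration: annotation -> alignments -> QC -> density ->
coding -> catalog, driven by a YAML run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import alignments as aln
from . import catalog as cat
from . import coding, density, qc
from .errors import ConfigError, DataError, NoFootprintsError
from .transcriptome import (
    TranscriptModel,
    coding_gene_ids,
    find_putative_orfs,
    parse_annotation,
    read_fasta,
    select_lncrnas,
    write_transcriptome,
)


@dataclass
class DatasetInput:
    dataset_id: str
    tissue: str
    ribo: Path
    rna: Path
    mapping_rate_ribo: float = 1.0
    mapping_rate_rna: float = 1.0


@dataclass
class Thresholds:
    rpkm_min: float = 1.0
    utr3_percentile: float = 90.0
    coding_percentile: float = 10.0
    catalog_percentiles: tuple[float, float] = (5.0, 95.0)
    trans_top_fraction: float = 0.05
    rate_min: float = 0.30
    dist_max: float = 0.15
    max_hits: int = 100
    min_utr3_length: int = 30
    floss_window: tuple[int, int] = (25, 35)
    min_datasets: int = 1

    def validate(self) -> None:
        checks = [
            (0 <= self.rpkm_min, "rpkm_min must be >= 0"),
            (0 < self.utr3_percentile < 100, "utr3_percentile in (0, 100)"),
            (0 < self.coding_percentile < 100, "coding_percentile in (0, 100)"),
            (0 < self.trans_top_fraction < 1, "trans_top_fraction in (0, 1)"),
            (0 <= self.rate_min < 1, "rate_min in [0, 1)"),
            (0 < self.dist_max <= 1, "dist_max in (0, 1]"),
            (self.max_hits >= 1, "max_hits >= 1"),
            (
                0 < self.catalog_percentiles[0] < self.catalog_percentiles[1] < 100,
                "catalog_percentiles must be increasing within (0, 100)",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)


@dataclass
class RunConfig:
    annotation: Path
    genome: Path
    outdir: Path
    datasets: list[DatasetInput]
    contaminants: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at the top level")
        base = path.parent

        def resolve(p) -> Path:
            p = Path(p)
            return p if p.is_absolute() else base / p

        try:
            datasets = [
                DatasetInput(
                    dataset_id=str(d["id"]),
                    tissue=str(d["tissue"]),
                    ribo=resolve(d["ribo"]),
                    rna=resolve(d["rna"]),
                    mapping_rate_ribo=float(d.get("mapping_rate_ribo", 1.0)),
                    mapping_rate_rna=float(d.get("mapping_rate_rna", 1.0)),
                )
                for d in raw["datasets"]
            ]
            config = cls(
                annotation=resolve(raw["annotation"]),
                genome=resolve(raw["genome"]),
                outdir=resolve(raw.get("outdir", "results")),
                datasets=datasets,
                contaminants=resolve(raw["contaminants"]) if raw.get("contaminants") else None,
                thresholds=Thresholds(**raw.get("thresholds", {})),
                seed=int(raw.get("seed", 0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: invalid run configuration ({exc})") from exc
        config.validate()
        return config

    def validate(self) -> None:
        self.thresholds.validate()
        if not self.datasets:
            raise ConfigError("no datasets configured")
        seen = set()
        for d in self.datasets:
            if d.dataset_id in seen:
                raise ConfigError(f"duplicate dataset id {d.dataset_id!r}")
            seen.add(d.dataset_id)
            for p in (d.ribo, d.rna):
                if not Path(p).exists():
                    raise ConfigError(f"dataset {d.dataset_id}: missing file {p}")
        for p in (self.annotation, self.genome):
            if not Path(p).exists():
                raise ConfigError(f"missing input file {p}")


@dataclass
class DatasetResult:
    dataset_id: str
    expression: aln.ExpressionTable
    stats: dict[str, density.TranscriptDatasetStats]
    cutoff: float
    levels: dict[str, int]
    coding_cutoffs: tuple[float, float, float] | None = None


@dataclass
class PipelineResult:
    transcripts: list[TranscriptModel]
    lncrnas: list[TranscriptModel]
    profiles: list[qc.DatasetProfile]
    selected: list[str]
    per_dataset: dict[str, DatasetResult]
    entries: list[cat.CatalogEntry]


def _load_contaminants(path: Path | None) -> frozenset[str]:
    if path is None:
        return frozenset()
    return frozenset(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write per-stage TSVs under ``config.outdir``."""
    config.validate()
    th = config.thresholds
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = read_fasta(config.genome)
    transcripts = parse_annotation(config.annotation, genome)
    write_transcriptome(transcripts, outdir / "transcripts.fa", outdir / "transcripts.tsv")
    lengths = {t.transcript_id: t.length for t in transcripts}
    lncs = select_lncrnas(transcripts, coding_gene_ids=coding_gene_ids(transcripts))
    lnc_ids = frozenset(t.transcript_id for t in lncs)
    contaminants = _load_contaminants(config.contaminants)
    mrna_spans = {
        t.transcript_id: t.cds_span for t in transcripts if t.cds_span is not None
    }
    lnc_spans = {t.transcript_id: (0, t.length) for t in lncs}
    orfs_by_lnc = {t.transcript_id: find_putative_orfs(t.sequence, t.transcript_id) for t in lncs}

    # --- per-dataset ingestion + QC profile
    loaded: dict[str, tuple[list, list, aln.ExpressionTable]] = {}
    profiles: list[qc.DatasetProfile] = []
    for ds in config.datasets:
        rna_alns = aln.load_alignments(ds.rna, lengths, th.max_hits)
        if not rna_alns:
            raise DataError(f"{ds.dataset_id}: no usable RNA-seq alignments in {ds.rna}")
        expression = aln.quantify(rna_alns, lengths)
        ribo_alns = aln.load_alignments(ds.ribo, lengths, th.max_hits)
        ribo_alns = aln.remove_contaminants(ribo_alns, contaminants)
        aln.assign_weights(ribo_alns, expression)
        try:
            p_hist = qc.length_distribution(ribo_alns, mrna_spans)
            q_hist = qc.length_distribution(ribo_alns, lnc_spans)
            dist_value = qc.distribution_distance(p_hist, q_hist)
        except NoFootprintsError:
            dist_value = 1.0
        profiles.append(
            qc.DatasetProfile(
                dataset_id=ds.dataset_id,
                tissue=ds.tissue,
                mapping_rate_rna=ds.mapping_rate_rna,
                mapping_rate_ribo=ds.mapping_rate_ribo,
                dist_value=dist_value,
            )
        )
        loaded[ds.dataset_id] = (ribo_alns, rna_alns, expression)

    qc.select_datasets(profiles, th.rate_min, th.dist_max)
    qc.write_profiles(profiles, outdir / "qc.tsv")
    selected = [p.dataset_id for p in profiles if p.selected]
    if len(selected) < 2:
        raise DataError(
            f"only {len(selected)} dataset(s) passed selection; the tissue-specificity "
            "denominator M-1 requires at least 2"
        )

    # --- density + coding per selected dataset
    per_dataset: dict[str, DatasetResult] = {}
    for ds_id in selected:
        ribo_alns, rna_alns, expression = loaded[ds_id]
        stats, cutoff = density.dataset_density_stats(
            transcripts,
            ribo_alns,
            expression,
            ds_id,
            lnc_ids,
            rpkm_min=th.rpkm_min,
            utr3_percentile=th.utr3_percentile,
            min_utr3_length=th.min_utr3_length,
        )
        density.write_density_stats(stats, outdir / f"density_{ds_id}.tsv", cutoff)

        ribo_by_tid = aln.index_by_transcript(ribo_alns)
        rna_by_tid = aln.index_by_transcript(rna_alns)
        translating = [
            tid
            for tid, s in stats.items()
            if tid in mrna_spans and s.expressed and s.associated
        ]
        levels: dict[str, int] = {}
        cutoffs = None
        try:
            ref_hist = coding.cds_reference_length_hist(
                transcripts, ribo_by_tid, translating, th.floss_window
            )
            ref_frames = coding.cds_reference_frame_dist(transcripts, ribo_by_tid, translating)
            calib = coding.calibration_scores(
                transcripts, ribo_by_tid, rna_by_tid, translating,
                ref_hist, ref_frames, th.floss_window,
            )
            cutoffs = coding.coding_cutoffs(calib, th.coding_percentile)
            assessments = {}
            for t in lncs:
                tid = t.transcript_id
                s = stats.get(tid)
                if s is None or not s.expressed or not s.associated:
                    continue
                a = coding.assess_lncrna(
                    t,
                    ribo_by_tid.get(tid, []),
                    rna_by_tid.get(tid, []),
                    ref_hist,
                    ref_frames,
                    cutoffs,
                    ds_id,
                    th.floss_window,
                    orfs=orfs_by_lnc[tid],
                )
                assessments[tid] = a
                levels[tid] = a.level
            coding.write_assessments(assessments, outdir / f"coding_{ds_id}.tsv", cutoffs)
        except (NoFootprintsError, DataError) as exc:
            raise DataError(f"coding stage failed for dataset {ds_id}: {exc}") from exc

        per_dataset[ds_id] = DatasetResult(
            dataset_id=ds_id,
            expression=expression,
            stats=stats,
            cutoff=cutoff,
            levels=levels,
            coding_cutoffs=cutoffs,
        )

    # --- cross-dataset catalog
    expressed = {
        ds: {tid: s.expressed for tid, s in res.stats.items()}
        for ds, res in per_dataset.items()
    }
    associated = {
        ds: {tid: bool(s.associated) for tid, s in res.stats.items() if s.expressed}
        for ds, res in per_dataset.items()
    }
    entries = cat.build_catalog(
        [(t.transcript_id, t.biotype) for t in lncs],
        selected,
        expressed,
        associated,
        {ds: res.levels for ds, res in per_dataset.items()},
        min_datasets=th.min_datasets,
        percentiles=th.catalog_percentiles,
        trans_top_fraction=th.trans_top_fraction,
    )
    cat.write_catalog(entries, selected, outdir / "catalog.tsv")

    return PipelineResult(
        transcripts=transcripts,
        lncrnas=lncs,
        profiles=profiles,
        selected=selected,
        per_dataset=per_dataset,
        entries=entries,
    )
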