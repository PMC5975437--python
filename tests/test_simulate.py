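import numpy as np
import pytest
from scipy.stats import spearmanr

from riboassoc import alignments as aln
from riboassoc.simulate import (
    SimulationConfig,
    simulate_ribo_reads,
    simulate_rna_reads,
    simulate_study,
    simulate_transcriptome,
    write_sam,
)
from riboassoc.transcriptome import STOP_CODONS, find_putative_orfs

TINY = SimulationConfig(
    n_mrna=10,
    n_lnc_associated_translated=6,
    n_lnc_associated_untranslated=6,
    n_lnc_free=6,
    n_datasets=2,
)


class TestSimulateTranscriptome:
    def test_deterministic_given_seed(self):
        a, _ = simulate_transcriptome(TINY, seed=5)
        b, _ = simulate_transcriptome(TINY, seed=5)
        assert [(t.transcript_id, t.sequence) for t in a] == [
            (t.transcript_id, t.sequence) for t in b
        ]

    def test_lncrna_only_transcriptome(self):
        cfg = SimulationConfig(
            n_mrna=0, n_lnc_associated_translated=3, n_lnc_associated_untranslated=3,
            n_lnc_free=3, n_contaminants=0,
        )
        transcripts, truth = simulate_transcriptome(cfg, seed=1)
        assert all(not truth[t.transcript_id].is_mrna for t in transcripts)

    def test_mrna_cds_structure(self):
        transcripts, _ = simulate_transcriptome(TINY, seed=2)
        for t in transcripts:
            if t.cds_span is None:
                continue
            c0, c1 = t.cds_span
            assert (c1 - c0) % 3 == 0
            assert t.sequence[c0 : c0 + 3] == "ATG"
            assert t.sequence[c1 - 3 : c1] in STOP_CODONS

    def test_every_lncrna_has_a_putative_orf(self):
        transcripts, truth = simulate_transcriptome(TINY, seed=3)
        for t in transcripts:
            info = truth[t.transcript_id]
            if info.is_mrna or info.is_contaminant:
                continue
            orfs = find_putative_orfs(t.sequence)
            assert orfs
            if info.active_orf is not None:
                assert info.active_orf in [(o.start, o.end) for o in orfs]


class TestSimulateReads:
    def test_full_periodicity_limit(self):
        cfg = SimulationConfig(
            n_mrna=0, n_lnc_associated_translated=1, n_lnc_associated_untranslated=0,
            n_lnc_free=0, n_contaminants=0, periodicity_strength=1.0, stop_dropoff=0.0,
            multimap_rate=0.0, antisense_rate=0.0,
        )
        transcripts, truth = simulate_transcriptome(cfg, seed=4)
        reads = simulate_ribo_reads(transcripts, truth, cfg, seed=4, periodicity=1.0)
        (tid,) = [t.transcript_id for t in transcripts]
        start, end = truth[tid].active_orf
        tx_len = transcripts[0].length
        assert reads
        for r in reads:
            if r.pos + r.length < tx_len:  # not clipped at the 3' edge
                assert start <= r.pos < end
                assert (r.pos - start) % 3 == 0

    def test_zero_dropoff_confines_reads_to_orf(self):
        cfg = SimulationConfig(
            n_mrna=0, n_lnc_associated_translated=2, n_lnc_associated_untranslated=0,
            n_lnc_free=0, n_contaminants=0, stop_dropoff=0.0, multimap_rate=0.0,
        )
        transcripts, truth = simulate_transcriptome(cfg, seed=6)
        reads = simulate_ribo_reads(transcripts, truth, cfg, seed=6)
        for r in reads:
            start, end = truth[r.transcript_id].active_orf
            assert r.pos >= start

    def test_zero_depth_gives_no_reads(self):
        cfg = SimulationConfig(
            n_mrna=2, n_lnc_associated_translated=0, n_lnc_associated_untranslated=0,
            n_lnc_free=0, n_contaminants=0, rna_depth=1e-9,
        )
        transcripts, truth = simulate_transcriptome(cfg, seed=7)
        assert simulate_rna_reads(transcripts, truth, cfg, seed=7) == []

    def test_read_counts_match_poisson_mean(self):
        cfg = SimulationConfig(
            n_mrna=1, n_lnc_associated_translated=0, n_lnc_associated_untranslated=0,
            n_lnc_free=0, n_contaminants=0, multimap_rate=0.0,
        )
        transcripts, truth = simulate_transcriptome(cfg, seed=8)
        (t,) = transcripts
        lam = truth[t.transcript_id].base_rpkm * (t.length / 1e3) * cfg.rna_depth
        counts = [
            len(simulate_rna_reads(transcripts, truth, cfg, seed=100 + k))
            for k in range(20)
        ]
        se = np.sqrt(lam / 20)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_rpkm_recovery_rank_correlation(self):
        cfg = SimulationConfig(
            n_mrna=30, n_lnc_associated_translated=10, n_lnc_associated_untranslated=10,
            n_lnc_free=10, n_contaminants=0,
        )
        transcripts, truth = simulate_transcriptome(cfg, seed=9)
        lengths = {t.transcript_id: t.length for t in transcripts}
        for k in range(3):
            reads = simulate_rna_reads(transcripts, truth, cfg, seed=200 + k)
            alns = [
                aln.FootprintAlignment(r.qname, r.transcript_id, r.pos, r.length, r.n_hits)
                for r in reads
                if r.flag == 0
            ]
            table = aln.quantify(alns, lengths)
            true = [truth[tid].base_rpkm for tid in lengths]
            est = [table.get(tid) for tid in lengths]
            rho = spearmanr(true, est).statistic
            assert rho >= 0.95

    def test_sam_roundtrip_and_bounds(self, tmp_path):
        transcripts, truth = simulate_transcriptome(TINY, seed=10)
        reads = simulate_ribo_reads(transcripts, truth, TINY, seed=10)
        path = tmp_path / "ribo.sam"
        write_sam(reads, transcripts, path)
        lengths = {t.transcript_id: t.length for t in transcripts}
        loaded = aln.load_alignments(path, lengths, max_hits=100)
        assert loaded
        for a in loaded:
            assert 0 <= a.five_prime < lengths[a.transcript_id]


class TestSimulateStudy:
    def test_same_seed_is_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            simulate_study(TINY, tmp_path / d, seed=21)
        for name in ("genome.fa", "annotation.gtf", "ribo_D1.sam", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_manifest_files_exist(self, tmp_path):
        manifest = simulate_study(TINY, tmp_path / "s", seed=22)
        for key in ("annotation", "genome", "contaminants"):
            assert (tmp_path / "s" / manifest[key]).exists()
        for ds in manifest["datasets"]:
            assert (tmp_path / "s" / ds["ribo"]).exists()
            assert (tmp_path / "s" / ds["rna"]).exists()
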