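import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from riboassoc.errors import DataError
from riboassoc.transcriptome import (
    DEFAULT_LNC_BIOTYPES,
    STOP_CODONS,
    PutativeORF,
    TranscriptModel,
    find_putative_orfs,
    parse_annotation,
    read_fasta,
    select_lncrnas,
    write_transcriptome,
)

GTF = (
    '{chrom}\tsrc\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t'
    'gene_id "{gene}"; transcript_id "{tid}"; transcript_type "{biotype}";\n'
)


def gtf_line(chrom, ftype, start0, end0, strand, tid, gene="G1", biotype="lincRNA"):
    return GTF.format(
        chrom=chrom, ftype=ftype, start=start0 + 1, end=end0, strand=strand,
        gene=gene, tid=tid, biotype=biotype,
    )


class TestParseAnnotation:
    def test_plus_strand_exon_concatenation(self):
        lines = [
            gtf_line("c1", "exon", 0, 3, "+", "T1"),
            gtf_line("c1", "exon", 6, 9, "+", "T1"),
        ]
        (t,) = parse_annotation(lines, {"c1": "AAATTTCCC"})
        assert t.sequence == "AAACCC"
        assert t.length == 6

    def test_minus_strand_reverse_complement(self):
        (t,) = parse_annotation([gtf_line("c1", "exon", 0, 3, "-", "T1")], {"c1": "AAAG"})
        assert t.sequence == "TTT"

    def test_cds_projection_partitions_transcript(self):
        # 30 nt single-exon mRNA: CDS (stop split into a stop_codon record) in the middle
        seq = "GGGGG" + "ATGAAATTTCCC" + "TAA" + "CCCCCCCCCC"
        lines = [
            gtf_line("c1", "exon", 0, 30, "+", "T1", biotype="protein_coding"),
            gtf_line("c1", "CDS", 5, 17, "+", "T1", biotype="protein_coding"),
            gtf_line("c1", "stop_codon", 17, 20, "+", "T1", biotype="protein_coding"),
        ]
        (t,) = parse_annotation(lines, {"c1": seq})
        assert t.utr5_span == (0, 5)
        assert t.cds_span == (5, 20)
        assert t.utr3_span == (20, 30)
        # spans partition [0, length)
        assert t.utr5_span[1] == t.cds_span[0] and t.cds_span[1] == t.utr3_span[0]
        assert t.utr3_span[1] == t.length

    def test_missing_chromosome_is_hard_error(self):
        with pytest.raises(DataError, match="T1"):
            parse_annotation([gtf_line("nope", "exon", 0, 3, "+", "T1")], {"c1": "AAA"})

    def test_exon_outside_bounds_is_hard_error(self):
        with pytest.raises(DataError, match="bounds"):
            parse_annotation([gtf_line("c1", "exon", 0, 50, "+", "T1")], {"c1": "AAA"})

    def test_roundtrip_through_fasta(self, small_study, tmp_path):
        transcripts = small_study["result"].transcripts
        path = tmp_path / "tx.fa"
        write_transcriptome(transcripts, path)
        back = read_fasta(path)
        assert set(back) == {t.transcript_id for t in transcripts}
        for t in transcripts:
            assert back[t.transcript_id] == t.sequence


class TestSelectLncrnas:
    def _tx(self, tid, biotype, gene):
        return TranscriptModel(tid, gene, biotype, "ACGT")

    def test_lincrna_kept(self):
        kept = select_lncrnas([self._tx("T1", "lincRNA", "G1")])
        assert [t.transcript_id for t in kept] == ["T1"]

    def test_lncrna_from_coding_gene_excluded(self):
        t = self._tx("T1", "retained_intron", "G1")
        assert select_lncrnas([t], coding_gene_ids={"G1"}) == []

    def test_non_lnc_biotype_excluded(self):
        assert select_lncrnas([self._tx("T1", "protein_coding", "G1")]) == []

    def test_empty_input(self):
        assert select_lncrnas([]) == []

    def test_default_whitelist_has_twelve_biotypes(self):
        assert len(DEFAULT_LNC_BIOTYPES) == 12


def orf_oracle(seq):
    """Exhaustive scan over all in-frame (ATG, stop) pairs; longest per stop."""
    seq = seq.upper()
    found = {}
    n = len(seq)
    for atg in range(n - 2):
        if seq[atg : atg + 3] != "ATG":
            continue
        for stop in range(atg + 3, n - 2, 3):
            codon = seq[stop : stop + 3]
            if codon in STOP_CODONS:
                if stop + 3 - atg >= 30:
                    key = (atg % 3, stop)
                    if key not in found or atg < found[key][0]:
                        found[key] = (atg, stop + 3)
                break  # first in-frame stop terminates this ORF
    return sorted(found.values())


class TestFindPutativeOrfs:
    def test_minimal_length_boundary(self):
        seq = "ATG" + "AAA" * 8 + "TAG"  # 30 nt
        (orf,) = find_putative_orfs(seq)
        assert (orf.start, orf.end) == (0, 30)

    def test_below_minimum_length(self):
        assert find_putative_orfs("ATGAAATAG") == []

    def test_longest_orf_per_stop(self):
        seq = "ATGATG" + "AAA" * 7 + "TAA"
        orfs = find_putative_orfs(seq)
        assert [(o.start, o.end) for o in orfs] == [(0, 30)]

    def test_n_codons_never_start_or_stop(self):
        seq = "ATN" + "AAA" * 8 + "TAG" + "NAA"
        assert find_putative_orfs(seq) == []

    def test_orfs_revalidate_against_sequence(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 200))
            for orf in find_putative_orfs(seq):
                orf.validate(seq)

    def test_matches_exhaustive_oracle_on_random_sequences(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 301))
            seq = "".join(rng.choice(list("ACGTN"), n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            got = [(o.start, o.end) for o in find_putative_orfs(seq)]
            assert got == orf_oracle(seq)

    @given(st.text(alphabet="ACGT", min_size=30, max_size=120))
    def test_matches_oracle_property(self, seq):
        got = [(o.start, o.end) for o in find_putative_orfs(seq)]
        assert got == orf_oracle(seq)
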