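"""Transcript models, lncRNA selection, and putative-ORF enumeration.

Annotations are consumed in the GENCODE GTF dialect (attributes
``transcript_id``, ``gene_id``, ``transcript_type``).  Exons of a transcript
are concatenated 5'->3' into a transcriptome sequence; minus-strand
transcripts are reverse-complemented.  CDS records (with the stop codon,
which GENCODE annotates separately as ``stop_codon``) are projected into
transcript coordinates, which partitions a coding transcript into
5'UTR / CDS / 3'UTR.

All internal coordinates are 0-based half-open transcript coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

from .errors import DataError

#: The twelve GENCODE biotypes treated as lncRNA by default.
DEFAULT_LNC_BIOTYPES = frozenset(
    {
        "lincRNA",
        "antisense",
        "TEC",
        "sense_intronic",
        "retained_intron",
        "processed_transcript",
        "sense_overlapping",
        "3prime_overlapping_ncRNA",
        "pseudogene",
        "bidirectional_promoter_lncRNA",
        "non_coding",
        "macro_lncRNA",
    }
)

STOP_CODONS = frozenset({"TGA", "TAA", "TAG"})
MIN_ORF_LENGTH = 30  # nt, stop codon included


@dataclass
class TranscriptModel:
    """A transcript with its sequence and region spans in transcript coordinates."""

    transcript_id: str
    gene_id: str
    biotype: str
    sequence: str
    utr5_span: tuple[int, int] | None = None
    cds_span: tuple[int, int] | None = None
    utr3_span: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    def validate(self) -> None:
        n = self.length
        if n == 0:
            raise DataError(f"{self.transcript_id}: empty sequence")
        if self.cds_span is not None:
            u5, cds, u3 = self.utr5_span, self.cds_span, self.utr3_span
            for span in (u5, cds, u3):
                if span is not None and not (0 <= span[0] <= span[1] <= n):
                    raise DataError(f"{self.transcript_id}: span {span} outside [0, {n})")
            if (cds[1] - cds[0]) % 3 != 0 or cds[1] <= cds[0]:
                raise DataError(
                    f"{self.transcript_id}: CDS length {cds[1] - cds[0]} is not a "
                    "positive multiple of 3"
                )
            if u5 is not None and u5[1] > cds[0]:
                raise DataError(f"{self.transcript_id}: 5'UTR overlaps CDS")
            if u3 is not None and u3[0] < cds[1]:
                raise DataError(f"{self.transcript_id}: 3'UTR overlaps CDS")


@dataclass(frozen=True)
class PutativeORF:
    """An ATG..stop reading frame of >= 30 nt (stop included) in a transcript."""

    transcript_id: str
    start: int
    end: int  # half-open; one past the last base of the stop codon

    @property
    def frame(self) -> int:
        return self.start % 3

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self, sequence: str) -> None:
        if self.length < MIN_ORF_LENGTH or self.length % 3:
            raise DataError(f"ORF {self.start}-{self.end}: bad length {self.length}")
        if sequence[self.start : self.start + 3] != "ATG":
            raise DataError(f"ORF {self.start}-{self.end}: does not start with ATG")
        if sequence[self.end - 3 : self.end] not in STOP_CODONS:
            raise DataError(f"ORF {self.start}-{self.end}: does not end with a stop codon")
        for pos in range(self.start + 3, self.end - 3, 3):
            if sequence[pos : pos + 3] in STOP_CODONS:
                raise DataError(f"ORF {self.start}-{self.end}: internal stop at {pos}")


def _attr(feature, *names: str) -> str | None:
    for name in names:
        values = feature.attributes.get(name)
        if values:
            return values[0]
    return None


def parse_annotation(
    annotation: str | Path | Iterable[str],
    genome: Mapping[str, str],
) -> list[TranscriptModel]:
    """Build :class:`TranscriptModel` objects from GTF records and genomic sequence.

    Parameters
    ----------
    annotation
        Path to a GTF file, or an iterable of GTF lines.
    genome
        Mapping of chromosome name to sequence (e.g. from :func:`read_fasta`).

    Raises
    ------
    DataError
        If a referenced chromosome is missing or an exon exceeds its bounds.
    """
    if isinstance(annotation, (str, Path)):
        lines: Iterable[str] = open(annotation)
    else:
        lines = annotation

    # transcript_id -> accumulated structure
    exons: dict[str, list[tuple[str, str, int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        feat = feature_from_line(line)
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tid = _attr(feat, "transcript_id")
        if tid is None:
            raise DataError(f"record without transcript_id: {line.strip()[:80]}")
        gid = _attr(feat, "gene_id") or tid
        biotype = _attr(feat, "transcript_type", "transcript_biotype", "gene_type") or "unknown"
        if tid not in meta:
            meta[tid] = (gid, biotype)
            order.append(tid)
        iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.seqid, feat.strand, iv[0], iv[1]))
        else:
            cds.setdefault(tid, []).append(iv)
    if isinstance(lines, io.IOBase):
        lines.close()

    transcripts = []
    for tid in order:
        if tid not in exons:
            continue  # e.g. gene/transcript rows only
        gid, biotype = meta[tid]
        transcripts.append(_build_transcript(tid, gid, biotype, exons[tid], cds.get(tid), genome))
    return transcripts


def _build_transcript(
    tid: str,
    gid: str,
    biotype: str,
    exon_records: Sequence[tuple[str, str, int, int]],
    cds_intervals: Sequence[tuple[int, int]] | None,
    genome: Mapping[str, str],
) -> TranscriptModel:
    chroms = {rec[0] for rec in exon_records}
    strands = {rec[1] for rec in exon_records}
    if len(chroms) != 1 or len(strands) != 1:
        raise DataError(f"{tid}: exons span multiple chromosomes or strands")
    chrom, strand = chroms.pop(), strands.pop()
    if chrom not in genome:
        raise DataError(f"{tid}: chromosome {chrom!r} not present in the genome FASTA")
    chrom_seq = genome[chrom]

    exon_ivs = sorted((s, e) for _, _, s, e in exon_records)
    for s, e in exon_ivs:
        if s < 0 or e > len(chrom_seq) or s >= e:
            raise DataError(f"{tid}: exon [{s}, {e}) outside chromosome {chrom} bounds")
    if strand == "-":
        tx_order = exon_ivs[::-1]
    else:
        tx_order = exon_ivs

    parts = []
    # (transcript offset, genomic start, genomic end) per exon, transcript order
    segmap: list[tuple[int, int, int]] = []
    off = 0
    for s, e in tx_order:
        piece = chrom_seq[s:e].upper()
        if strand == "-":
            piece = str(Seq(piece).reverse_complement())
        parts.append(piece)
        segmap.append((off, s, e))
        off += e - s
    sequence = "".join(parts)
    length = len(sequence)

    spans = (None, None, None)
    if cds_intervals:
        tx_positions: list[int] = []
        for gs, ge in cds_intervals:
            for t_off, es, ee in segmap:
                lo, hi = max(gs, es), min(ge, ee)
                if lo >= hi:
                    continue
                if strand == "-":
                    tx_positions.extend((t_off + (ee - hi), t_off + (ee - lo)))
                else:
                    tx_positions.extend((t_off + (lo - es), t_off + (hi - es)))
        if not tx_positions:
            raise DataError(f"{tid}: CDS does not overlap any exon")
        cds_start, cds_end = min(tx_positions), max(tx_positions)
        spans = (
            (0, cds_start) if cds_start > 0 else None,
            (cds_start, cds_end),
            (cds_end, length) if cds_end < length else None,
        )

    model = TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        biotype=biotype,
        sequence=sequence,
        utr5_span=spans[0],
        cds_span=spans[1],
        utr3_span=spans[2],
    )
    model.validate()
    return model


def select_lncrnas(
    transcripts: Iterable[TranscriptModel],
    lnc_biotypes: frozenset[str] | set[str] = DEFAULT_LNC_BIOTYPES,
    coding_gene_ids: set[str] | frozenset[str] = frozenset(),
) -> list[TranscriptModel]:
    """lncRNA whitelist filter: keep lncRNA biotypes not derived from coding genes."""
    return [
        t
        for t in transcripts
        if t.biotype in lnc_biotypes and t.gene_id not in coding_gene_ids
    ]


def coding_gene_ids(transcripts: Iterable[TranscriptModel]) -> set[str]:
    """Gene ids having at least one protein-coding transcript."""
    return {t.gene_id for t in transcripts if t.biotype == "protein_coding" or t.is_coding}


def find_putative_orfs(sequence: str, transcript_id: str = "") -> list[PutativeORF]:
    """Enumerate putative ORFs: ATG..{TGA,TAA,TAG}, >= 30 nt including the stop.

    One ORF is reported per (frame, stop codon): the longest one, anchored at
    the most 5' in-frame ATG with no intervening in-frame stop.  Codons
    containing N never match a start or stop codon.  Results are sorted by
    start position.
    """
    sequence = sequence.upper()
    orfs: list[PutativeORF] = []
    n = len(sequence)
    for frame in range(3):
        pending: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = sequence[pos : pos + 3]
            if codon in STOP_CODONS:
                if pending is not None and pos + 3 - pending >= MIN_ORF_LENGTH:
                    orfs.append(PutativeORF(transcript_id, pending, pos + 3))
                pending = None
            elif codon == "ATG" and pending is None:
                pending = pos
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_transcriptome(
    transcripts: Sequence[TranscriptModel],
    fasta_path: str | Path,
    table_path: str | Path | None = None,
) -> None:
    """Write transcript sequences (FASTA) and an optional summary table (TSV)."""
    with open(fasta_path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, t.length, 70):
                fh.write(t.sequence[i : i + 70] + "\n")
    if table_path is None:
        return
    with open(table_path, "w") as fh:
        fh.write(
            "transcript_id\tgene_id\tbiotype\tlength\t"
            "utr5_start\tutr5_end\tcds_start\tcds_end\tutr3_start\tutr3_end\n"
        )
        for t in transcripts:
            cells = [t.transcript_id, t.gene_id, t.biotype, str(t.length)]
            for span in (t.utr5_span, t.cds_span, t.utr3_span):
                cells.extend(["", ""] if span is None else [str(span[0]), str(span[1])])
            fh.write("\t".join(cells) + "\n")
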