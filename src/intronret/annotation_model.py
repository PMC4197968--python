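"""Transcript models and intron derivation from GTF/FASTA.

Internally every interval is 0-based, half-open, on genomic coordinates.
GTF input/output uses the Ensembl dialect (1-based, inclusive) and the
conversion happens only at the I/O boundary.  Introns are the gaps between
consecutive exons of one transcript, ordered and numbered in transcript
orientation (ordinal 1 = most 5' intron), with their sequence extracted
strand-aware so that every intron reads donor ``GT ... AG`` acceptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pyfaidx

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch an uppercase genomic slice from a dict of strings or a pyfaidx Fasta."""
    if isinstance(genome, Mapping):
        return str(genome[chrom][start:end]).upper()
    return str(genome[chrom][start:end]).upper()


@dataclass
class TranscriptModel:
    """One transcript's exon chain on a strand.

    ``exons`` are stored sorted in ascending genomic order regardless of
    strand; use :meth:`exons_5to3` for transcript orientation.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r} for {self.transcript_id}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon ({s},{e}) in {self.transcript_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
            prev_end = e

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_5to3(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def genomic_gaps(self) -> list[tuple[int, int]]:
        """Inter-exon gaps in ascending genomic order (may include width zero)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]


@dataclass
class IntronRecord:
    """One intron with coordinates and architectural context.

    ``ordinal`` is 1-based in transcript orientation; neighbor lengths refer
    to the adjacent introns of the same transcript (None at the ends).
    ``sequence`` is in transcript orientation, so it starts with the donor
    dinucleotide and ends with the acceptor.
    """

    intron_id: str
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    ordinal: int
    n_introns: int
    upstream_intron_length: int | None = None
    downstream_intron_length: int | None = None
    sequence: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_first(self) -> bool:
        return self.ordinal == 1

    @property
    def is_last(self) -> bool:
        return self.ordinal == self.n_introns


@dataclass
class GenomeAnnotation:
    """A collection of transcript models plus chromosome lengths."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    genome: object | None = None  # dict[str, str] or pyfaidx.Fasta, optional

    def __post_init__(self) -> None:
        for t in self.transcripts.values():
            if self.chrom_lengths:
                if t.chrom not in self.chrom_lengths:
                    raise ValueError(
                        f"chromosome {t.chrom!r} of {t.transcript_id} missing from genome"
                    )
                if t.span[1] > self.chrom_lengths[t.chrom] or t.span[0] < 0:
                    raise ValueError(
                        f"exon of {t.transcript_id} outside bounds of {t.chrom!r}"
                    )

    def all_introns(self, genome=None) -> list[IntronRecord]:
        """Introns of every transcript, sequences filled if a genome is available."""
        genome = genome if genome is not None else self.genome
        out: list[IntronRecord] = []
        for tid in sorted(self.transcripts):
            out.extend(extract_introns(self.transcripts[tid], genome))
        return out


def extract_introns(transcript: TranscriptModel, genome=None) -> list[IntronRecord]:
    """Derive the ordered introns of one transcript.

    Zero-width gaps (abutting exons) are skipped with a warning; ordinals
    number the remaining introns 1..k in transcript orientation.
    """
    gaps = [g for g in transcript.genomic_gaps() if g[1] > g[0]]
    for g in transcript.genomic_gaps():
        if g[1] == g[0]:
            logger.warning(
                "abutting exons at %s:%d in %s; no intron recorded",
                transcript.chrom, g[0], transcript.transcript_id,
            )
    if transcript.strand == "-":
        gaps = list(reversed(gaps))  # transcript orientation
    n = len(gaps)
    records: list[IntronRecord] = []
    for i, (s, e) in enumerate(gaps):
        seq = None
        if genome is not None:
            seq = fetch_sequence(genome, transcript.chrom, s, e)
            if transcript.strand == "-":
                seq = reverse_complement(seq)
        records.append(
            IntronRecord(
                intron_id=f"{transcript.transcript_id}.i{i + 1}",
                transcript_id=transcript.transcript_id,
                gene_id=transcript.gene_id,
                chrom=transcript.chrom,
                strand=transcript.strand,
                start=s,
                end=e,
                ordinal=i + 1,
                n_introns=n,
                upstream_intron_length=(gaps[i - 1][1] - gaps[i - 1][0]) if i > 0 else None,
                downstream_intron_length=(gaps[i + 1][1] - gaps[i + 1][0]) if i < n - 1 else None,
                sequence=seq,
            )
        )
    return records


def deduplicate_introns(
    introns: Iterable[IntronRecord],
    transcript_rank: Mapping[str, float] | None = None,
) -> list[IntronRecord]:
    """Collapse introns with identical genomic coordinates within one gene.

    Isoforms of a gene frequently share introns; counting each copy would
    double-weight them in group statistics.  The surviving record is the one
    attached to the transcript with the highest ``transcript_rank`` (e.g.
    control-condition RPKM); ties and missing ranks fall back to lexicographic
    transcript id for determinism.
    """
    best: dict[tuple, IntronRecord] = {}
    for rec in introns:
        key = (rec.gene_id, rec.chrom, rec.start, rec.end, rec.strand)
        if key not in best:
            best[key] = rec
            continue
        cur = best[key]
        r_new = transcript_rank.get(rec.transcript_id, 0.0) if transcript_rank else 0.0
        r_cur = transcript_rank.get(cur.transcript_id, 0.0) if transcript_rank else 0.0
        if (r_new, cur.transcript_id) > (r_cur, rec.transcript_id):
            best[key] = rec
    return sorted(best.values(), key=lambda r: r.intron_id)


def load_annotation(gtf_path: str, fasta_path: str | None = None) -> GenomeAnnotation:
    """Read a GTF (Ensembl dialect) and an indexable FASTA into an annotation.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Exon lines may appear in any order.  A chromosome referenced by the GTF
    but absent from the FASTA, or an exon outside chromosome bounds, is a
    hard error.
    """
    raw: dict[str, dict] = {}
    try:
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
        exon_features = list(db.features_of_type("exon"))
    except gffutils.exceptions.EmptyInputError:
        exon_features = []  # an empty annotation is valid input
    for feat in exon_features:
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        entry = raw.setdefault(tid, {"gene_id": gid, "chrom": feat.seqid,
                                     "strand": feat.strand, "exons": []})
        entry["exons"].append((feat.start - 1, feat.end))

    genome = None
    chrom_lengths: dict[str, int] = {}
    if fasta_path is not None:
        genome = pyfaidx.Fasta(str(fasta_path))
        chrom_lengths = {name: len(genome[name]) for name in genome.keys()}
        for tid, entry in raw.items():
            if entry["chrom"] not in chrom_lengths:
                raise ValueError(
                    f"chromosome {entry['chrom']!r} (transcript {tid}) not in FASTA"
                )

    transcripts = {
        tid: TranscriptModel(
            transcript_id=tid,
            gene_id=entry["gene_id"],
            chrom=entry["chrom"],
            strand=entry["strand"],
            exons=entry["exons"],
        )
        for tid, entry in raw.items()
    }
    return GenomeAnnotation(
        transcripts=transcripts, chrom_lengths=chrom_lengths, genome=genome
    )


def write_gtf(annotation: GenomeAnnotation, path: str, source: str = "intronret") -> None:
    """Write exon lines in GTF (1-based inclusive) for every transcript."""
    with open(path, "w") as fh:
        for tid in sorted(annotation.transcripts):
            t = annotation.transcripts[tid]
            for s, e in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def introns_to_bed6(introns: Sequence[IntronRecord], path: str) -> None:
    """Export introns as BED6 (0-based half-open, strand in column 6)."""
    with open(path, "w") as fh:
        for rec in introns:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.intron_id}\t0\t{rec.strand}\n"
            )


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    """Write a dict of chromosome sequences as FASTA."""
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
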