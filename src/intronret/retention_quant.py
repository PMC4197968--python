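"""Read counting, RPKM, analysis filters, retention indices and fold changes.

Counting rules
--------------
Only uniquely aligned fragments are used.  A fragment (read pair, or single
read) increments a transcript's exonic count when every aligned block lies
inside that transcript's exons and internal block boundaries coincide with
the exon junctions (block-compatible).  It increments an intron's count
when any aligned base overlaps the intron interval.  The asymmetry is
deliberate: a single intronic base is unambiguous evidence of retention,
whereas exonic assignment must respect the splice structure.  A fragment
counts at most once per feature.  With a strand-specific library only
same-strand fragments count.

RPKM = count / (feature length in kb x library size in millions), with the
library size being the number of uniquely aligned fragments.  The retention
index of an intron is its RPKM divided by its transcript's exonic RPKM in
the same sample (replicates combined by arithmetic mean of RPKM first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from intronret.annotation_model import GenomeAnnotation, IntronRecord

logger = logging.getLogger(__name__)

BLOCK_COLUMNS = ["fragment_id", "chrom", "strand", "start", "end", "block_index", "n_blocks"]


@dataclass
class SampleQuant:
    """Per-sample raw counts and derived RPKM for transcripts and introns."""

    sample_id: str
    condition: str
    replicate: int
    library_size: int
    transcript_counts: dict[str, int] = field(default_factory=dict)
    intron_counts: dict[str, int] = field(default_factory=dict)
    transcript_rpkm: dict[str, float] | None = None
    intron_rpkm: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# fragment input


def load_fragments_tsv(path: str) -> pd.DataFrame:
    """Read the plain-text read-placement format into a block table.

    The TSV has one row per fragment: ``fragment_id  chrom  strand  blocks``
    with blocks as ``start-end`` pairs (0-based half-open) joined by commas.
    The returned frame has one row per aligned block (columns
    ``BLOCK_COLUMNS``).
    """
    frame = pd.read_csv(
        path, sep="\t", dtype={"fragment_id": str, "chrom": str, "strand": str}
    )
    rows = []
    for frag, chrom, strand, blocks in frame[
        ["fragment_id", "chrom", "strand", "blocks"]
    ].itertuples(index=False):
        parts = blocks.split(",")
        for i, part in enumerate(parts):
            s, e = part.split("-")
            rows.append((frag, chrom, strand, int(s), int(e), i, len(parts)))
    return pd.DataFrame(rows, columns=BLOCK_COLUMNS)


def write_fragments_tsv(blocks: pd.DataFrame, path: str) -> None:
    """Inverse of :func:`load_fragments_tsv`."""
    frame = blocks.sort_values(["fragment_id", "block_index"], kind="stable")
    frame = frame.assign(
        blk=frame["start"].astype(str) + "-" + frame["end"].astype(str)
    )
    grouped = frame.groupby(["fragment_id", "chrom", "strand"], sort=True)["blk"].agg(
        ",".join
    )
    out = grouped.reset_index().rename(columns={"blk": "blocks"})
    out.to_csv(path, sep="\t", index=False)


def load_fragments_sam(path: str, min_mapq: int = 1) -> pd.DataFrame:
    """Read uniquely aligned fragments from SAM/BAM into a block table.

    Multimappers are excluded by mapping quality (< ``min_mapq``) or an NH
    tag > 1.  Mates of a pair are merged into a single fragment; overlapping
    mate blocks are unioned so a base never counts twice.
    """
    import pysam

    by_fragment: dict[str, dict] = {}
    with pysam.AlignmentFile(str(path)) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.has_tag("NH") and read.get_tag("NH") > 1:
                continue
            strand = "-" if read.is_reverse else "+"
            entry = by_fragment.setdefault(
                read.query_name,
                {"chrom": read.reference_name, "strand": strand, "blocks": []},
            )
            entry["blocks"].extend(read.get_blocks())

    rows = []
    for frag, entry in by_fragment.items():
        merged: list[list[int]] = []
        for s, e in sorted(entry["blocks"]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for i, (s, e) in enumerate(merged):
            rows.append((frag, entry["chrom"], entry["strand"], s, e, i, len(merged)))
    return pd.DataFrame(rows, columns=BLOCK_COLUMNS)


# ---------------------------------------------------------------------------
# counting


def _exon_table(annotation: GenomeAnnotation) -> pd.DataFrame:
    rows = []
    for tid in sorted(annotation.transcripts):
        t = annotation.transcripts[tid]
        for s, e in t.exons:
            rows.append((t.chrom, s, e, t.strand, tid))
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "Strand", "transcript_id"])


def _intron_table(introns: Sequence[IntronRecord]) -> pd.DataFrame:
    rows = [(r.chrom, r.start, r.end, r.strand, r.intron_id) for r in introns]
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "Strand", "intron_id"])


def count_features(
    blocks: pd.DataFrame,
    annotation: GenomeAnnotation,
    introns: Sequence[IntronRecord] | None = None,
    stranded: bool = True,
    sample_id: str = "sample",
    condition: str = "control",
    replicate: int = 1,
    library_size: int | None = None,
) -> SampleQuant:
    """Count fragments per transcript (exonic) and per intron.

    ``blocks`` is a block table (see :data:`BLOCK_COLUMNS`).  The library
    size defaults to the number of distinct fragments in the table.
    """
    if introns is None:
        introns = annotation.all_introns(genome=None)

    if library_size is None:
        library_size = int(blocks["fragment_id"].nunique())
    if library_size == 0:
        raise ValueError("zero library size: no uniquely aligned fragments")

    known = set(annotation.chrom_lengths) or {
        t.chrom for t in annotation.transcripts.values()
    }
    missing = set(blocks["chrom"].unique()) - known
    if missing:
        logger.warning("skipping fragments on unannotated chromosomes: %s", sorted(missing))
        blocks = blocks[~blocks["chrom"].isin(missing)]

    frag_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": blocks["chrom"].to_numpy(),
                "Start": blocks["start"].to_numpy(),
                "End": blocks["end"].to_numpy(),
                "Strand": blocks["strand"].to_numpy(),
                "fragment_id": blocks["fragment_id"].to_numpy(),
                "block_index": blocks["block_index"].to_numpy(),
                "n_blocks": blocks["n_blocks"].to_numpy(),
            }
        )
    )
    strandedness = "same" if stranded else False

    # intron counts: any overlap, each fragment at most once per intron
    intron_counts: dict[str, int] = {r.intron_id: 0 for r in introns}
    if introns and len(blocks):
        join = frag_pr.join(pr.PyRanges(_intron_table(introns)), strandedness=strandedness)
        jdf = join.df
        if len(jdf):
            pairs = jdf[["fragment_id", "intron_id"]].drop_duplicates()
            for iid, n in pairs["intron_id"].value_counts().items():
                intron_counts[iid] = int(n)

    # transcript exonic counts: every block contained and block-compatible
    transcript_counts: dict[str, int] = {t: 0 for t in annotation.transcripts}
    if annotation.transcripts and len(blocks):
        join = frag_pr.join(pr.PyRanges(_exon_table(annotation)), strandedness=strandedness)
        jdf = join.df
        if len(jdf):
            contained = (jdf["Start"] >= jdf["Start_b"]) & (jdf["End"] <= jdf["End_b"])
            jdf = jdf[contained]
        if len(jdf):
            last = jdf["block_index"] == jdf["n_blocks"] - 1
            first = jdf["block_index"] == 0
            compatible = (last | (jdf["End"] == jdf["End_b"])) & (
                first | (jdf["Start"] == jdf["Start_b"])
            )
            jdf = jdf.assign(compatible=compatible)
            grp = jdf.groupby(["fragment_id", "transcript_id"], sort=False).agg(
                n_matched=("block_index", "nunique"),
                n_blocks=("n_blocks", "first"),
                all_compatible=("compatible", "all"),
            )
            ok = grp[(grp["n_matched"] == grp["n_blocks"]) & grp["all_compatible"]]
            for tid, n in ok.reset_index()["transcript_id"].value_counts().items():
                transcript_counts[tid] = int(n)

    return SampleQuant(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        library_size=library_size,
        transcript_counts=transcript_counts,
        intron_counts=intron_counts,
    )


# ---------------------------------------------------------------------------
# RPKM and filters


def _rpkm(count: float, length: int, library_size: int) -> float:
    if length <= 0:
        raise ValueError("zero-length feature")
    return count * 1e9 / (length * library_size)


def compute_rpkm(
    quant: SampleQuant,
    annotation: GenomeAnnotation,
    introns: Sequence[IntronRecord] | None = None,
) -> SampleQuant:
    """Fill the RPKM maps of a sample from its counts and feature lengths."""
    if quant.library_size == 0:
        raise ValueError("zero library size")
    if introns is None:
        introns = annotation.all_introns(genome=None)
    intron_lengths = {r.intron_id: r.length for r in introns}
    quant.transcript_rpkm = {
        tid: _rpkm(c, annotation.transcripts[tid].exonic_length, quant.library_size)
        for tid, c in quant.transcript_counts.items()
    }
    quant.intron_rpkm = {
        iid: _rpkm(c, intron_lengths[iid], quant.library_size)
        for iid, c in quant.intron_counts.items()
    }
    return quant


def apply_analysis_filters(
    quants: Sequence[SampleQuant],
    introns: Sequence[IntronRecord],
    control_condition: str = "control",
    min_transcript_rpkm: float = 10.0,
    intron_fraction: float = 0.10,
    intron_filter_scope: str = "any",
) -> tuple[set[str], set[str]]:
    """Select analyzable transcripts and introns.

    A transcript passes when its mean control-condition RPKM is strictly
    greater than ``min_transcript_rpkm``.  An intron passes when its parent
    transcript passes and its RPKM exceeds ``intron_fraction`` of the
    transcript RPKM in at least one replicate — of any sample when
    ``intron_filter_scope='any'`` (literal reading), or of the control
    replicates only when ``'control'``.
    """
    controls = [q for q in quants if q.condition == control_condition]
    if not controls:
        raise ValueError(f"no samples with control condition {control_condition!r}")
    for q in quants:
        if q.transcript_rpkm is None or q.intron_rpkm is None:
            raise ValueError(f"sample {q.sample_id} has no RPKM; run compute_rpkm first")

    tids = set(controls[0].transcript_rpkm)
    mean_ctrl = {
        tid: float(np.mean([q.transcript_rpkm[tid] for q in controls])) for tid in tids
    }
    passed_t = {tid for tid, v in mean_ctrl.items() if v > min_transcript_rpkm}

    scope = quants if intron_filter_scope == "any" else controls
    passed_i = set()
    for rec in introns:
        if rec.transcript_id not in passed_t:
            continue
        for q in scope:
            t_rpkm = q.transcript_rpkm.get(rec.transcript_id, 0.0)
            if q.intron_rpkm.get(rec.intron_id, 0.0) > intron_fraction * t_rpkm:
                passed_i.add(rec.intron_id)
                break
    return passed_t, passed_i


# ---------------------------------------------------------------------------
# retention index and fold changes


def retention_index(intron_rpkm: float, transcript_rpkm: float) -> float:
    """Intron RPKM divided by the transcript's exonic RPKM (same sample)."""
    if transcript_rpkm <= 0:
        raise ValueError("retention index undefined for transcript RPKM <= 0")
    return intron_rpkm / transcript_rpkm


def fold_retention_change(index_kd: float, index_ctrl: float, eps: float = 0.01) -> float:
    """(index_kd + eps) / (index_ctrl + eps); eps keeps fully spliced introns finite."""
    return (index_kd + eps) / (index_ctrl + eps)


def flag_affected(
    folds: Iterable[float], window: tuple[float, float] = (2.0, 10.0)
) -> bool:
    """True iff any knockdown's retention fold change lies within ``window``."""
    lo, hi = window
    return any(lo <= f <= hi for f in folds)


def retention_table(
    quants: Sequence[SampleQuant],
    annotation: GenomeAnnotation,
    introns: Sequence[IntronRecord],
    control_condition: str = "control",
    eps: float = 0.01,
    affected_window: tuple[float, float] = (2.0, 10.0),
    min_transcript_rpkm: float = 10.0,
    intron_fraction: float = 0.10,
    intron_filter_scope: str = "any",
    deduplicate: bool = True,
) -> pd.DataFrame:
    """Full per-intron result table over all samples.

    Applies the analysis filters, deduplicates isoform-shared introns
    (keeping the copy on the highest-expressed control transcript), computes
    per-condition retention indices (replicate-mean RPKM) and per-knockdown
    fold changes, and flags affected introns.  One row per analyzed intron.
    """
    from intronret.annotation_model import deduplicate_introns

    for q in quants:
        if q.transcript_rpkm is None:
            compute_rpkm(q, annotation, introns)

    passed_t, passed_i = apply_analysis_filters(
        quants, introns, control_condition, min_transcript_rpkm,
        intron_fraction, intron_filter_scope,
    )
    analyzed = [r for r in introns if r.intron_id in passed_i]
    if deduplicate:
        controls = [q for q in quants if q.condition == control_condition]
        rank = {
            tid: float(np.mean([q.transcript_rpkm.get(tid, 0.0) for q in controls]))
            for tid in passed_t
        }
        analyzed = deduplicate_introns(analyzed, rank)

    conditions = sorted({q.condition for q in quants})
    knockdowns = [c for c in conditions if c != control_condition]

    def mean_rpkm(condition: str, feature: str, key: str) -> float:
        reps = [q for q in quants if q.condition == condition]
        vals = [getattr(q, feature).get(key, 0.0) for q in reps]
        return float(np.mean(vals))

    rows = []
    for rec in analyzed:
        row: dict = {
            "intron_id": rec.intron_id,
            "transcript_id": rec.transcript_id,
            "gene_id": rec.gene_id,
            "chrom": rec.chrom,
            "start": rec.start,
            "end": rec.end,
            "strand": rec.strand,
            "ordinal": rec.ordinal,
            "length": rec.length,
        }
        indices = {}
        for cond in conditions:
            t_rpkm = mean_rpkm(cond, "transcript_rpkm", rec.transcript_id)
            i_rpkm = mean_rpkm(cond, "intron_rpkm", rec.intron_id)
            idx = retention_index(i_rpkm, t_rpkm) if t_rpkm > 0 else float("nan")
            indices[cond] = idx
            row[f"index_{cond}"] = idx
        folds = []
        for kd in knockdowns:
            fold = fold_retention_change(indices[kd], indices[control_condition], eps)
            row[f"fold_{kd}"] = fold
            folds.append(fold)
        row["affected"] = flag_affected(folds, affected_window)
        rows.append(row)
    return pd.DataFrame(rows)


def transcript_fold_table(
    quants: Sequence[SampleQuant],
    passed_transcripts: set[str],
    control_condition: str = "control",
    eps: float = 0.01,
) -> pd.DataFrame:
    """Per-transcript steady-state RPKM fold changes (knockdown over control).

    Uses the same pseudo-count rule as the intron fold changes.
    """
    conditions = sorted({q.condition for q in quants})
    knockdowns = [c for c in conditions if c != control_condition]
    rows = []
    for tid in sorted(passed_transcripts):
        row: dict = {"transcript_id": tid}
        means = {}
        for cond in conditions:
            reps = [q for q in quants if q.condition == cond]
            means[cond] = float(np.mean([q.transcript_rpkm.get(tid, 0.0) for q in reps]))
            row[f"rpkm_{cond}"] = means[cond]
        for kd in knockdowns:
            row[f"fold_{kd}"] = (means[kd] + eps) / (means[control_condition] + eps)
        rows.append(row)
    return pd.DataFrame(rows)
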