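"""Synthetic annotation, genome and read placements with planted truth.

The generator emulates a two-condition (control vs knockdown), replicated,
strand-specific bulk RNA-seq experiment over multi-exon genes: gene
structures are drawn from configurable exon/intron length distributions
(with controls to plant large > 2 kb and huge > 10 kb introns and to enrich
first-introns-before-a-large-second), every intron begins GT and ends AG,
poor-pY introns are synthesized with pyrimidine runs capped below the
scanner threshold while good-pY introns carry an embedded run inside the
last 50 nt.  Per intron, a true retention fraction r governs the expected
number of intron-overlapping fragments (proportional to abundance x r x
intron length); exonic fragments are proportional to abundance x exonic
length and are spliced across junctions.  Counts follow Poisson or
negative-binomial noise; placements are uniform within eligible regions.
Retention is modeled per intron independently rather than per pre-mRNA
molecule — a simplification that suffices for retention-index recovery.

Fixed seed implies byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from intronret.annotation_model import (
    GenomeAnnotation,
    IntronRecord,
    TranscriptModel,
    reverse_complement,
)
from intronret.group_stats import ALL_LABELS, GroupScheme, classify_table
from intronret.retention_quant import BLOCK_COLUMNS, SampleQuant
from intronret.sequence_features import SpliceRuleParams, has_py_tract

_BASES = np.array(list("ACGT"))
_PURINES = np.array(list("AG"))
_PYRIMIDINES = np.array(list("CT"))


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the standard conditions.

    ``depth`` is the expected number of fragments per sample.  ``p_*``
    probabilities control planting of large/huge introns;
    ``p_first_before_large`` is the per-gene probability (genes with >= 2
    introns) that the second intron is forced large, which populates the
    FIRST_BEFORE_LARGE_SECOND group.
    """

    seed: int = 0
    n_genes: int = 200
    chrom_name: str = "chrSim"
    gene_spacing: int = 300
    exon_count_min: int = 2
    exon_count_max: int = 8
    exon_len_min: int = 100
    exon_len_max: int = 400
    intron_len_min: int = 61
    intron_len_max: int = 800
    p_large_intron: float = 0.06
    large_intron_range: tuple[int, int] = (2001, 8000)
    p_huge_intron: float = 0.015
    huge_intron_range: tuple[int, int] = (10001, 16000)
    p_first_before_large: float = 0.25
    fraction_poor_py: float = 0.3
    abundance_sigma: float = 1.0
    retention_low: float = 0.02
    retention_high: float = 0.5
    conditions: tuple[str, ...] = ("control", "knockdown")
    replicates: int = 2
    depth: int = 1_000_000
    fragment_length: int = 100
    read_length: int = 50
    noise: str = "poisson"
    nb_dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.intron_len_min < 60:
            raise ValueError(
                "intron_len_min < 60 nt is infeasible: introns need GT..AG "
                "termini plus a 50-nt 3' window with controlled pY content"
            )
        if not 0.0 <= self.retention_low <= self.retention_high <= 1.0:
            raise ValueError("retention fractions must satisfy 0 <= low <= high <= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.noise not in ("poisson", "nb"):
            raise ValueError("noise must be 'poisson' or 'nb'")


@dataclass
class TruthTable:
    """Planted ground truth, keyed by intron_id / transcript_id.

    ``intron_truth`` columns: transcript_id, length, ordinal, py_good, one
    ``r_<condition>`` column per condition, and the boolean architecture
    labels.  ``transcript_truth`` columns: exonic_length and one
    ``abundance_<condition>`` per condition.
    """

    intron_truth: pd.DataFrame
    transcript_truth: pd.DataFrame

    def copy(self) -> "TruthTable":
        return TruthTable(self.intron_truth.copy(), self.transcript_truth.copy())

    def to_tsv(self, intron_path: str, transcript_path: str) -> None:
        self.intron_truth.to_csv(intron_path, sep="\t")
        self.transcript_truth.to_csv(transcript_path, sep="\t")


# ---------------------------------------------------------------------------
# sequence synthesis helpers


def _capped_py_seq(rng: np.random.Generator, n: int, cap: int = 4) -> list[str]:
    """Random ACGT sequence whose longest C/T run is at most ``cap``."""
    out: list[str] = []
    run = 0
    draws = rng.integers(0, 4, size=n)
    purine_draws = rng.integers(0, 2, size=n)
    for i in range(n):
        if run >= cap:
            base = _PURINES[purine_draws[i]]
        else:
            base = _BASES[draws[i]]
        run = run + 1 if base in ("C", "T") else 0
        out.append(base)
    return out


def _intron_sequence(rng: np.random.Generator, length: int, py_good: bool) -> str:
    body = _capped_py_seq(rng, length - 4)
    if py_good:
        # a 12-py run at [-40,-28) of the full intron: inside the last 50 nt
        run = _PYRIMIDINES[rng.integers(0, 2, size=12)]
        lo = length - 40 - 2  # body coordinates exclude the leading GT
        body[lo : lo + 12] = list(run)
    return "GT" + "".join(body) + "AG"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# annotation simulation


def simulate_annotation(
    config: SimulationConfig,
    scheme: GroupScheme | None = None,
    rule_params: SpliceRuleParams | None = None,
) -> tuple[GenomeAnnotation, dict[str, str], TruthTable]:
    """Draw gene structures, synthesize the genome, and record the truth."""
    scheme = scheme or GroupScheme()
    rule_params = rule_params or SpliceRuleParams()
    rng = np.random.default_rng(config.seed)

    chrom_parts: list[str] = []
    pos = 0
    transcripts: dict[str, TranscriptModel] = {}
    intron_meta: list[dict] = []
    records: list[IntronRecord] = []

    for g in range(config.n_genes):
        tid, gid = f"t{g:04d}", f"g{g:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exon_count_min, config.exon_count_max + 1))
        exon_lens = rng.integers(config.exon_len_min, config.exon_len_max + 1, n_exons)
        n_introns = n_exons - 1
        force_large_second = n_introns >= 2 and rng.random() < config.p_first_before_large

        intron_lens: list[int] = []
        for j in range(n_introns):
            if j == 1 and force_large_second:
                lo, hi = config.large_intron_range
                intron_lens.append(int(rng.integers(lo, hi + 1)))
                continue
            u = rng.random()
            if u < config.p_huge_intron:
                lo, hi = config.huge_intron_range
            elif u < config.p_huge_intron + config.p_large_intron:
                lo, hi = config.large_intron_range
            else:
                lo, hi = config.intron_len_min, config.intron_len_max
                intron_lens.append(
                    int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
                )
                continue
            intron_lens.append(int(rng.integers(lo, hi + 1)))

        py_good = [rng.random() >= config.fraction_poor_py for _ in range(n_introns)]

        # segments in transcript orientation
        segments: list[tuple[str, str]] = []
        for j in range(n_exons):
            segments.append(("exon", _random_seq(rng, int(exon_lens[j]))))
            if j < n_introns:
                segments.append(
                    ("intron", _intron_sequence(rng, intron_lens[j], py_good[j]))
                )
        if strand == "-":
            segments = [(kind, reverse_complement(seq)) for kind, seq in reversed(segments)]

        chrom_parts.append(_random_seq(rng, config.gene_spacing))
        pos += config.gene_spacing
        exons: list[tuple[int, int]] = []
        for kind, seq in segments:
            if kind == "exon":
                exons.append((pos, pos + len(seq)))
            chrom_parts.append(seq)
            pos += len(seq)

        transcripts[tid] = TranscriptModel(
            transcript_id=tid, gene_id=gid, chrom=config.chrom_name,
            strand=strand, exons=exons,
        )
        for j in range(n_introns):
            intron_meta.append(
                {"intron_id": f"{tid}.i{j + 1}", "transcript_id": tid,
                 "py_intended": py_good[j]}
            )

    chrom_parts.append(_random_seq(rng, config.gene_spacing))
    genome = {config.chrom_name: "".join(chrom_parts)}
    annotation = GenomeAnnotation(
        transcripts=transcripts,
        chrom_lengths={config.chrom_name: len(genome[config.chrom_name])},
        genome=genome,
    )

    records = annotation.all_introns(genome)
    py_status = {r.intron_id: has_py_tract(r, rule_params) for r in records}
    labels = classify_table(records, py_status, scheme)

    by_id = {r.intron_id: r for r in records}
    intron_truth = pd.DataFrame(
        {
            "transcript_id": [m["transcript_id"] for m in intron_meta],
            "length": [by_id[m["intron_id"]].length for m in intron_meta],
            "ordinal": [by_id[m["intron_id"]].ordinal for m in intron_meta],
            "py_good": [py_status[m["intron_id"]] for m in intron_meta],
        },
        index=pd.Index([m["intron_id"] for m in intron_meta], name="intron_id"),
    )
    r_vals = rng.uniform(config.retention_low, config.retention_high, len(intron_truth))
    for cond in config.conditions:
        intron_truth[f"r_{cond}"] = r_vals
    intron_truth = intron_truth.join(labels.astype(bool))

    abundances = rng.lognormal(0.0, config.abundance_sigma, len(transcripts))
    tids = sorted(transcripts)
    transcript_truth = pd.DataFrame(
        {"exonic_length": [transcripts[t].exonic_length for t in tids]},
        index=pd.Index(tids, name="transcript_id"),
    )
    for cond in config.conditions:
        transcript_truth[f"abundance_{cond}"] = abundances

    return annotation, genome, TruthTable(intron_truth, transcript_truth)


# ---------------------------------------------------------------------------
# planted effects


def plant_group_effect(
    truth: TruthTable,
    group_label: str,
    multiplier: float,
    condition: str = "knockdown",
) -> TruthTable:
    """Multiply the knockdown retention fraction of labeled introns (clip to 1)."""
    if group_label not in truth.intron_truth.columns:
        raise KeyError(f"unknown group label {group_label!r}")
    out = truth.copy()
    mask = out.intron_truth[group_label].astype(bool)
    col = f"r_{condition}"
    out.intron_truth.loc[mask, col] = np.clip(
        out.intron_truth.loc[mask, col] * multiplier, 0.0, 1.0
    )
    return out


def plant_transcript_effect(
    truth: TruthTable,
    transcript_ids: Sequence[str],
    multiplier: float,
    condition: str = "knockdown",
) -> TruthTable:
    """Multiply knockdown-condition abundance of selected transcripts."""
    out = truth.copy()
    col = f"abundance_{condition}"
    idx = out.transcript_truth.index.isin(set(transcript_ids))
    out.transcript_truth.loc[idx, col] = out.transcript_truth.loc[idx, col] * multiplier
    return out


# ---------------------------------------------------------------------------
# read / count simulation


def _sample_rng(config: SimulationConfig, condition: str, replicate: int, tag: int) -> np.random.Generator:
    cond_index = list(config.conditions).index(condition)
    return np.random.default_rng([config.seed, tag, cond_index, replicate])


def _expected_counts(
    annotation: GenomeAnnotation,
    truth: TruthTable,
    config: SimulationConfig,
    condition: str,
    introns: Sequence[IntronRecord],
) -> tuple[pd.Series, pd.Series]:
    """Expected fragments per transcript (exonic) and per intron."""
    tt = truth.transcript_truth
    it = truth.intron_truth
    ab = tt[f"abundance_{condition}"]
    w_t = ab * tt["exonic_length"]
    parent_ab = ab.reindex(it["transcript_id"]).to_numpy()
    w_i = pd.Series(
        parent_ab * it[f"r_{condition}"].to_numpy() * it["length"].to_numpy(),
        index=it.index,
    )
    total = w_t.sum() + w_i.sum()
    scale = config.depth / total
    return w_t * scale, w_i * scale


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, config: SimulationConfig) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if config.noise == "poisson":
        return rng.poisson(lam)
    shape = 1.0 / config.nb_dispersion
    mix = rng.gamma(shape, 1.0, size=lam.shape) / shape
    return rng.poisson(lam * mix)


def simulate_counts(
    annotation: GenomeAnnotation,
    truth: TruthTable,
    config: SimulationConfig,
    condition: str,
    replicate: int,
    introns: Sequence[IntronRecord] | None = None,
) -> SampleQuant:
    """Draw per-feature fragment counts directly, skipping read placement.

    This count-level path shares the expected-count model with
    :func:`simulate_reads` and is the appropriate scale for calibration
    studies that need hundreds of replicate simulations.
    """
    introns = introns if introns is not None else annotation.all_introns(genome=None)
    lam_t, lam_i = _expected_counts(annotation, truth, config, condition, introns)
    rng = _sample_rng(config, condition, replicate, tag=104729)
    c_t = _draw_counts(rng, lam_t.to_numpy(), config)
    c_i = _draw_counts(rng, lam_i.to_numpy(), config)
    library = int(c_t.sum() + c_i.sum())
    return SampleQuant(
        sample_id=f"{condition}_r{replicate}",
        condition=condition,
        replicate=replicate,
        library_size=library,
        transcript_counts=dict(zip(lam_t.index, (int(x) for x in c_t))),
        intron_counts=dict(zip(lam_i.index, (int(x) for x in c_i))),
    )


def _transcript_blocks(
    transcript: TranscriptModel, starts: np.ndarray, frag_len: int
) -> list[list[tuple[int, int]]]:
    """Map transcript-coordinate fragments to genomic block lists."""
    exons = transcript.exons_5to3()
    lens = np.array([e - s for s, e in exons])
    cum_end = np.cumsum(lens)
    cum_start = cum_end - lens
    out = []
    i1 = np.searchsorted(cum_end, starts, side="right")
    i2 = np.searchsorted(cum_end, starts + frag_len - 1, side="right")
    for s, a, b in zip(starts, i1, i2):
        blocks = []
        for j in range(a, b + 1):
            o1 = max(int(s), int(cum_start[j])) - int(cum_start[j])
            o2 = min(int(s) + frag_len, int(cum_end[j])) - int(cum_start[j])
            gs, ge = exons[j]
            if transcript.strand == "+":
                blocks.append((gs + o1, gs + o2))
            else:
                blocks.append((ge - o2, ge - o1))
        blocks.sort()
        out.append(blocks)
    return out


def simulate_reads(
    annotation: GenomeAnnotation,
    truth: TruthTable,
    config: SimulationConfig,
    condition: str,
    replicate: int,
    introns: Sequence[IntronRecord] | None = None,
) -> pd.DataFrame:
    """Generate strand-specific fragment placements for one sample.

    Returns a block table (:data:`~intronret.retention_quant.BLOCK_COLUMNS`):
    exonic fragments are spliced across exon junctions, intronic fragments
    lie entirely within their intron.  Fragment strand equals the
    transcript strand (strand-specific library).
    """
    introns = introns if introns is not None else annotation.all_introns(genome=None)
    lam_t, lam_i = _expected_counts(annotation, truth, config, condition, introns)
    rng = _sample_rng(config, condition, replicate, tag=7919)
    c_t = _draw_counts(rng, lam_t.to_numpy(), config)
    c_i = _draw_counts(rng, lam_i.to_numpy(), config)

    frag_ids: list[str] = []
    chroms: list[str] = []
    strands: list[str] = []
    starts_out: list[int] = []
    ends_out: list[int] = []
    block_idx: list[int] = []
    n_blocks_out: list[int] = []
    next_id = 0

    for tid, count in zip(lam_t.index, c_t):
        if count == 0:
            continue
        t = annotation.transcripts[tid]
        frag_len = min(config.fragment_length, t.exonic_length)
        starts = rng.integers(0, t.exonic_length - frag_len + 1, size=int(count))
        for blocks in _transcript_blocks(t, starts, frag_len):
            fid = f"f{next_id}"
            next_id += 1
            for k, (bs, be) in enumerate(blocks):
                frag_ids.append(fid)
                chroms.append(t.chrom)
                strands.append(t.strand)
                starts_out.append(bs)
                ends_out.append(be)
                block_idx.append(k)
                n_blocks_out.append(len(blocks))

    by_id = {r.intron_id: r for r in introns}
    for iid, count in zip(lam_i.index, c_i):
        if count == 0:
            continue
        rec = by_id[iid]
        frag_len = min(config.fragment_length, rec.length)
        starts = rng.integers(rec.start, rec.end - frag_len + 1, size=int(count))
        for s in starts:
            fid = f"f{next_id}"
            next_id += 1
            frag_ids.append(fid)
            chroms.append(rec.chrom)
            strands.append(rec.strand)
            starts_out.append(int(s))
            ends_out.append(int(s) + frag_len)
            block_idx.append(0)
            n_blocks_out.append(1)

    return pd.DataFrame(
        {
            "fragment_id": frag_ids,
            "chrom": chroms,
            "strand": strands,
            "start": starts_out,
            "end": ends_out,
            "block_index": block_idx,
            "n_blocks": n_blocks_out,
        },
        columns=BLOCK_COLUMNS,
    )


def write_fragments_sam(
    blocks: pd.DataFrame, chrom_lengths: dict[str, int], path: str
) -> None:
    """Write a block table as minimal single-end SAM (M/N CIGAR, no sequence)."""
    order = sorted(chrom_lengths)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in order:
            fh.write(f"@SQ\tSN:{name}\tLN:{chrom_lengths[name]}\n")
        for (fid, chrom, strand), group in blocks.groupby(
            ["fragment_id", "chrom", "strand"], sort=True
        ):
            g = group.sort_values("block_index")
            cigar = []
            prev_end = None
            for s, e in zip(g["start"], g["end"]):
                if prev_end is not None and s > prev_end:
                    cigar.append(f"{s - prev_end}N")
                cigar.append(f"{e - s}M")
                prev_end = e
            flag = 16 if strand == "-" else 0
            fh.write(
                f"{fid}\t{flag}\t{chrom}\t{int(g['start'].iloc[0]) + 1}\t60\t"
                f"{''.join(cigar)}\t*\t0\t0\t*\t*\n"
            )
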