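"""End-to-end pipeline: quantify -> filter -> retention -> classify -> test.

The inter-stage contract is TSV so every stage can also be run on its own
through the command line; a JSON manifest records package version, every
parameter, and input checksums for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from intronret import __version__
from intronret.annotation_model import GenomeAnnotation, load_annotation
from intronret.group_stats import (
    GroupScheme,
    classify_table,
    run_group_tests,
    transcript_intron_size_bins,
    transcript_level_test,
)
from intronret.retention_quant import (
    apply_analysis_filters,
    compute_rpkm,
    count_features,
    load_fragments_sam,
    load_fragments_tsv,
    retention_table,
    transcript_fold_table,
)
from intronret.sequence_features import SpliceRuleParams, has_py_tract

logger = logging.getLogger(__name__)


class DataError(RuntimeError):
    """Invalid or missing input data; maps to exit code 2 in the CLI."""


@dataclass
class RunConfig:
    """Paths and every threshold of a pipeline run (defaults as published)."""

    annotation: str = ""
    genome: str = ""
    samples: str = ""
    outdir: str = "results"
    control_condition: str = "control"
    stranded: bool = True
    min_transcript_rpkm: float = 10.0
    intron_fraction: float = 0.10
    intron_filter_scope: str = "any"
    eps: float = 0.01
    affected_window: tuple[float, float] = (2.0, 10.0)
    deduplicate: bool = True
    splice_rule: SpliceRuleParams = field(default_factory=SpliceRuleParams)
    group_scheme: GroupScheme = field(default_factory=GroupScheme)
    alternative: str = "two-sided"
    bh_adjust: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        rule = SpliceRuleParams(**raw.pop("splice_rule", {}))
        scheme = GroupScheme(**raw.pop("group_scheme", {}))
        window = tuple(raw.pop("affected_window", (2.0, 10.0)))
        return cls(splice_rule=rule, group_scheme=scheme, affected_window=window, **raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, condition, replicate, path."""
    if not Path(path).exists():
        raise DataError(f"sample sheet not found: {path}")
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "condition", "replicate", "path"}
    missing = required - set(sheet.columns)
    if missing:
        raise DataError(f"sample sheet {path} lacks columns: {sorted(missing)}")
    return sheet


def load_fragments(path: str) -> pd.DataFrame:
    if str(path).endswith((".sam", ".bam")):
        return load_fragments_sam(path)
    return load_fragments_tsv(path)


def quantify_samples(
    annotation: GenomeAnnotation, sheet: pd.DataFrame, config: RunConfig, introns
):
    quants = []
    for row in sheet.itertuples(index=False):
        frag_path = row.path
        if not Path(frag_path).exists():
            raise DataError(f"fragment file not found: {frag_path}")
        blocks = load_fragments(frag_path)
        q = count_features(
            blocks, annotation, introns, stranded=config.stranded,
            sample_id=row.sample_id, condition=row.condition,
            replicate=int(row.replicate),
        )
        compute_rpkm(q, annotation, introns)
        logger.info(
            "sample %s: %d fragments, %d exonic, %d intronic assignments",
            q.sample_id, q.library_size,
            sum(q.transcript_counts.values()), sum(q.intron_counts.values()),
        )
        quants.append(q)
    return quants


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; writes all result files into ``outdir``.

    Returns a dict of output paths plus the stage counts.  Any stage error
    aborts with a stage-tagged message.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for label, path in [("annotation", config.annotation), ("genome", config.genome)]:
        if not path or not Path(path).exists():
            raise DataError(f"[input] {label} file not found: {path!r}")

    try:
        annotation = load_annotation(config.annotation, config.genome)
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise DataError(f"[load] {exc}") from exc
    introns = annotation.all_introns()
    logger.info("loaded %d transcripts, %d introns", len(annotation.transcripts), len(introns))

    sheet = read_sample_sheet(config.samples)
    try:
        quants = quantify_samples(annotation, sheet, config, introns)
    except DataError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"[quantify] {exc}") from exc

    passed_t, passed_i = apply_analysis_filters(
        quants, introns, config.control_condition, config.min_transcript_rpkm,
        config.intron_fraction, config.intron_filter_scope,
    )
    logger.info(
        "filters: %d/%d transcripts, %d/%d introns analyzed",
        len(passed_t), len(annotation.transcripts), len(passed_i), len(introns),
    )

    table = retention_table(
        quants, annotation, introns,
        control_condition=config.control_condition, eps=config.eps,
        affected_window=config.affected_window,
        min_transcript_rpkm=config.min_transcript_rpkm,
        intron_fraction=config.intron_fraction,
        intron_filter_scope=config.intron_filter_scope,
        deduplicate=config.deduplicate,
    )
    logger.info("retention table: %d introns, %d affected", len(table),
                int(table["affected"].sum()) if len(table) else 0)

    analyzed = [r for r in introns if r.intron_id in set(table["intron_id"])]
    py_status = {r.intron_id: has_py_tract(r, config.splice_rule) for r in analyzed}
    labels = classify_table(analyzed, py_status, config.group_scheme)

    fold_cols = [c for c in table.columns if c.startswith("fold_")]
    knockdowns = [c.removeprefix("fold_") for c in fold_cols]
    group_results = {}
    for kd, col in zip(knockdowns, fold_cols):
        folds = table.set_index("intron_id")[col]
        group_results[kd] = run_group_tests(
            folds, labels, alternative=config.alternative, bh_adjust=config.bh_adjust
        ).assign(knockdown=kd)

    tfold = transcript_fold_table(quants, passed_t, config.control_condition, config.eps)
    max_intron = pd.Series(
        {r.transcript_id: 0 for r in introns}, dtype=float, name="max_intron"
    )
    for r in introns:
        max_intron[r.transcript_id] = max(max_intron[r.transcript_id], r.length)
    bins = transcript_intron_size_bins(max_intron.reindex(sorted(passed_t)))
    transcript_results = {}
    for kd in knockdowns:
        folds = tfold.set_index("transcript_id")[f"fold_{kd}"]
        transcript_results[kd] = transcript_level_test(
            folds, bins, alternative=config.alternative
        ).assign(knockdown=kd)

    # outputs
    paths = {
        "retention": outdir / "retention.tsv",
        "groups": outdir / "intron_groups.tsv",
        "group_tests": outdir / "group_tests.tsv",
        "group_tests_json": outdir / "group_tests.json",
        "transcript_folds": outdir / "transcript_folds.tsv",
        "transcript_bins": outdir / "transcript_bins.tsv",
        "transcript_tests": outdir / "transcript_tests.tsv",
        "manifest": outdir / "manifest.json",
    }
    table.to_csv(paths["retention"], sep="\t", index=False)
    labels.to_csv(paths["groups"], sep="\t")
    all_group = pd.concat(group_results.values(), ignore_index=True)
    all_group.to_csv(paths["group_tests"], sep="\t", index=False)
    with open(paths["group_tests_json"], "w") as fh:
        json.dump(
            {kd: frame.drop(columns="knockdown").to_dict(orient="records")
             for kd, frame in group_results.items()},
            fh, indent=2, default=float,
        )
    tfold.to_csv(paths["transcript_folds"], sep="\t", index=False)
    bins.rename_axis("transcript_id").to_frame().to_csv(paths["transcript_bins"], sep="\t")
    pd.concat(transcript_results.values(), ignore_index=True).to_csv(
        paths["transcript_tests"], sep="\t", index=False
    )

    manifest = {
        "package": "intronret",
        "version": __version__,
        "parameters": {
            **{k: v for k, v in asdict(config).items()
               if k not in ("splice_rule", "group_scheme")},
            "splice_rule": asdict(config.splice_rule),
            "group_scheme": asdict(config.group_scheme),
        },
        "inputs": {
            "annotation": {"path": config.annotation, "sha256": _sha256(config.annotation)},
            "genome": {"path": config.genome, "sha256": _sha256(config.genome)},
            "samples": {"path": config.samples, "sha256": _sha256(config.samples)},
        },
        "counts": {
            "transcripts_total": len(annotation.transcripts),
            "introns_total": len(introns),
            "transcripts_analyzed": len(passed_t),
            "introns_analyzed": len(passed_i),
            "introns_reported": len(table),
            "introns_affected": int(table["affected"].sum()) if len(table) else 0,
        },
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {"paths": {k: str(v) for k, v in paths.items()}, "counts": manifest["counts"]}
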