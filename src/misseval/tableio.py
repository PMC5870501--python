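"""Tab-separated variant tables and the end-to-end evaluation pipeline.

The native exchange format is a TSV with one header row and one variant
per row.  Declared columns::

    variant_id  gene  truth_class  product_of_lrs
    af_afr af_eas af_sas af_fin af_nfe af_amr
    spliceogenic  expert_override  family_count
    agvgd_class  sift_score  sift_label  mt2_label  pph2_label

Empty cells mean "missing"; unknown columns are preserved on round-trip.
Numbers use dot decimals regardless of locale.  Genomic coordinates are
deliberately out of scope — the pipeline's atoms are classified variants
with predictor outputs, not positions, so no VCF ingestion is offered.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .curation import (
    POPULATIONS,
    CurationResult,
    VariantRecord,
    build_classified_set,
    build_evaluation_set,
    set_composition,
    truth_call,
)
from .ensemble import ConsensusPartition, consensus_partition, evaluate_schemes
from .harmonize import BENIGN, PATHOGENIC, RAW_COLUMNS, TOOLS, harmonize_record
from .metrics import PerformanceReport, confusion, impact_counts, performance

__all__ = [
    "AF_COLUMNS",
    "COLUMNS",
    "RunConfig",
    "PipelineReport",
    "read_variant_table",
    "write_variant_table",
    "run_pipeline",
    "load_run_config",
]

AF_COLUMNS = {pop: f"af_{pop}" for pop in POPULATIONS}

_RAW_COLUMN_ORDER = [c for cols in RAW_COLUMNS.values() for c in cols]

COLUMNS = (
    ["variant_id", "gene", "truth_class", "product_of_lrs"]
    + list(AF_COLUMNS.values())
    + ["spliceogenic", "expert_override", "family_count"]
    + _RAW_COLUMN_ORDER
)

MANDATORY_COLUMNS = ("variant_id", "gene", "truth_class")

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_float(cell: str, column: str, row: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"row {row}: malformed number {cell!r} in column {column!r}") from None


def _parse_bool(cell: str, column: str, row: int) -> bool:
    if cell.strip().lower() not in _BOOL:
        raise ValueError(f"row {row}: malformed boolean {cell!r} in column {column!r}")
    return _BOOL[cell.strip().lower()]


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV into records.

    Raises on a missing mandatory column (naming it) and on malformed
    numerics (naming the row).  Raw predictor columns are kept verbatim in
    ``raw_calls`` except ``sift_score`` which is parsed numerically.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in MANDATORY_COLUMNS:
            if col not in header:
                raise ValueError(f"missing mandatory column {col!r} in {path}")
        records = []
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            afs = {
                pop: _parse_float(row[col], col, i)
                for pop, col in AF_COLUMNS.items()
                if row.get(col, "") != ""
            }
            raw: dict[str, object] = {}
            for col in _RAW_COLUMN_ORDER:
                cell = row.get(col, "")
                if cell == "":
                    continue
                raw[col] = _parse_float(cell, col, i) if col == "sift_score" else cell
            records.append(
                VariantRecord(
                    variant_id=row["variant_id"],
                    gene=row["gene"],
                    truth_class=(
                        None
                        if row["truth_class"] == ""
                        else int(_parse_float(row["truth_class"], "truth_class", i))
                    ),
                    product_of_lrs=(
                        None
                        if row.get("product_of_lrs", "") == ""
                        else _parse_float(row["product_of_lrs"], "product_of_lrs", i)
                    ),
                    population_afs=afs,
                    spliceogenic=_parse_bool(row.get("spliceogenic") or "false", "spliceogenic", i),
                    expert_override=_parse_bool(
                        row.get("expert_override") or "false", "expert_override", i
                    ),
                    family_count=int(_parse_float(row.get("family_count") or "0", "family_count", i)),
                    raw_calls=raw,
                )
            )
    return records


def _format_cell(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest round-tripping decimal
    return str(value)


def record_to_row(rec: VariantRecord) -> dict[str, str]:
    row = {
        "variant_id": rec.variant_id,
        "gene": rec.gene,
        "truth_class": _format_cell(rec.truth_class),
        "product_of_lrs": _format_cell(rec.product_of_lrs),
        "spliceogenic": _format_cell(rec.spliceogenic),
        "expert_override": _format_cell(rec.expert_override),
        "family_count": str(rec.family_count),
    }
    for pop, col in AF_COLUMNS.items():
        row[col] = (
            _format_cell(rec.population_afs[pop]) if pop in rec.population_afs else ""
        )
    for col in _RAW_COLUMN_ORDER:
        row[col] = _format_cell(rec.raw_calls.get(col))
    return row


def write_variant_table(
    records: list[VariantRecord],
    path: str | Path,
    extra_columns: dict[str, dict[str, str]] | None = None,
) -> None:
    """Write records as TSV; ``extra_columns`` maps column -> variant_id -> cell."""
    extra = extra_columns or {}
    header = COLUMNS + list(extra)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=header, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        for rec in records:
            row = record_to_row(rec)
            for col, mapping in extra.items():
                row[col] = mapping.get(rec.variant_id, "")
            writer.writerow(row)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    input_path: str | Path | None = None
    out_dir: str | Path | None = None
    priors: "PriorConfig" = None  # type: ignore[assignment]
    thresholds: "PlonThresholds" = None  # type: ignore[assignment]
    tools: tuple[str, ...] = TOOLS
    precision: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        from .multifactorial import PlonThresholds, PriorConfig

        if self.priors is None:
            self.priors = PriorConfig()
        if self.thresholds is None:
            self.thresholds = PlonThresholds()
        if self.precision < 0:
            raise ValueError("precision must be >= 0")


@dataclass
class PipelineReport:
    """Everything the evaluation pipeline produces in one pass."""

    curation: CurationResult
    composition: dict
    tool_metrics: dict[str, PerformanceReport]
    tool_confusions: dict[str, tuple[int, int, int, int]]
    tool_impact: dict[str, tuple[int, int]]
    ensemble_table: list[dict]
    consensus: ConsensusPartition | None
    n_incomplete_calls: int


def run_pipeline(
    config: RunConfig, records: list[VariantRecord] | None = None
) -> PipelineReport:
    """Curate, harmonize, evaluate stand-alone tools and ensembles.

    Deterministic given the input records and configuration.  Stage order:
    classified-set filters -> prior-independence screen -> harmonization ->
    per-tool metrics (pairwise-complete) -> ensemble evaluation and
    consensus partition (complete-case) -> family-weighted impact counts.
    """
    if records is None:
        if config.input_path is None:
            raise ValueError("run_pipeline needs records or an input path")
        records = read_variant_table(config.input_path)

    stage1 = build_classified_set(records)
    stage2 = build_evaluation_set(stage1.classified_set, config.priors, config.thresholds)
    curation = CurationResult(
        classified_set=stage1.classified_set,
        evaluation_set=stage2.evaluation_set,
        exclusion_log=stage1.exclusion_log + stage2.exclusion_log,
    )
    evaluation = curation.evaluation_set
    composition = set_composition(evaluation).per_gene if evaluation else {}

    calls_by_variant = {
        rec.variant_id: harmonize_record(rec.raw_calls) for rec in evaluation
    }
    truth = {rec.variant_id: truth_call(rec) for rec in evaluation}

    tool_metrics: dict[str, PerformanceReport] = {}
    tool_confusions: dict[str, tuple[int, int, int, int]] = {}
    tool_impact: dict[str, tuple[int, int]] = {}
    for tool in config.tools:
        pairs = [
            (truth[v], calls[tool])
            for v, calls in calls_by_variant.items()
            if calls[tool] in (PATHOGENIC, BENIGN)
        ]
        if not pairs:
            continue
        cm = confusion([t for t, _ in pairs], [c for _, c in pairs])
        tool_metrics[tool] = performance(cm)
        tool_confusions[tool] = (cm.tp, cm.fp, cm.tn, cm.fn)
        complete = [
            rec
            for rec in evaluation
            if calls_by_variant[rec.variant_id][tool] in (PATHOGENIC, BENIGN)
        ]
        tool_impact[tool] = impact_counts(
            complete, {r.variant_id: calls_by_variant[r.variant_id][tool] for r in complete}
        )

    complete_ids = {
        v
        for v, calls in calls_by_variant.items()
        if all(calls[t] in (PATHOGENIC, BENIGN) for t in config.tools)
    }
    n_incomplete = len(calls_by_variant) - len(complete_ids)
    ensemble_table = evaluate_schemes(
        truth, {v: calls_by_variant[v] for v in complete_ids}
    )
    consensus = (
        consensus_partition(
            {v: calls_by_variant[v] for v in complete_ids}, tools=config.tools
        )
        if complete_ids and config.tools == TOOLS
        else None
    )

    report = PipelineReport(
        curation=curation,
        composition=composition,
        tool_metrics=tool_metrics,
        tool_confusions=tool_confusions,
        tool_impact=tool_impact,
        ensemble_table=ensemble_table,
        consensus=consensus,
        n_incomplete_calls=n_incomplete,
    )
    if config.out_dir is not None:
        _write_report(report, Path(config.out_dir), config.precision)
    return report


def _write_report(report: PipelineReport, out_dir: Path, precision: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "tool_metrics.tsv", "w") as fh:
        fh.write("tool\ttp\tfp\ttn\tfn\tsens\tspec\tacc\tmcc\tfamilies_fn\tfamilies_fp\n")
        for tool, perf in report.tool_metrics.items():
            cm = report.tool_confusions[tool]
            r = perf.rounded(precision)
            fn_fam, fp_fam = report.tool_impact[tool]
            fh.write(
                f"{tool}\t" + "\t".join(map(str, cm)) + "\t"
                + "\t".join("" if r[k] is None else str(r[k]) for k in ("sens", "spec", "acc", "mcc"))
                + f"\t{fn_fam}\t{fp_fam}\n"
            )
    with open(out_dir / "ensemble.tsv", "w") as fh:
        if report.ensemble_table:
            cols = list(report.ensemble_table[0])
            fh.write("\t".join(cols) + "\n")
            for row in report.ensemble_table:
                fh.write("\t".join(_format_cell(row[c]) for c in cols) + "\n")
    with open(out_dir / "exclusions.tsv", "w") as fh:
        fh.write("variant_id\treason\n")
        for vid, reason in report.curation.exclusion_log:
            fh.write(f"{vid}\t{reason}\n")
    summary = {
        "n_classified": len(report.curation.classified_set),
        "n_evaluation": len(report.curation.evaluation_set),
        "composition": {g: list(c) for g, c in report.composition.items()},
        "n_incomplete_calls": report.n_incomplete_calls,
    }
    if report.consensus is not None:
        summary["consensus"] = {
            "concordant_benign": len(report.consensus.concordant_benign),
            "concordant_pathogenic": len(report.consensus.concordant_pathogenic),
            "discordant": len(report.consensus.discordant),
            "exclusive_pathogenic": report.consensus.exclusive_pathogenic,
            "exclusive_benign": report.consensus.exclusive_benign,
        }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def load_run_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML key-value file.

    Recognized keys: ``prior_low``, ``prior_high``, ``c1_upper``,
    ``c2_upper``, ``c4_lower``, ``c5_lower``, ``precision``, ``seed``,
    ``tools`` (list).
    """
    from .multifactorial import PlonThresholds, PriorConfig

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    priors = PriorConfig(
        prior_low=data.get("prior_low", 0.03),
        prior_high=data.get("prior_high", 0.81),
    )
    thresholds = PlonThresholds(
        c1_upper=data.get("c1_upper", 0.001),
        c2_upper=data.get("c2_upper", 0.05),
        c4_lower=data.get("c4_lower", 0.95),
        c5_lower=data.get("c5_lower", 0.99),
    )
    return RunConfig(
        priors=priors,
        thresholds=thresholds,
        tools=tuple(data.get("tools", TOOLS)),
        precision=data.get("precision", 2),
        seed=data.get("seed", 0),
    )
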