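"""End-to-end orchestration: cascade runs, the score benchmark, and simulation.

The benchmark mirrors the study layout: per tool and per comparison (positive
variant class vs the random common-variant background) it normalizes scores,
computes ROC/AUC and an MCC, summarizes per-category score distributions, runs
Mann-Whitney U tests of category 1 against categories 2-4, and compares the
AUC vectors of the two comparisons with a paired one-sided Bonferroni-corrected
t-test.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cascade as _cascade
from . import metrics as _metrics
from .cascade import CascadeAudit, CascadeConfig, ConfusionSummary
from .io import (
    GeneAnnotationMap,
    ToolScoreTable,
    TruthLabel,
    VariantRecord,
)
from .metrics import (
    DEFAULT_CONVENTIONS,
    ROC_TOOLS,
    GroupSummary,
    RocCurve,
    TestResult,
    ToolConvention,
)
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset, write_dataset

__all__ = [
    "ComparisonSpec",
    "DEFAULT_COMPARISONS",
    "MetricRow",
    "BenchmarkReport",
    "run_cascade",
    "run_benchmark",
    "run_simulate",
    "write_benchmark_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonSpec:
    """One positive-vs-negative group comparison over the score table."""

    label: str
    positive_groups: tuple[str, ...]
    negative_groups: tuple[str, ...]


#: The study's two comparisons: high-confidence (category 1, Type A enriched)
#: and low-confidence (categories 3+4 pooled, Type B enriched) variants, each
#: against the random common-variant background.
DEFAULT_COMPARISONS = (
    ComparisonSpec("TypeA_enriched", ("1",), ("random",)),
    ComparisonSpec("TypeB_enriched", ("3", "4"), ("random",)),
)


@dataclass
class MetricRow:
    """Benchmark result for one (tool, comparison); failures carry a reason."""

    tool: str
    comparison: str
    status: str = "ok"
    reason: str = ""
    auc: float | None = None
    mcc: float | None = None
    mcc_threshold: float | None = None
    n_pos: int = 0
    n_neg: int = 0
    n_missing: int = 0
    curve: RocCurve | None = None


@dataclass
class BenchmarkReport:
    metrics: list[MetricRow]
    summaries: list[GroupSummary]
    mwu_tests: dict[tuple[str, str], TestResult]
    auc_ttest: TestResult | None

    def row(self, tool: str, comparison: str) -> MetricRow:
        for r in self.metrics:
            if r.tool == tool and r.comparison == comparison:
                return r
        raise KeyError((tool, comparison))


# ---------------------------------------------------------------------------
# cascade command
# ---------------------------------------------------------------------------


def run_cascade(
    variants: Sequence[VariantRecord],
    genes: GeneAnnotationMap,
    clinvar: set[str],
    config: CascadeConfig = CascadeConfig(),
    truth: Sequence[TruthLabel] | None = None,
    outdir=None,
) -> tuple[CascadeAudit, ConfusionSummary | None]:
    """Run the cascade; optionally score against a truth set and write outputs."""
    audit = _cascade.apply_cascade(variants, genes, clinvar, config)
    summary = None
    if truth:
        summary = _cascade.evaluate_cascade(audit.flagged_rsids, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _cascade.write_audit(audit, outdir / "cascade_audit.tsv")
        _cascade.export_candidates(audit, variants, outdir / "candidates.tsv")
        if summary is not None:
            _cascade.write_confusion(summary, outdir / "confusion.tsv")
    return audit, summary


# ---------------------------------------------------------------------------
# benchmark command
# ---------------------------------------------------------------------------


def _comparison_sides(
    table: ToolScoreTable, spec: ComparisonSpec
) -> tuple[list[str], list[str]]:
    groups = table.groups
    pos = [r for r in table.rsids if groups.loc[r] in spec.positive_groups]
    pos_set = set(pos)
    neg_all = [r for r in table.rsids if groups.loc[r] in spec.negative_groups]
    neg = [r for r in neg_all if r not in pos_set]
    if len(neg) != len(neg_all):
        logger.info(
            "%s: excluded %d negative rsid(s) overlapping the positive set",
            spec.label, len(neg_all) - len(neg),
        )
    return pos, neg


def run_benchmark(
    table: ToolScoreTable,
    tools: Sequence[str] | None = None,
    comparisons: Sequence[ComparisonSpec] = DEFAULT_COMPARISONS,
    conventions: Mapping[str, ToolConvention] = DEFAULT_CONVENTIONS,
    mcc_mode: str = "best",
    outdir=None,
) -> BenchmarkReport:
    """Score every configured tool on every comparison.

    ``mcc_mode`` is ``"best"`` (maximum over the threshold sweep) or
    ``"fixed:<t>"`` for a fixed normalized-score cutoff.  A tool missing from
    the table or a comparison with an empty side is marked failed and the run
    continues.
    """
    tools = list(tools if tools is not None else ROC_TOOLS)
    fixed_threshold: float | None = None
    if mcc_mode != "best":
        if not mcc_mode.startswith("fixed:"):
            raise ValueError(f"mcc_mode must be 'best' or 'fixed:<t>', got {mcc_mode!r}")
        fixed_threshold = float(mcc_mode.split(":", 1)[1])

    rows: list[MetricRow] = []
    for spec in comparisons:
        pos_ids, neg_ids = _comparison_sides(table, spec)
        if pos_ids and neg_ids:
            # min/max reference for rescaled tools: union of the two sides,
            # recomputed per comparison
            normalized = _metrics.normalize_scores(
                table, conventions, reference=pos_ids + neg_ids
            )
        else:
            normalized = None
        for tool in tools:
            row = MetricRow(tool, spec.label)
            if tool not in table.tools:
                row.status, row.reason = "failed", "tool absent from score table"
                rows.append(row)
                continue
            if normalized is None:
                side = "positive" if not pos_ids else "negative"
                row.status, row.reason = "failed", f"empty {side} group"
                rows.append(row)
                continue
            pos = normalized.scores.loc[pos_ids, tool].to_numpy(dtype=float)
            neg = normalized.scores.loc[neg_ids, tool].to_numpy(dtype=float)
            row.n_missing = int(np.isnan(pos).sum() + np.isnan(neg).sum())
            pos, neg = pos[~np.isnan(pos)], neg[~np.isnan(neg)]
            if pos.size == 0 or neg.size == 0:
                side = "positive" if pos.size == 0 else "negative"
                row.status = "failed"
                row.reason = f"{side} side empty after dropping missing values"
                rows.append(row)
                continue
            row.n_pos, row.n_neg = int(pos.size), int(neg.size)
            row.curve = _metrics.roc_curve(pos, neg)
            row.auc = _metrics.auc(row.curve)
            if fixed_threshold is None:
                row.mcc_threshold, row.mcc = _metrics.mcc_best_threshold(pos, neg)
            else:
                row.mcc_threshold = fixed_threshold
                row.mcc = _metrics.mcc_at_threshold(pos, neg, fixed_threshold)
            logger.info(
                "%s / %s: AUC %.3f MCC %.3f (n_pos %d, n_neg %d, NA %d)",
                tool, spec.label, row.auc, row.mcc, row.n_pos, row.n_neg, row.n_missing,
            )
            rows.append(row)

    # per-category distribution summaries on raw scores
    summaries: list[GroupSummary] = []
    for tool in tools:
        if tool not in table.tools:
            continue
        for group in table.group_labels:
            summaries.append(_metrics.group_summary(table, tool, group, conventions))

    # Mann-Whitney U: category 1 vs each of 2, 3, 4 per tool (two-sided)
    mwu: dict[tuple[str, str], TestResult] = {}
    present_groups = set(table.group_labels)
    for tool in tools:
        if tool not in table.tools or "1" not in present_groups:
            continue
        for other in ("2", "3", "4"):
            if other not in present_groups:
                continue
            x = table.values(tool, "1")
            y = table.values(tool, other)
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
            if x.size == 0 or y.size == 0:
                continue
            mwu[(tool, other)] = _metrics.mann_whitney_u(x, y, sides="two")

    # paired one-sided t-test across the first two comparisons' AUC vectors
    ttest = None
    if len(comparisons) >= 2:
        a, b = [], []
        for tool in tools:
            try:
                ra = next(r for r in rows if r.tool == tool and r.comparison == comparisons[0].label)
                rb = next(r for r in rows if r.tool == tool and r.comparison == comparisons[1].label)
            except StopIteration:
                continue
            if ra.auc is not None and rb.auc is not None:
                a.append(ra.auc)
                b.append(rb.auc)
        if len(a) >= 2:
            ttest = _metrics.paired_one_sided_t_test(a, b, bonferroni_m=len(a))

    report = BenchmarkReport(rows, summaries, mwu, ttest)
    if outdir is not None:
        write_benchmark_report(report, outdir)
    return report


def write_benchmark_report(report: BenchmarkReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def fmt(x) -> str:
        return "NA" if x is None else f"{x:.6g}"

    with open(outdir / "metrics.tsv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tool", "comparison", "status", "auc", "mcc", "mcc_threshold",
                    "n_pos", "n_neg", "n_missing", "reason"])
        for r in report.metrics:
            w.writerow([r.tool, r.comparison, r.status, fmt(r.auc), fmt(r.mcc),
                        fmt(r.mcc_threshold), r.n_pos, r.n_neg, r.n_missing, r.reason])

    with open(outdir / "roc_points.tsv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tool", "comparison", "threshold", "fpr", "tpr"])
        for r in report.metrics:
            if r.curve is None:
                continue
            for t, (fpr, tpr) in zip(r.curve.thresholds, r.curve.points):
                w.writerow([r.tool, r.comparison, fmt(t), fmt(fpr), fmt(tpr)])

    with open(outdir / "summary.tsv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tool", "group", "n", "n_missing", "median", "q1", "q3", "bin_counts"])
        for s in report.summaries:
            bins = (
                ";".join(f"{k}={v}" for k, v in s.bin_counts.items())
                if s.bin_counts is not None
                else "NA"
            )
            w.writerow([s.tool, s.group, s.n, s.n_missing, fmt(s.median), fmt(s.q1),
                        fmt(s.q3), bins])

    with open(outdir / "tests.tsv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["test", "tool", "statistic", "p_raw", "p_corrected", "sides",
                    "correction", "n1", "n2"])
        for (tool, other), res in report.mwu_tests.items():
            w.writerow([f"mwu_cat1_vs_cat{other}", tool, fmt(res.statistic),
                        fmt(res.raw_p), fmt(res.p_value), res.sides, res.correction,
                        res.n1, res.n2])
        if report.auc_ttest is not None:
            res = report.auc_ttest
            w.writerow(["paired_t_auc", "all", fmt(res.statistic), fmt(res.raw_p),
                        fmt(res.p_value), res.sides, res.correction, res.n1, res.n2])


# ---------------------------------------------------------------------------
# simulate command
# ---------------------------------------------------------------------------


def _config_to_jsonable(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["n_per_category"] = {str(k): v for k, v in config.n_per_category.items()}
    return d


def config_from_manifest(manifest: Mapping) -> SyntheticConfig:
    """Rebuild a SyntheticConfig from a manifest written by :func:`run_simulate`."""
    from .synthetic import ClassProfile, ScoreDistribution

    cfg = dict(manifest["config"])
    cfg["n_per_category"] = {
        (int(k) if k.isdigit() else k): v for k, v in cfg["n_per_category"].items()
    }
    cfg["annotation_model"] = {
        k: ClassProfile(**v) for k, v in cfg["annotation_model"].items()
    }
    cfg["score_model"] = {
        tool: {
            cls: ScoreDistribution(
                sd["kind"], tuple(sd["params"]), tuple(sd["scale"]), sd["flip"]
            )
            for cls, sd in per_class.items()
        }
        for tool, per_class in cfg["score_model"].items()
    }
    return SyntheticConfig(**cfg)


def run_simulate(config: SyntheticConfig, outdir) -> SyntheticDataset:
    """Generate and serialize a dataset plus a manifest recording config+seed."""
    dataset = generate_dataset(config)
    paths = write_dataset(dataset, outdir)
    manifest = {"config": _config_to_jsonable(config), "files": paths}
    with open(Path(outdir) / "manifest.json", "w", encoding="utf-8") as fh:
        # insertion order is meaningful (it fixes RNG consumption order), so
        # keys are not sorted
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return dataset
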