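"""Five-step filter cascade enriching for off-target (Type B) pharmacogenetic variants.

Type B (idiosyncratic) adverse drug reactions are largely unrelated to a drug's
primary pharmacological action, so the variants behind them tend to sit outside
the drug's target and metabolic systems.  The cascade encodes that profile as
five successive annotation filters over gene-contextual variant records:

1. keep missense variants only (drop synonymous and non-coding);
2. keep variants annotated with a Toxicity/ADR effect for at least one drug;
3. drop variants that, for any drug carrying Toxicity/ADR, also carry an
   additional effect type (efficacy, dosage, ...) for that same drug —
   mixed-effect associations point to on-target (Type A) pharmacology;
4. drop variants in ADME genes (PharmaADME) or in genes annotated with an
   excluded GO term ("xenobiotic metabolic process", "transporter");
5. apply the ClinVar-presence rule (default: keep variants with a ClinVar entry).

Every step is audited: retained counts and surviving (rsid, gene) keys are
recorded so the full filter trajectory can be exported and inspected.

The truth-set arithmetic mirrors the enrichment bookkeeping used to validate
the scheme: with Type B as the positive class, precision is the Type B fraction
among flagged variants, prevalence the Type B fraction overall, and
fold-enrichment the ratio of the two after half-up rounding to two decimals
(reported to two significant figures), e.g. 5/8 and 9/30 give 0.63/0.30 = 2.1.
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

from .io import (
    TOXICITY,
    GeneAnnotation,
    GeneAnnotationMap,
    TruthLabel,
    VariantRecord,
    write_variant_annotations,
)

__all__ = [
    "CascadeConfig",
    "CascadeAudit",
    "ConfusionSummary",
    "apply_cascade",
    "evaluate_cascade",
    "export_candidates",
    "write_audit",
    "write_confusion",
]

logger = logging.getLogger(__name__)

DEFAULT_GO_EXCLUSION_TERMS = frozenset({"xenobiotic metabolic process", "transporter"})


@dataclass(frozen=True)
class CascadeConfig:
    """Tunable choices of the cascade.

    ``clinvar_rule`` selects which side of the ClinVar-presence split step 5
    keeps.  ``effect_grouping`` controls step 3: ``per_drug`` pools effect
    types for a given (rsid, drug) across gene-contextual records, while
    ``per_drug_gene`` evaluates each record's own drug annotations only.
    ``disabled_steps`` (1-based) is a testing hook for filter-ablation audits.
    """

    go_exclusion_terms: frozenset[str] = DEFAULT_GO_EXCLUSION_TERMS
    clinvar_rule: str = "keep_in_clinvar"
    effect_grouping: str = "per_drug"
    disabled_steps: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.go_exclusion_terms:
            raise ValueError("go_exclusion_terms must be non-empty")
        if self.clinvar_rule not in ("keep_in_clinvar", "keep_not_in_clinvar"):
            raise ValueError(f"unknown clinvar_rule {self.clinvar_rule!r}")
        if self.effect_grouping not in ("per_drug", "per_drug_gene"):
            raise ValueError(f"unknown effect_grouping {self.effect_grouping!r}")
        if not self.disabled_steps <= {1, 2, 3, 4, 5}:
            raise ValueError("disabled_steps must be a subset of {1..5}")


@dataclass(frozen=True)
class CascadeAudit:
    """Per-step audit trail of one cascade run.

    ``retained_counts`` holds six entries: the initial record count followed by
    the count after each of the five steps; ``retained_ids`` the corresponding
    surviving (rsid, gene) keys in input order.
    """

    step_names: tuple[str, ...]
    retained_counts: tuple[int, ...]
    retained_ids: tuple[tuple[tuple[str, str], ...], ...]
    config: CascadeConfig

    def __post_init__(self) -> None:
        if len(self.retained_counts) != len(self.step_names) + 1:
            raise ValueError("retained_counts must hold initial count plus one per step")
        for a, b in zip(self.retained_counts, self.retained_counts[1:]):
            if b > a:
                raise ValueError("retained counts must be non-increasing")
        for ids, n in zip(self.retained_ids, self.retained_counts):
            if len(ids) != n:
                raise ValueError("retained_ids lengths must match retained_counts")

    @property
    def survivors(self) -> tuple[tuple[str, str], ...]:
        return self.retained_ids[-1]

    @property
    def flagged_rsids(self) -> set[str]:
        return {rsid for rsid, _ in self.survivors}

    @property
    def final_count(self) -> int:
        return self.retained_counts[-1]


def _step_names(config: CascadeConfig) -> tuple[str, ...]:
    clinvar = (
        "require a ClinVar entry"
        if config.clinvar_rule == "keep_in_clinvar"
        else "require absence from ClinVar"
    )
    return (
        "exclude synonymous and non-coding variants",
        "require a Toxicity/ADR effect type",
        "exclude variants with additional effect types for the same drug",
        "exclude ADME genes and GO-excluded genes",
        clinvar,
    )


def apply_cascade(
    variants: Sequence[VariantRecord],
    genes: GeneAnnotationMap | Mapping[str, GeneAnnotation],
    clinvar: set[str],
    config: CascadeConfig = CascadeConfig(),
) -> CascadeAudit:
    """Run the five filters over ``variants`` and return the full audit trail.

    Genes absent from ``genes`` are treated as non-ADME with no GO terms
    (logged at warning level), never an error.
    """
    if not isinstance(genes, GeneAnnotationMap):
        genes = GeneAnnotationMap(genes.values())
    excl_terms = {t.lower() for t in config.go_exclusion_terms}

    # step-3 context: pooled effect types per (rsid, drug) across gene records
    pooled: dict[tuple[str, str], set[str]] = {}
    if config.effect_grouping == "per_drug":
        for rec in variants:
            for de in rec.drug_effects:
                pooled.setdefault((rec.rsid, de.drug), set()).update(de.effect_types)

    def effects_of(rec: VariantRecord, drug: str) -> frozenset[str]:
        if config.effect_grouping == "per_drug":
            return frozenset(pooled[(rec.rsid, drug)])
        return rec.effects_for(drug)

    def keep_missense(rec: VariantRecord) -> bool:
        return rec.consequence == "missense"

    def keep_toxicity(rec: VariantRecord) -> bool:
        return rec.has_effect_type(TOXICITY)

    def keep_toxicity_only(rec: VariantRecord) -> bool:
        for de in rec.drug_effects:
            grouped = effects_of(rec, de.drug)
            if TOXICITY in grouped and grouped - {TOXICITY}:
                return False
        return True

    unknown_genes: set[str] = set()

    def keep_non_adme(rec: VariantRecord) -> bool:
        if rec.gene not in genes:
            unknown_genes.add(rec.gene)
        ann = genes.get(rec.gene)
        if ann.is_adme:
            return False
        return not ({t.lower() for t in ann.go_terms} & excl_terms)

    def keep_clinvar(rec: VariantRecord) -> bool:
        present = rec.rsid in clinvar
        return present if config.clinvar_rule == "keep_in_clinvar" else not present

    steps = (keep_missense, keep_toxicity, keep_toxicity_only, keep_non_adme, keep_clinvar)

    current = list(variants)
    counts = [len(current)]
    ids = [tuple(rec.key for rec in current)]
    for number, predicate in enumerate(steps, start=1):
        if number not in config.disabled_steps:
            current = [rec for rec in current if predicate(rec)]
        counts.append(len(current))
        ids.append(tuple(rec.key for rec in current))
    if unknown_genes:
        logger.warning(
            "%d gene(s) missing from annotation map, treated as non-ADME with no GO terms: %s",
            len(unknown_genes),
            ", ".join(sorted(unknown_genes)),
        )
    for name, n in zip(_step_names(config), counts[1:]):
        logger.info("cascade step %-55s retained %d", name, n)
    return CascadeAudit(_step_names(config), tuple(counts), tuple(ids), config)


# ---------------------------------------------------------------------------
# truth-set evaluation
# ---------------------------------------------------------------------------


def _half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _two_sig_figs(x: float) -> float:
    return float(f"{x:.2g}")


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts for Type B detection, with the enrichment arithmetic.

    Type B is the positive class.  ``precision`` (TP over flagged) and
    ``prevalence`` (positives over total) drive ``fold_enrichment``, computed
    as the ratio of the two after half-up rounding to two decimals and
    reported to two significant figures.  Degenerate ratios (nothing flagged,
    no positives) are ``None``, never zero.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def precision(self) -> float | None:
        return self.tp / self.n_flagged if self.n_flagged else None

    @property
    def prevalence(self) -> float | None:
        return self.n_positive / self.n_total if self.n_total else None

    @property
    def sensitivity(self) -> float | None:
        return self.tp / self.n_positive if self.n_positive else None

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        return self.tn / denom if denom else None

    @property
    def fold_enrichment(self) -> float | None:
        if self.precision is None or not self.prevalence:
            return None
        prev = _half_up(self.prevalence, 2)
        if prev == 0:
            return None
        return _two_sig_figs(_half_up(self.precision, 2) / prev)


def evaluate_cascade(flagged: set[str], truth: Sequence[TruthLabel]) -> ConfusionSummary:
    """Score a flagged rsid set against the Type A/B truth labels.

    Every flagged rsid must appear in the truth set; ``truth`` must be
    non-empty.
    """
    if not truth:
        raise ValueError("truth set must be non-empty")
    by_rsid = {t.rsid: t.label for t in truth}
    for rsid in sorted(flagged):
        if rsid not in by_rsid:
            raise ValueError(f"flagged rsid {rsid!r} absent from truth set")
    tp = sum(1 for r in flagged if by_rsid[r] == "TypeB")
    fp = len(flagged) - tp
    fn = sum(1 for r, lab in by_rsid.items() if lab == "TypeB" and r not in flagged)
    tn = len(by_rsid) - tp - fp - fn
    return ConfusionSummary(tp, fp, fn, tn)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def export_candidates(audit: CascadeAudit, variants: Sequence[VariantRecord], path) -> None:
    """Write the final survivors with all their annotations (candidate Type B table)."""
    by_key = {rec.key: rec for rec in variants}
    missing = [key for key in audit.survivors if key not in by_key]
    if missing:
        raise ValueError(f"audit survivors not present in variants: {missing[:3]!r}")
    write_variant_annotations([by_key[key] for key in audit.survivors], path)


def write_audit(audit: CascadeAudit, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["step", "filter", "retained_count"])
        writer.writerow(["0", "input", str(audit.retained_counts[0])])
        for i, (name, n) in enumerate(zip(audit.step_names, audit.retained_counts[1:]), 1):
            writer.writerow([str(i), name, str(n)])


def _fmt(x: float | None) -> str:
    return "NA" if x is None else repr(round(x, 6))


def write_confusion(summary: ConfusionSummary, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["tp", "fp", "fn", "tn", "n_total", "n_flagged", "n_positive",
             "precision", "prevalence", "sensitivity", "specificity", "fold_enrichment"]
        )
        writer.writerow(
            [summary.tp, summary.fp, summary.fn, summary.tn, summary.n_total,
             summary.n_flagged, summary.n_positive, _fmt(summary.precision),
             _fmt(summary.prevalence), _fmt(summary.sensitivity),
             _fmt(summary.specificity), _fmt(summary.fold_enrichment)]
        )
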