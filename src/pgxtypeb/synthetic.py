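"""Synthetic PharmGKB-like datasets with planted Type A / Type B structure.

The generator emulates the statistical shape the analysis assumes, so every
pipeline stage is testable without any database download:

* variant records carry a consequence, a major evidence category (1-4), and
  per-drug effect-type annotations;
* a latent Type A / Type B label controls the annotation profile — planted
  Type B variants tend to be missense, Toxicity/ADR-only, outside ADME and
  GO-excluded genes and present in ClinVar, so the filter cascade can recover
  them at configurable rates;
* per-tool scores are drawn from class-conditional distributions (Type A high,
  Type B and random background low on the damaging scale), with independent
  per-cell missingness;
* :func:`generate_binormal_scores` draws positive/negative samples from the
  binormal model N(delta, 1) vs N(0, 1) with delta = sqrt(2) * Phi^-1(AUC), so
  the expected AUC is known exactly and AUC machinery can be calibration-tested.

All generators are pure functions of (config, seed): the same seed reproduces
byte-identical serialized output.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import (
    DEFAULT_TOOLS,
    TOXICITY,
    DrugEffect,
    GeneAnnotation,
    GeneAnnotationMap,
    ToolScoreTable,
    TruthLabel,
    VariantRecord,
    write_clinvar_set,
    write_gene_annotations,
    write_score_table,
    write_truth_set,
    write_variant_annotations,
)

__all__ = [
    "ClassProfile",
    "ScoreDistribution",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_binormal_scores",
    "generate_cascade_fixture",
    "default_score_model",
    "write_dataset",
]


@dataclass(frozen=True)
class ClassProfile:
    """Per-class annotation probabilities driving cascade behavior.

    ``p_missense``: probability the variant is missense (else synonymous or
    non-coding, split evenly).  ``p_toxicity``: probability of a Toxicity/ADR
    effect annotation.  ``p_extra_effect``: given toxicity, probability the
    same drug also carries another effect type.  ``p_adme`` / ``p_go_hit``:
    probabilities the host gene is PharmaADME or carries an excluded GO term.
    ``p_clinvar``: probability of a ClinVar entry.
    """

    p_missense: float
    p_toxicity: float
    p_extra_effect: float
    p_adme: float
    p_go_hit: float
    p_clinvar: float

    def __post_init__(self) -> None:
        for name in ("p_missense", "p_toxicity", "p_extra_effect", "p_adme", "p_go_hit", "p_clinvar"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")

    @property
    def cascade_pass_probability(self) -> float:
        """Expected probability that a variant with this profile survives all
        five filters under the default cascade config."""
        return (
            self.p_missense
            * self.p_toxicity
            * (1 - self.p_extra_effect)
            * (1 - self.p_adme)
            * (1 - self.p_go_hit)
            * self.p_clinvar
        )


# Defaults echo the truth-set experiment: Type B variants survive the cascade at
# roughly 5/9 and Type A leak through at roughly 3/21.
DEFAULT_PROFILES: Mapping[str, ClassProfile] = {
    "TypeA": ClassProfile(0.85, 0.6, 0.5, 0.4, 0.2, 0.7),
    "TypeB": ClassProfile(1.0, 1.0, 0.25, 0.1, 0.05, 0.85),
}


@dataclass(frozen=True)
class ScoreDistribution:
    """Beta or normal draw, affinely mapped onto a tool's native scale.

    ``flip`` mirrors the draw (x -> 1 - x before scaling) for tools where low
    raw scores mean damaging (SIFT).
    """

    kind: str
    params: tuple[float, float]
    scale: tuple[float, float] = (0.0, 1.0)
    flip: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "normal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "beta":
            x = rng.beta(*self.params, size=n)
        else:
            x = rng.normal(*self.params, size=n)
        if self.flip:
            x = 1.0 - x
        lo, hi = self.scale
        return lo + x * (hi - lo)


_DAMAGING = (8.0, 2.0)
_BENIGN = (2.0, 8.0)

# native scales for tools that do not emit unit-range scores
_TOOL_SCALES: Mapping[str, tuple[float, float]] = {
    "CADD": (0.0, 50.0),
    "MutationAssessor": (-5.0, 6.0),
    "GERP++": (-12.0, 6.0),
}


def default_score_model(tools: list[str] | None = None) -> dict[str, dict[str, ScoreDistribution]]:
    """Class-conditional score model: Type A variants score damaging
    (Beta(8, 2) on the unit scale), Type B and the random background score
    benign (Beta(2, 8)), mapped onto each tool's native scale and direction."""
    model: dict[str, dict[str, ScoreDistribution]] = {}
    for tool in tools if tools is not None else DEFAULT_TOOLS:
        scale = _TOOL_SCALES.get(tool, (0.0, 1.0))
        flip = tool == "SIFT"
        model[tool] = {
            "TypeA": ScoreDistribution("beta", _DAMAGING, scale, flip),
            "TypeB": ScoreDistribution("beta", _BENIGN, scale, flip),
            "random": ScoreDistribution("beta", _BENIGN, scale, flip),
        }
    return model


# Category sizes follow the study's composition: 561 PharmGKB missense variants
# (119 category 1, 183 category 2; the unreported 3/4 split is taken as even)
# and 2155 random common variants.
DEFAULT_N_PER_CATEGORY: Mapping[str | int, int] = {1: 119, 2: 183, 3: 130, 4: 129, "random": 2155}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic dataset; ``seed`` is mandatory."""

    seed: int
    n_per_category: Mapping[str | int, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_CATEGORY)
    )
    typeb_prevalence: float = 0.3
    annotation_model: Mapping[str, ClassProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    score_model: Mapping[str, Mapping[str, ScoreDistribution]] = field(
        default_factory=default_score_model
    )
    missing_rate: float = 0.05
    count_exact: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if not 0.0 <= self.typeb_prevalence <= 1.0:
            raise ValueError("typeb_prevalence must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if any(n < 0 for n in self.n_per_category.values()):
            raise ValueError("n_per_category counts must be >= 0")

    @property
    def tools(self) -> list[str]:
        return list(self.score_model)


@dataclass
class SyntheticDataset:
    """A complete generated dataset in the package's own data model."""

    variants: list[VariantRecord]
    gene_annotations: GeneAnnotationMap
    clinvar_set: set[str]
    truth_labels: list[TruthLabel]
    score_table: ToolScoreTable


_EXTRA_EFFECTS = ("Efficacy", "Dosage", "Metabolism/PK", "Other")


def _make_variant(
    i: int,
    category: int,
    label: str,
    profile: ClassProfile,
    rng: np.random.Generator,
) -> tuple[VariantRecord, GeneAnnotation, bool]:
    rsid = f"rs{1000000 + i}"
    gene = f"GENE{i:05d}"
    if rng.random() < profile.p_missense:
        consequence = "missense"
    else:
        consequence = "synonymous" if rng.random() < 0.5 else "noncoding"
    drug = f"drug{i}"
    if rng.random() < profile.p_toxicity:
        effects = {TOXICITY}
        if rng.random() < profile.p_extra_effect:
            effects.add(str(rng.choice(_EXTRA_EFFECTS)))
    else:
        effects = {str(rng.choice(_EXTRA_EFFECTS))}
    record = VariantRecord(
        rsid, gene, consequence, category, (DrugEffect(drug, frozenset(effects)),)
    )
    is_adme = rng.random() < profile.p_adme
    go_terms = frozenset({"transporter"}) if rng.random() < profile.p_go_hit else frozenset()
    in_clinvar = rng.random() < profile.p_clinvar
    return record, GeneAnnotation(gene, is_adme, go_terms), in_clinvar


def _typeb_count(n: int, prevalence: float, count_exact: bool, rng: np.random.Generator) -> int:
    if count_exact:
        return int(round(n * prevalence))
    return int(rng.binomial(n, prevalence))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full dataset; deterministic given ``config.seed``.

    Categories 1-4 receive planted Type B labels at ``typeb_prevalence``
    (rounded expectation per category in count-exact mode).  The random group
    models the common-variant background and is labelled Type A throughout.
    """
    rng = np.random.default_rng(config.seed)
    variants: list[VariantRecord] = []
    annotations: list[GeneAnnotation] = []
    clinvar: set[str] = set()
    truth: list[TruthLabel] = []
    rsids: list[str] = []
    groups: list[str] = []
    classes: list[str] = []

    i = 0
    for category in (1, 2, 3, 4):
        n = int(config.n_per_category.get(category, 0))
        n_typeb = _typeb_count(n, config.typeb_prevalence, config.count_exact, rng)
        labels = np.array(["TypeB"] * n_typeb + ["TypeA"] * (n - n_typeb))
        rng.shuffle(labels)
        for label in labels:
            label = str(label)
            rec, ann, in_clinvar = _make_variant(
                i, category, label, config.annotation_model[label], rng
            )
            variants.append(rec)
            annotations.append(ann)
            if in_clinvar:
                clinvar.add(rec.rsid)
            truth.append(TruthLabel(rec.rsid, label, "synthetic planted label"))
            rsids.append(rec.rsid)
            groups.append(str(category))
            classes.append(label)
            i += 1
    n_random = int(config.n_per_category.get("random", 0))
    for _ in range(n_random):
        rsid = f"rs{1000000 + i}"
        truth.append(TruthLabel(rsid, "TypeA", "synthetic common background variant"))
        rsids.append(rsid)
        groups.append("random")
        classes.append("random")
        i += 1

    tools = config.tools
    data = np.empty((len(rsids), len(tools)))
    cls = np.array(classes)
    for j, tool in enumerate(tools):
        col = np.empty(len(rsids))
        for class_name in ("TypeA", "TypeB", "random"):
            mask = cls == class_name
            if mask.any():
                col[mask] = config.score_model[tool][class_name].draw(rng, int(mask.sum()))
        if config.missing_rate > 0:
            col[rng.random(len(rsids)) < config.missing_rate] = np.nan
        data[:, j] = col
    scores = pd.DataFrame(data, index=pd.Index(rsids, name="rsid"), columns=tools)
    table = ToolScoreTable(tools, scores, pd.Series(groups, index=scores.index, name="group"))
    return SyntheticDataset(variants, GeneAnnotationMap(annotations), clinvar, truth, table)


def generate_binormal_scores(
    target_auc: float, n_pos: int, n_neg: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw positives ~ N(delta, 1) and negatives ~ N(0, 1) with
    delta = sqrt(2) * Phi^-1(target_auc), so E[AUC] = target_auc exactly."""
    if not 0.5 < target_auc < 1.0:
        raise ValueError(f"target_auc must be in (0.5, 1), got {target_auc!r}")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    delta = binormal_delta(target_auc)
    rng = np.random.default_rng(seed)
    return rng.normal(delta, 1.0, n_pos), rng.normal(0.0, 1.0, n_neg)


def binormal_delta(target_auc: float) -> float:
    """Mean separation of the equal-variance binormal model with the given AUC."""
    return float(np.sqrt(2.0) * norm.ppf(target_auc))


def generate_cascade_fixture(
    n: int,
    planted_typeb: int,
    seed: int,
    leak_prob: float = 0.0,
) -> SyntheticDataset:
    """Truth-set-style fixture with construction-guaranteed cascade behavior.

    Planted Type B variants satisfy every filter (missense, Toxicity/ADR-only,
    non-ADME gene without excluded GO terms, ClinVar-present).  Each Type A
    variant leaks through all filters with probability ``leak_prob`` and
    otherwise violates exactly one uniformly chosen filter, so expected cascade
    precision is planted / (planted + leaked).
    """
    if not 0 <= planted_typeb <= n:
        raise ValueError("need 0 <= planted_typeb <= n")
    if not 0.0 <= leak_prob <= 1.0:
        raise ValueError("leak_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = np.array(["TypeB"] * planted_typeb + ["TypeA"] * (n - planted_typeb))
    rng.shuffle(labels)

    variants: list[VariantRecord] = []
    annotations: list[GeneAnnotation] = []
    clinvar: set[str] = set()
    truth: list[TruthLabel] = []
    for i, label in enumerate(str(x) for x in labels):
        rsid = f"rs{2000000 + i}"
        gene = f"FXGENE{i:05d}"
        drug = f"drug{i}"
        consequence = "missense"
        effects = {TOXICITY}
        is_adme = False
        go_terms: frozenset[str] = frozenset()
        in_clinvar = True
        if label == "TypeA" and rng.random() >= leak_prob:
            violated = int(rng.integers(1, 6))
            if violated == 1:
                consequence = "synonymous"
            elif violated == 2:
                effects = {"Efficacy"}
            elif violated == 3:
                effects = {TOXICITY, "Efficacy"}
            elif violated == 4:
                if rng.random() < 0.5:
                    is_adme = True
                else:
                    go_terms = frozenset({"xenobiotic metabolic process"})
            else:
                in_clinvar = False
        variants.append(
            VariantRecord(rsid, gene, consequence, int(rng.integers(1, 3)),
                          (DrugEffect(drug, frozenset(effects)),))
        )
        annotations.append(GeneAnnotation(gene, is_adme, go_terms))
        if in_clinvar:
            clinvar.add(rsid)
        truth.append(TruthLabel(rsid, label, "synthetic cascade fixture"))

    model = default_score_model()
    tools = list(model)
    cls = np.array([t.label for t in truth])
    data = np.empty((n, len(tools)))
    for j, tool in enumerate(tools):
        for class_name in ("TypeA", "TypeB"):
            mask = cls == class_name
            if mask.any():
                data[mask, j] = model[tool][class_name].draw(rng, int(mask.sum()))
    rsid_index = pd.Index([v.rsid for v in variants], name="rsid")
    table = ToolScoreTable(
        tools,
        pd.DataFrame(data, index=rsid_index, columns=tools),
        pd.Series([str(v.evidence_category) for v in variants], index=rsid_index, name="group"),
    )
    return SyntheticDataset(variants, GeneAnnotationMap(annotations), clinvar, truth, table)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Serialize a dataset through the standard writers; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": outdir / "variants.tsv",
        "scores": outdir / "scores.tsv",
        "adme": outdir / "adme_genes.txt",
        "go": outdir / "go_terms.tsv",
        "clinvar": outdir / "clinvar_rsids.txt",
        "truth": outdir / "truth_labels.tsv",
    }
    write_variant_annotations(dataset.variants, paths["variants"])
    write_score_table(dataset.score_table, paths["scores"])
    write_gene_annotations(dataset.gene_annotations, paths["adme"], paths["go"])
    write_clinvar_set(dataset.clinvar_set, paths["clinvar"])
    write_truth_set(dataset.truth_labels, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
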