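"""Score conventions and the statistical layer of the benchmark.

Raw predictor outputs use heterogeneous conventions: most tools emit a unit-range
score with higher meaning more damaging, SIFT runs the other way (0 most
damaging), and CADD (Phred scale) and Mutation Assessor use open positive/mixed
ranges.  :func:`normalize_scores` maps everything onto a common
"higher = more damaging, range [0, 1]" scale: SIFT is inverted (s -> 1 - s),
CADD and Mutation Assessor are min-max rescaled over a stated reference row set,
and everything else is clipped to the unit interval.

On the normalized scale the module provides ROC curves with trapezoidal AUC
(equal to the concordance probability P(X > Y) + 0.5 P(X = Y)), the Matthews
correlation coefficient with a best-threshold sweep, Mann-Whitney U rank tests
(exact for small tie-free samples), and the paired one-sided t-test used to
compare AUC sets across variant classes.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ToolScoreTable

__all__ = [
    "Bin",
    "ToolConvention",
    "DEFAULT_CONVENTIONS",
    "ROC_TOOLS",
    "RocCurve",
    "TestResult",
    "normalize_scores",
    "polyphen2_bin",
    "cadd_phred_to_rank_fraction",
    "roc_curve",
    "auc",
    "auc_scores",
    "mcc",
    "mcc_at_threshold",
    "mcc_best_threshold",
    "mann_whitney_u",
    "paired_one_sided_t_test",
    "GroupSummary",
    "group_summary",
]


@dataclass(frozen=True)
class Bin:
    """Half-open (or closed) interval with a categorical label on the unit scale."""

    label: str
    lower: float
    upper: float
    lower_closed: bool = True
    upper_closed: bool = False

    def contains(self, x: float) -> bool:
        lo = x >= self.lower if self.lower_closed else x > self.lower
        hi = x <= self.upper if self.upper_closed else x < self.upper
        return lo and hi


POLYPHEN2_BINS = (
    Bin("benign", 0.0, 0.15),
    Bin("possibly damaging", 0.15, 0.85),
    Bin("probably damaging", 0.85, 1.0, upper_closed=True),
)


@dataclass(frozen=True)
class ToolConvention:
    """How one tool's raw scores map to the common damaging-is-high unit scale."""

    tool: str
    direction: str = "higher_is_damaging"
    scaling: str = "identity"
    native_range: tuple[float, float] | None = None
    bins: tuple[Bin, ...] | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("higher_is_damaging", "lower_is_damaging"):
            raise ValueError(f"{self.tool}: unknown direction {self.direction!r}")
        if self.scaling not in ("identity", "invert_unit", "minmax"):
            raise ValueError(f"{self.tool}: unknown scaling {self.scaling!r}")


#: Conventions for the eleven benchmarked tools.  Only SIFT is inverted and only
#: CADD and Mutation Assessor are min-max rescaled; the rest are identity tools
#: clipped to [0, 1].
DEFAULT_CONVENTIONS: Mapping[str, ToolConvention] = {
    "SIFT": ToolConvention("SIFT", "lower_is_damaging", "invert_unit", (0.0, 1.0)),
    "PolyPhen2": ToolConvention("PolyPhen2", native_range=(0.0, 1.0), bins=POLYPHEN2_BINS),
    "CADD": ToolConvention("CADD", scaling="minmax"),
    "DANN": ToolConvention("DANN", native_range=(0.0, 1.0)),
    "FATHMM": ToolConvention("FATHMM", native_range=(0.0, 1.0)),
    "GERP++": ToolConvention("GERP++", native_range=(0.0, 1.0)),
    "MutPred": ToolConvention("MutPred", native_range=(0.0, 1.0)),
    "MutationAssessor": ToolConvention("MutationAssessor", scaling="minmax"),
    "MutationTaster": ToolConvention("MutationTaster", native_range=(0.0, 1.0)),
    "REVEL": ToolConvention("REVEL", native_range=(0.0, 1.0)),
    "PhastCons": ToolConvention("PhastCons", native_range=(0.0, 1.0)),
}

#: The most widely used subset, benchmarked with ROC curves.
ROC_TOOLS = ["CADD", "PolyPhen2", "SIFT", "MutationAssessor", "MutPred", "REVEL"]


def normalize_scores(
    table: ToolScoreTable,
    conventions: Mapping[str, ToolConvention] = DEFAULT_CONVENTIONS,
    reference: Iterable[str] | None = None,
) -> ToolScoreTable:
    """Map raw scores onto the common damaging-is-high [0, 1] scale.

    ``reference`` names the rows (rsids) whose observed values define the
    min/max for min-max scaled tools — conventionally the union of the positive
    and negative sets under comparison.  ``None`` uses all rows.  Missing
    values stay missing.
    """
    scores = table.scores.copy()
    ref_index = scores.index if reference is None else [r for r in scores.index if r in set(reference)]
    for tool in table.tools:
        conv = conventions.get(tool, ToolConvention(tool))
        col = scores[tool].to_numpy(dtype=float)
        if conv.scaling == "minmax":
            ref = scores.loc[ref_index, tool].to_numpy(dtype=float)
            ref = ref[~np.isnan(ref)]
            if ref.size == 0:
                raise ValueError(f"{tool}: empty reference set for min-max scaling")
            lo, hi = ref.min(), ref.max()
            if hi == lo:
                raise ValueError(f"{tool}: degenerate reference (min == max == {lo!r})")
            col = (col - lo) / (hi - lo)
        col = np.clip(col, 0.0, 1.0)
        if conv.direction == "lower_is_damaging" or conv.scaling == "invert_unit":
            col = 1.0 - col
        scores[tool] = col
    return ToolScoreTable(list(table.tools), scores, table.groups.copy())


def polyphen2_bin(score: float) -> str:
    """Categorical PolyPhen2 label: benign [0, 0.15), possibly damaging
    [0.15, 0.85), probably damaging [0.85, 1]."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"PolyPhen2 score {score!r} outside [0, 1]")
    for b in POLYPHEN2_BINS:
        if b.contains(score):
            return b.label
    raise AssertionError("unreachable: bins partition [0, 1]")


def cadd_phred_to_rank_fraction(phred: float) -> float:
    """Fraction of all possible variants ranked at or above this CADD Phred score.

    A Phred-scaled score s places the variant in the top 10**(-s/10) of all
    possible substitutions (10 -> top 10%, 20 -> top 1%, 30 -> top 0.1%).
    """
    if phred < 0:
        raise ValueError(f"CADD Phred score must be non-negative, got {phred!r}")
    return 10.0 ** (-phred / 10.0)


# ---------------------------------------------------------------------------
# ROC / AUC / MCC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocCurve:
    """ROC points from sweeping the damaging-call threshold over observed scores.

    ``points`` runs from (0, 0) to (1, 1); ``thresholds`` aligns with points
    (+inf for the all-negative origin).  A call is "damaging" when
    score >= threshold, so ties share a point.
    """

    points: tuple[tuple[float, float], ...]
    thresholds: tuple[float, ...]
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        fprs = [p[0] for p in self.points]
        tprs = [p[1] for p in self.points]
        if self.points[0] != (0.0, 0.0) or self.points[-1] != (1.0, 1.0):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if any(b < a for a, b in zip(fprs, fprs[1:])) or any(
            b < a for a, b in zip(tprs, tprs[1:])
        ):
            raise ValueError("ROC rates must be non-decreasing")


def _drop_na(values: Sequence[float] | np.ndarray, side: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError(f"{side} sample is empty after dropping missing values")
    return arr


def roc_curve(pos: Sequence[float], neg: Sequence[float]) -> RocCurve:
    """ROC curve for damaging-is-high scores; thresholds are the distinct scores."""
    p = _drop_na(pos, "positive")
    n = _drop_na(neg, "negative")
    thresholds = np.unique(np.concatenate([p, n]))[::-1]
    points = [(0.0, 0.0)]
    ths = [math.inf]
    for t in thresholds:
        tpr = float(np.count_nonzero(p >= t)) / p.size
        fpr = float(np.count_nonzero(n >= t)) / n.size
        points.append((fpr, tpr))
        ths.append(float(t))
    return RocCurve(tuple(points), tuple(ths), int(p.size), int(n.size))


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the concordance probability P(X > Y) + 0.5 P(X = Y) for the samples
    that generated the curve.
    """
    fprs = np.array([p[0] for p in curve.points])
    tprs = np.array([p[1] for p in curve.points])
    return float(np.trapezoid(tprs, fprs))


def auc_scores(pos: Sequence[float], neg: Sequence[float]) -> float:
    return auc(roc_curve(pos, neg))


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; zero-denominator cases return 0."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_at_threshold(pos: Sequence[float], neg: Sequence[float], threshold: float) -> float:
    """MCC of the classifier "damaging when score >= threshold"."""
    p = _drop_na(pos, "positive")
    n = _drop_na(neg, "negative")
    tp = int(np.count_nonzero(p >= threshold))
    fp = int(np.count_nonzero(n >= threshold))
    return mcc(tp, fp, int(p.size - tp), int(n.size - fp))


def mcc_best_threshold(pos: Sequence[float], neg: Sequence[float]) -> tuple[float, float]:
    """Sweep every distinct observed score as threshold; return the maximizer.

    Ties on MCC break toward the larger threshold.
    """
    p = _drop_na(pos, "positive")
    n = _drop_na(neg, "negative")
    best_t, best_m = math.inf, -math.inf
    for t in np.unique(np.concatenate([p, n]))[::-1]:
        m = mcc_at_threshold(p, n, float(t))
        if m > best_m:
            best_t, best_m = float(t), m
    return best_t, best_m


# ---------------------------------------------------------------------------
# rank tests and the AUC comparison t-test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    """Test statistic with raw and multiplicity-corrected p-value."""

    statistic: float
    p_value: float
    raw_p: float
    sides: str
    correction: str
    n1: int
    n2: int


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], sides: str = "two"
) -> TestResult:
    """Mann-Whitney U rank test (U reported for ``x``).

    The exact null distribution is used for tie-free samples with
    n1*n2 <= 400; otherwise the normal approximation with tie-corrected
    variance and continuity correction.  One-sided tests the alternative that
    ``x`` is stochastically greater than ``y``.
    """
    if sides not in ("one", "two"):
        raise ValueError(f"sides must be 'one' or 'two', got {sides!r}")
    xa = _drop_na(x, "x")
    ya = _drop_na(y, "y")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and xa.size * ya.size <= 400) else "asymptotic"
    res = stats.mannwhitneyu(
        xa,
        ya,
        alternative="two-sided" if sides == "two" else "greater",
        method=method,
        use_continuity=True,
    )
    return TestResult(
        float(res.statistic), float(res.pvalue), float(res.pvalue), sides, "none",
        int(xa.size), int(ya.size),
    )


def paired_one_sided_t_test(
    auc_a: Sequence[float], auc_b: Sequence[float], bonferroni_m: int = 1
) -> TestResult:
    """Paired one-sided t-test on per-tool AUC differences (alternative a > b).

    The raw p is multiplied by ``bonferroni_m`` and capped at 1.  Identical
    inputs (all differences zero) report p = 1.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least two paired values")
    if bonferroni_m < 1:
        raise ValueError("bonferroni_m must be >= 1")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        mean = float(d.mean())
        stat = 0.0 if mean == 0 else math.copysign(math.inf, mean)
        raw = 1.0 if mean <= 0 else 0.0
    else:
        res = stats.ttest_rel(a, b, alternative="greater")
        stat, raw = float(res.statistic), float(res.pvalue)
    corrected = min(1.0, raw * bonferroni_m)
    label = "none" if bonferroni_m == 1 else f"bonferroni({bonferroni_m})"
    return TestResult(stat, corrected, raw, "one", label, int(a.size), int(b.size))


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    tool: str
    group: str
    n: int
    n_missing: int
    median: float | None
    q1: float | None
    q3: float | None
    bin_counts: Mapping[str, int] | None


def group_summary(
    table: ToolScoreTable,
    tool: str,
    group: str,
    conventions: Mapping[str, ToolConvention] = DEFAULT_CONVENTIONS,
) -> GroupSummary:
    """Median, quartiles and (where defined) categorical bin counts for one
    tool within one group.  Statistics run over non-missing values only."""
    values = table.values(tool, group)  # raises KeyError for unknown tool/group
    present = values[~np.isnan(values)]
    n_missing = int(values.size - present.size)
    conv = conventions.get(tool)
    bins = conv.bins if conv is not None else None
    if present.size == 0:
        counts = {b.label: 0 for b in bins} if bins else None
        return GroupSummary(tool, group, 0, n_missing, None, None, None, counts)
    median = float(np.median(present))
    q1, q3 = (float(q) for q in np.percentile(present, [25, 75]))
    counts = None
    if bins:
        counts = {b.label: int(sum(b.contains(v) for v in present)) for b in bins}
    return GroupSummary(tool, group, int(present.size), n_missing, median, q1, q3, counts)
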