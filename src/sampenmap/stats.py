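"""Group statistics: ROC analysis, t-tests, age correlation, BH-FDR.

The discrimination question throughout is whether a subject's mean
whole-brain SampEn separates younger from elderly adults.  Orientation is
fixed as *higher SampEn implies younger* (the loss-of-entropy-with-age
direction), so the ROC area is the probability that a random younger
subject outscores a random elderly one, and the operating rule classifies
``score >= threshold`` as younger.

Conventions:

* t-tests are pooled-variance Student tests (df = n1 + n2 - 2) by default,
  with a Welch option;
* multiple comparisons across data lengths use Benjamini-Hochberg step-up
  q-values, significance at q < 0.05;
* Pearson coefficients are bucketed into the Dancey-Reidy interpretive
  bands (|r| rounded to 1 d.p.: 0 zero, 0.1-0.3 weak, 0.4-0.6 moderate,
  0.7-0.9 strong, 1 perfect);
* ROC areas are bucketed as >=0.90 excellent, 0.80-0.89 good, 0.70-0.79
  fair, 0.60-0.69 poor, 0.50-0.59 bad, below 0.50 'below chance'.

The operating threshold (not prescribed by any convention) is chosen among
midpoints between consecutive distinct pooled scores, maximizing accuracy,
tie-broken by maximal Youden index (sensitivity + specificity) and then by
the lowest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .core import SeriesTooShortError  # noqa: F401  (re-exported pipeline error)
from .mapping import EntropyMap, mean_sampen_over_r_grid

__all__ = [
    "ROCResult", "TestResult", "CorrelationResult", "RSweepResult", "GroupMapResult",
    "EntropyThresholdClassifier",
    "roc_area", "roc_operating_point", "r_sweep",
    "pooled_t_test_from_summary", "two_sample_t_test",
    "pearson_with_age", "bh_fdr", "classify_roc_area", "classify_correlation",
    "voxelwise_group_map", "DEFAULT_R_GRID",
]

#: The standard tolerance sweep: 0.05 to 0.50 in steps of 0.05.
DEFAULT_R_GRID = tuple(np.round(np.arange(1, 11) * 0.05, 2))


@dataclass(frozen=True)
class ROCResult:
    """ROC area plus the chosen operating point (percent units)."""

    area: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    orientation: str = "higher score => younger"

    def __post_init__(self) -> None:
        if not (0.0 <= self.area <= 1.0):
            raise ValueError("area must lie in [0, 1]")
        for name in ("sensitivity", "specificity", "accuracy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be a percentage in [0, 100]")


@dataclass(frozen=True)
class TestResult:
    """A t-test outcome, optionally FDR-adjusted."""

    statistic: float
    df: float
    p_value: float
    q_value: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its Dancey-Reidy interpretive category."""

    r: float
    p_value: float
    q_value: float | None = None
    category: str = ""


@dataclass
class RSweepResult:
    """Tolerance sweep outcome: per-r ROC areas and the chosen optimum."""

    table: pd.DataFrame
    optimal_r: float


@dataclass
class GroupMapResult:
    """Simplified voxel-wise group comparison: t, p and BH-FDR q maps."""

    t_map: np.ndarray
    p_map: np.ndarray
    q_map: np.ndarray
    tested: np.ndarray  # boolean grid of voxels that entered the test


def _scores(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("score list must be nonempty")
    if not np.all(np.isfinite(a)):
        raise ValueError("scores must be finite")
    return a


def roc_area(scores_young, scores_old) -> float:
    """P(random younger score > random elderly score), ties counted half."""
    y = _scores(scores_young)
    o = _scores(scores_old)
    labels = np.r_[np.ones(y.size), np.zeros(o.size)]
    return float(roc_auc_score(labels, np.r_[y, o]))


class EntropyThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-threshold classifier on a scalar entropy score.

    ``fit(X, y)`` takes scores (n,) or (n, 1) and labels with the positive
    class 'younger'; it learns ``threshold_`` by exhaustive search over
    midpoints between consecutive distinct scores, maximizing accuracy with
    Youden-index then lowest-threshold tie-breaks.  Fitted attributes also
    include ``area_``, ``sensitivity_``, ``specificity_`` and ``accuracy_``
    (percent).  ``predict`` applies ``score >= threshold_ -> 'younger'``.
    """

    positive_label = "younger"
    negative_label = "elderly"

    def fit(self, X, y):
        scores = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        if scores.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        pos = y == self.positive_label
        if not pos.any() or pos.all():
            raise ValueError("need scores from both groups")
        young, old = scores[pos], scores[~pos]
        self.classes_ = np.array([self.negative_label, self.positive_label])
        self.area_ = roc_area(young, old)

        pooled = np.unique(np.r_[young, old])
        if pooled.size >= 2:
            candidates = (pooled[:-1] + pooled[1:]) / 2.0
        else:
            candidates = pooled  # degenerate: all scores identical
        best = None
        for thr in candidates:
            sens = 100.0 * np.mean(young >= thr)
            spec = 100.0 * np.mean(old < thr)
            acc = 100.0 * (np.sum(young >= thr) + np.sum(old < thr)) / scores.size
            key = (acc, sens + spec, -thr)
            if best is None or key > best[0]:
                best = (key, thr, sens, spec, acc)
        _, self.threshold_, self.sensitivity_, self.specificity_, self.accuracy_ = best
        self.threshold_ = float(self.threshold_)
        return self

    def predict(self, X):
        scores = np.asarray(X, dtype=float).reshape(-1)
        return np.where(scores >= self.threshold_, self.positive_label, self.negative_label)

    def result(self) -> ROCResult:
        return ROCResult(area=self.area_, threshold=self.threshold_,
                         sensitivity=float(self.sensitivity_),
                         specificity=float(self.specificity_),
                         accuracy=float(self.accuracy_))


def roc_operating_point(scores_young, scores_old) -> ROCResult:
    """ROC area and operating point for two groups of entropy scores."""
    y = _scores(scores_young)
    o = _scores(scores_old)
    clf = EntropyThresholdClassifier().fit(
        np.r_[y, o], np.r_[["younger"] * y.size, ["elderly"] * o.size])
    return clf.result()


def r_sweep(young, old, r_grid=DEFAULT_R_GRID, m: int = 2, tau: int = 1,
            N: int | None = None, policy: str = "propagate") -> RSweepResult:
    """ROC area of the group separation at every tolerance in ``r_grid``.

    ``young`` and ``old`` are lists of ``(Volume4D, BrainMask)`` pairs of
    *preprocessed* subjects.  Mean whole-brain SampEn is recomputed per
    subject at each r; an r at which any subject's mean is undefined is kept
    in the table but flagged and excluded from the optimum.  The optimal r
    maximizes the ROC area, ties broken toward the larger r (larger
    tolerances are more robust to noise).
    """
    r_grid = [float(r) for r in r_grid]
    if not r_grid:
        raise ValueError("r_grid must be nonempty")
    per_group_means: list[list[dict[float, float | None]]] = []
    for group in (young, old):
        means = []
        for vol, mask in group:
            wb = mean_sampen_over_r_grid(vol, mask, r_grid, m=m, tau=tau, N=N, policy=policy)
            means.append({r: wb[r].value for r in r_grid})
        per_group_means.append(means)
    rows = []
    for r in r_grid:
        ys = [s[r] for s in per_group_means[0]]
        os_ = [s[r] for s in per_group_means[1]]
        n_undef = sum(v is None for v in ys + os_)
        area = roc_area([v for v in ys], [v for v in os_]) if n_undef == 0 else np.nan
        rows.append({"r": r, "roc_area": area, "n_undefined_subjects": n_undef})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["roc_area"])
    if valid.empty:
        failures = ", ".join(f"r={row.r:g}: {row.n_undefined_subjects} undefined"
                             for row in table.itertuples())
        raise ValueError(f"no tolerance yields all-defined subject means ({failures})")
    best_area = valid["roc_area"].max()
    optimal_r = float(valid.loc[valid["roc_area"] == best_area, "r"].max())
    return RSweepResult(table=table, optimal_r=optimal_r)


def pooled_t_test_from_summary(mean1: float, sd1: float, n1: int,
                               mean2: float, sd2: float, n2: int,
                               equal_var: bool = True) -> TestResult:
    """Two-sample t-test from group summaries (pooled Student by default)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return TestResult(statistic=float(t), df=float(df), p_value=float(p))


def two_sample_t_test(group1, group2, equal_var: bool = True) -> TestResult:
    """Two-sample t-test from raw data; consistent with the summary version."""
    a, b = _scores(group1), _scores(group2)
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        v1, v2 = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (v1 + v2) ** 2 / (v1 ** 2 / (a.size - 1) + v2 ** 2 / (b.size - 1))
    return TestResult(statistic=float(t), df=float(df), p_value=float(p))


def classify_correlation(r: float) -> str:
    """Dancey-Reidy band of a Pearson coefficient (on |r| rounded to 1 d.p.)."""
    if not (-1.0 <= r <= 1.0):
        raise ValueError("r must lie in [-1, 1]")
    a = round(abs(r), 1)
    if a == 0.0:
        return "zero"
    if a <= 0.3:
        return "weak"
    if a <= 0.6:
        return "moderate"
    if a <= 0.9:
        return "strong"
    return "perfect"


def pearson_with_age(values, ages) -> CorrelationResult:
    """Pearson correlation of a per-subject measure with age, two-tailed p."""
    v, a = _scores(values), _scores(ages)
    if v.size != a.size:
        raise ValueError("values and ages must have equal length")
    if v.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(v) == 0 or np.std(a) == 0:
        raise ValueError("zero variance in values or ages")
    res = sps.pearsonr(v, a)
    r = float(res.statistic)
    return CorrelationResult(r=r, p_value=float(res.pvalue), category=classify_correlation(r))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_roc_area(area: float) -> str:
    """Diagnostic-precision band of an ROC area."""
    if not (0.0 <= area <= 1.0):
        raise ValueError("area must lie in [0, 1]")
    if area >= 0.90:
        return "excellent"
    if area >= 0.80:
        return "good"
    if area >= 0.70:
        return "fair"
    if area >= 0.60:
        return "poor"
    if area >= 0.50:
        return "bad"
    return "below chance"


def voxelwise_group_map(maps_young: list[EntropyMap], maps_old: list[EntropyMap],
                        equal_var: bool = True) -> GroupMapResult:
    """Per-voxel two-sample t-test between groups of entropy maps, with BH-FDR.

    A voxel is tested only where it is in-mask and every subject's estimate
    is defined; untested voxels are NaN in all three maps.  q-values are
    adjusted across the tested voxels only.  (A deliberate simplification of
    cluster-level inference: no spatial model, voxel-wise FDR only.)
    """
    if len(maps_young) < 2 or len(maps_old) < 2:
        raise ValueError("need at least two subjects per group")
    ref = maps_young[0]
    grid = ref.values.shape
    for em in maps_young + maps_old:
        if em.values.shape != grid or not np.array_equal(em.mask.include, ref.mask.include):
            raise ValueError("all maps must share the same grid and mask")
    Y = np.stack([em.values for em in maps_young])  # (n1, x, y, z)
    O = np.stack([em.values for em in maps_old])
    tested = ref.mask.include & np.isfinite(Y).all(axis=0) & np.isfinite(O).all(axis=0)
    t_map = np.full(grid, np.nan)
    p_map = np.full(grid, np.nan)
    q_map = np.full(grid, np.nan)
    if tested.any():
        t, p = sps.ttest_ind(Y[:, tested], O[:, tested], axis=0, equal_var=equal_var)
        t_map[tested] = t
        p_map[tested] = p
        q_map[tested] = bh_fdr(p)
    return GroupMapResult(t_map=t_map, p_map=p_map, q_map=q_map, tested=tested)
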