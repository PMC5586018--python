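"""Voxel-level statistics: overlap classification, Mann-Whitney, logistic
regression, odds ratios, probability-inversion thresholds, ROC/AUC.

Every voxel of the primary-tumor region (ROI_pri) is an observation. In a
patient whose tumor recurred, voxels inside both the recurrent-tumor
region and ROI_pri are *overlap* voxels (``ovl``); the rest of ROI_pri are
*non-overlap* (``non_ovl``). Non-recurrent patients contribute only
non-overlap voxels. Pooling voxels across patients and treating them as
independent observations — the working assumption of the whole analysis —
yields a two-column logistic regression of recurrence membership on TMR:

    logit P(ovl | TMR = t) = a + b * t

The odds ratio per unit TMR is exp(b); inverting the fitted curve gives
the TMR at which the predicted recurrence probability reaches a chosen
level (e.g. 50% or 30%), the quantity a dose-painting protocol would
threshold on. Discrimination is summarized by the ROC curve over TMR
cut points, whose trapezoidal AUC equals the Mann-Whitney U statistic
scaled by the number of (ovl, non_ovl) pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from .grids import ROIMask, _require_same_geometry
from .tmr import TMRMap

__all__ = [
    "LABEL_OVL",
    "LABEL_NON_OVL",
    "VOXEL_TABLE_COLUMNS",
    "LogisticFit",
    "GroupComparison",
    "ROCResult",
    "SeparationError",
    "ConvergenceError",
    "classify_voxels",
    "pool_whole_series",
    "mann_whitney",
    "fit_logistic_irls",
    "odds_ratio",
    "tmr_at_probability",
    "roc_auc",
    "count_above",
    "tmr_max",
]

LABEL_OVL = "ovl"
LABEL_NON_OVL = "non_ovl"
VOXEL_TABLE_COLUMNS = ["patient_id", "i", "j", "k", "tmr", "label"]

EXACT_MW_LIMIT = 400  # exact null distribution when n1 * n2 <= this


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class ConvergenceError(RuntimeError):
    """Iteratively reweighted least squares failed to converge."""


# ---------------------------------------------------------------------------
# voxel classification and pooling


def classify_voxels(
    primary: ROIMask,
    recurrence: ROIMask | None,
    tmr: TMRMap,
    patient_id: str,
    outside_policy: str = "clip",
) -> pd.DataFrame:
    """Label every primary-ROI voxel as overlap / non-overlap.

    Returns a voxel table: one row per ROI_pri voxel with columns
    ``patient_id, i, j, k, tmr, label``. With no recurrence mask (a
    non-recurrent patient) every voxel is non-overlap.

    Recurrence voxels falling outside the primary ROI are counted and
    logged; ``outside_policy`` decides whether they are clipped away
    (``"clip"``, default — consistent with cohorts where the recurrent
    contour lies within the primary tumor) or rejected (``"error"``).
    """
    if outside_policy not in ("clip", "error"):
        raise ValueError(f"unknown outside_policy {outside_policy!r}")
    _require_same_geometry(primary.geometry, tmr.geometry, "classify_voxels")
    idx = primary.indices()
    if recurrence is None:
        labels = np.full(len(idx), LABEL_NON_OVL, dtype=object)
    else:
        _require_same_geometry(primary.geometry, recurrence.geometry, "classify_voxels")
        n_outside = int((recurrence.values & ~primary.values).sum())
        if n_outside:
            msg = (
                f"patient {patient_id}: {n_outside} recurrence voxels lie outside "
                f"the primary ROI"
            )
            if outside_policy == "error":
                raise ValueError(msg)
            warnings.warn(msg + " (clipped)", stacklevel=2)
        inside = recurrence.values[tuple(idx.T)]
        labels = np.where(inside, LABEL_OVL, LABEL_NON_OVL).astype(object)
    table = pd.DataFrame(
        {
            "patient_id": patient_id,
            "i": idx[:, 0],
            "j": idx[:, 1],
            "k": idx[:, 2],
            "tmr": tmr.values[tuple(idx.T)],
            "label": labels,
        }
    )
    return table


def pool_whole_series(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-patient voxel tables into the whole-series table.

    Patient ids must be distinct; per-label counts of the pooled table are
    by construction the sums of the per-patient counts.
    """
    if not tables:
        return pd.DataFrame(columns=VOXEL_TABLE_COLUMNS)
    ids = [t["patient_id"].iloc[0] for t in tables if len(t)]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids in pooled series: {dupes}")
    return pd.concat(tables, ignore_index=True)


def label_counts(table: pd.DataFrame) -> tuple[int, int]:
    """(n_ovl, n_non_ovl) of a voxel table."""
    vc = table["label"].value_counts()
    return int(vc.get(LABEL_OVL, 0)), int(vc.get(LABEL_NON_OVL, 0))


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass
class GroupComparison:
    """Two-group rank comparison (Mann-Whitney U, two-sided)."""

    u_statistic: float
    z_value: float
    p_value: float
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    n_a: int
    n_b: int
    method: str = "asymptotic"


def _exact_rank_sum_p(ranks2: np.ndarray, n_a: int, w_obs: int) -> float:
    """Exact two-sided permutation p-value for the rank sum of group a.

    ``ranks2`` are the pooled mid-ranks doubled to integers. The exact
    null distribution of the group-a rank sum under random relabeling is
    built by dynamic programming over (subset size, subset sum); subset
    counts up to C(40, 20) ≈ 1.4e11 are exactly representable in float64.
    Two-sided p = 2 * min(P(W <= w), P(W >= w)), capped at 1.
    """
    total = int(ranks2.sum())
    # dp[k, s] = number of k-subsets of the ranks seen so far with sum s
    dp = np.zeros((n_a + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    dist = dp[n_a]
    n_total = dist.sum()
    lo = dist[: w_obs + 1].sum() / n_total
    hi = dist[w_obs:].sum() / n_total
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney(a: np.ndarray, b: np.ndarray) -> GroupComparison:
    """Mann-Whitney U test between two value samples (two-sided).

    U is the a-side statistic ``#(a > b) + ties/2`` computed through
    mid-ranks. For small problems (``n_a * n_b <= 400``) the p-value is the
    exact permutation tail of the rank-sum distribution (correct under
    ties); otherwise the normal approximation with tie-corrected variance
    and continuity correction is used. When every pooled value is
    identical the test is vacuous: p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # mid-ranks
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0

    mean_a, mean_b = float(a.mean()), float(b.mean())
    se_a = float(a.std(ddof=1) / np.sqrt(n_a)) if n_a > 1 else float("nan")
    se_b = float(b.std(ddof=1) / np.sqrt(n_b)) if n_b > 1 else float("nan")

    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both groups; test is vacuous", stacklevel=2)
        return GroupComparison(
            u_a, 0.0, 1.0, mean_a, se_a, mean_b, se_b, n_a, n_b, method="degenerate"
        )

    # tie-corrected normal approximation with continuity correction
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    mu = n_a * n_b / 2.0
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    diff = u_a - mu
    z = (diff - 0.5 * np.sign(diff)) / sigma if sigma > 0 else 0.0

    if n_a * n_b <= EXACT_MW_LIMIT:
        # mid-ranks doubled to integers so the DP runs on an integer lattice
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        p = _exact_rank_sum_p(ranks2, n_a, int(np.rint(2 * r_a)))
        method = "exact"
    else:
        p = float(2 * sps.norm.sf(abs(z)))
        p = min(1.0, max(p, np.finfo(float).tiny))
        method = "asymptotic"

    return GroupComparison(
        float(u_a), float(z), float(p), mean_a, se_a, mean_b, se_b, n_a, n_b, method
    )


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticFit:
    """Maximum-likelihood fit of ``logit P(ovl) = intercept + slope * TMR``."""

    intercept: float
    slope: float
    covariance: np.ndarray
    n_events: int
    n_total: int
    converged: bool
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(2, 2)
        if self.converged:
            if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
                raise ValueError("converged fit must have finite parameters")
            eig = np.linalg.eigvalsh((self.covariance + self.covariance.T) / 2)
            if eig.min() < -1e-8:
                raise ValueError("covariance must be positive semidefinite")

    @classmethod
    def from_parameters(cls, intercept: float, slope: float) -> "LogisticFit":
        """An analytic fit with known coefficients and zero covariance —
        for reconstructing a published curve from its printed anchors."""
        return cls(float(intercept), float(slope), np.zeros((2, 2)), 0, 0, True)

    def predict_probability(self, tmr: np.ndarray | float) -> np.ndarray | float:
        return special.expit(self.intercept + self.slope * np.asarray(tmr, dtype=float))

    @property
    def slope_se(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    @property
    def intercept_se(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))


def _check_separation(t1: np.ndarray, t0: np.ndarray) -> None:
    lo1, hi1 = t1.min(), t1.max()
    lo0, hi0 = t0.min(), t0.max()
    complete = hi0 < lo1 or hi1 < lo0
    quasi = (hi0 <= lo1 or hi1 <= lo0) and not complete
    if complete:
        raise SeparationError(
            "complete separation: a TMR threshold classifies every voxel; "
            "the maximum-likelihood slope is infinite"
        )
    if quasi:
        raise SeparationError(
            "quasi-complete separation at the boundary TMR value; "
            "the maximum-likelihood estimate does not exist"
        )


def fit_logistic_irls(
    table: pd.DataFrame,
    score_tol: float = 1e-8,
    step_tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit the voxel-level recurrence model by IRLS (Newton-Raphson).

    Observations are the rows of the voxel table: response 1 for overlap
    voxels, 0 for non-overlap; single covariate TMR. Convergence when the
    largest absolute score (gradient) falls below ``score_tol`` or the
    parameter step below ``step_tol``. Covariance is the inverse observed
    information at the optimum.

    Raises
    ------
    SeparationError
        Complete or quasi-complete separation (detected exactly from the
        ordering of the single covariate, and guarded during iteration).
    ConvergenceError
        No convergence within ``max_iter`` iterations; the message carries
        the iteration trace.
    """
    t = np.asarray(table["tmr"], dtype=float)
    y = (np.asarray(table["label"]) == LABEL_OVL).astype(float)
    if not np.all(np.isfinite(t)):
        raise ValueError("voxel table contains non-finite TMR values")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both overlap and non-overlap voxels are required for the fit")
    if np.ptp(t) == 0:
        raise ValueError("TMR is constant; the slope is unidentifiable")
    _check_separation(t[y == 1], t[y == 0])

    x = np.column_stack([np.ones_like(t), t])
    beta = np.zeros(2)
    trace: list[str] = []
    for it in range(1, max_iter + 1):
        eta = x @ beta
        p = special.expit(eta)
        w = p * (1.0 - p)
        score = x.T @ (y - p)
        info = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular information matrix at iteration {it} "
                "(fitted probabilities collapsed to 0/1)"
            ) from exc
        beta = beta + step
        max_score = float(np.max(np.abs(score)))
        max_step = float(np.max(np.abs(step)))
        trace.append(f"iter {it}: max|score|={max_score:.3e} max|step|={max_step:.3e}")
        if np.max(np.abs(x @ beta)) > 300:
            raise SeparationError(
                "diverging linear predictor (|eta| > 300): fitted probabilities "
                "approach 0/1, indicating separation"
            )
        if max_score < score_tol or max_step < step_tol:
            eta = x @ beta
            p = special.expit(eta)
            w = p * (1.0 - p)
            info = (x * w[:, None]).T @ x
            cov = np.linalg.inv(info)
            return LogisticFit(
                float(beta[0]), float(beta[1]), cov, n1, n1 + n0, True, it
            )
    raise ConvergenceError(
        "IRLS did not converge within "
        f"{max_iter} iterations:\n" + "\n".join(trace[-10:])
    )


def odds_ratio(fit: LogisticFit, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio per unit TMR with a Wald confidence interval.

    OR = exp(slope); the interval is exp(slope ± z * SE(slope)) — symmetric
    on the log-odds scale.
    """
    if not fit.converged:
        raise ValueError("odds ratio requires a converged fit")
    z = sps.norm.ppf(0.5 + level / 2)
    se = fit.slope_se
    or_ = float(np.exp(fit.slope))
    return or_, float(np.exp(fit.slope - z * se)), float(np.exp(fit.slope + z * se))


def tmr_at_probability(
    fit: LogisticFit, p: float, level: float = 0.95
) -> tuple[float, float, float]:
    """TMR at which the fitted recurrence probability equals ``p``.

    Inverts the logistic curve: ``t = (logit(p) - intercept) / slope``.
    The confidence interval is by the delta method on this ratio using the
    fit covariance (gradient (-1/b, -t/b)).
    """
    if not 0 < p < 1:
        raise ValueError("probability must lie strictly between 0 and 1")
    if not fit.converged:
        raise ValueError("threshold inversion requires a converged fit")
    b = fit.slope
    if abs(b) < 1e-8:
        raise ValueError("slope is (numerically) zero: the threshold is unidentifiable")
    t = (special.logit(p) - fit.intercept) / b
    grad = np.array([-1.0 / b, -t / b])
    var = float(grad @ fit.covariance @ grad)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(t), float(t - half), float(t + half)


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCResult:
    """ROC curve over TMR cut points with trapezoidal AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def roc_auc(table: pd.DataFrame) -> ROCResult:
    """ROC curve of TMR as a classifier of overlap membership.

    The curve is swept over every distinct TMR value; the AUC is the
    trapezoidal area, which with mid-rank tie handling equals
    ``U / (n_ovl * n_non_ovl)`` for the Mann-Whitney U on the same data.
    """
    y = (np.asarray(table["label"]) == LABEL_OVL).astype(int)
    t = np.asarray(table["tmr"], dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC requires both overlap and non-overlap voxels")
    fpr, tpr, thr = _sk_roc_curve(y, t, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thr, tpr, fpr, auc, n1, n0)


# ---------------------------------------------------------------------------
# simple tabulations


def count_above(table: pd.DataFrame, threshold: float) -> tuple[int, float]:
    """Voxels with TMR strictly greater than ``threshold``: (count, fraction).

    The fraction is of all table rows; multiply by 100 and round to two
    decimals to report a percentage.
    """
    if len(table) == 0:
        raise ValueError("voxel table is empty")
    count = int((np.asarray(table["tmr"], dtype=float) > threshold).sum())
    return count, count / len(table)


def tmr_max(tmr: TMRMap, roi: ROIMask) -> float:
    """Maximum TMR over the voxels of ``roi``."""
    _require_same_geometry(tmr.geometry, roi.geometry, "tmr_max")
    if roi.n_voxels == 0:
        raise ValueError("ROI is empty")
    vals = tmr.values[roi.values]
    if np.all(np.isnan(vals)):
        raise ValueError("ROI contains no defined TMR values")
    return float(np.nanmax(vals))
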