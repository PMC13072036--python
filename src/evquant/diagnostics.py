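"""CD98+ EV Index construction and diagnostic evaluation.

The index for one subject is

    score = max(0, sample_well_count - mean(negative-control well counts))
    index = score / (total_ev_concentration / scale)

i.e. a disc-local background subtraction followed by normalization to the
subject's total EV concentration (scale default 1e9 particles/mL, so
indices land in the single-digit range). Evaluation follows the standard
screening toolkit: ROC with tie-aware AUC (identical to the Mann-Whitney
U statistic), Youden-maximizing cutoff, confusion counts at a cutoff, a
two-proportion z-test, Welch's t-test, Pearson chi-square, and logistic
regression under stratified k-fold cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import parse_control_counts

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# index construction

def normalize_score(sample_well_count: float, control_well_counts) -> float:
    """Control-normalized CD98+ EV score: sample minus same-disc control mean.

    Background binding events add to every well on a disc, so subtraction
    (not division) removes them; negative differences floor at zero.
    """
    controls = np.asarray(control_well_counts, dtype=float)
    if controls.size == 0:
        raise ValueError("no negative-control wells supplied for this disc")
    return max(0.0, float(sample_well_count) - float(controls.mean()))


def ev_index(cd98_score: float, total_ev_concentration: float, scale: float = 1e9) -> float:
    """CD98+ EV Index: score per unit of total EV concentration."""
    if total_ev_concentration <= 0:
        raise ValueError("total EV concentration must be positive")
    return cd98_score / (total_ev_concentration / scale)


def derive_index(df: pd.DataFrame, scale: float = 1e9) -> pd.Series:
    """Per-subject index from the raw columns of a cohort table."""
    missing = df["control_well_counts"].isna()
    if missing.any():
        bad = df.loc[missing, "disc_id"].unique() if "disc_id" in df else ["?"]
        raise ValueError(f"missing negative-control counts for disc(s): {list(bad)}")
    scores = [
        normalize_score(s, parse_control_counts(c))
        for s, c in zip(df["sample_well_count"], df["control_well_counts"])
    ]
    return pd.Series(
        [ev_index(s, c, scale) for s, c in zip(scores, df["total_ev_concentration"])],
        index=df.index,
        name="cd98_index",
    )


# ---------------------------------------------------------------------------
# ROC / cutoff / confusion

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


@dataclass
class ROCCurve:
    """Empirical ROC: positive call iff score >= threshold.

    ``thresholds`` descend from +inf to -inf through midpoints between
    consecutive distinct scores, so sensitivity and 1-specificity are both
    non-decreasing along the curve from (0,0) to (1,1). ``auc`` is the
    trapezoidal area, which with midpoint thresholds equals the tie-corrected
    Mann-Whitney U divided by n_pos*n_neg.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray  # 1 - specificity
    auc: float


def _as_binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        labels = (labels == "hcc").astype(int)
    labels = labels.astype(int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1 or 'healthy'/'hcc')")
    return labels


def roc_curve(indices, labels) -> ROCCurve:
    """ROC over all candidate cutoffs (midpoints between distinct scores)."""
    x = np.asarray(indices, dtype=float)
    y = _as_binary_labels(labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    uniq = np.unique(x)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))
    # call positive iff x >= t
    calls = x[None, :] >= thresholds[:, None]
    tp = (calls & (y == 1)).sum(axis=1)
    fp = (calls & (y == 0)).sum(axis=1)
    sens = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(thresholds=thresholds, sensitivity=sens, fpr=fpr, auc=auc)


def youden_cutoff(roc: ROCCurve) -> tuple[float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Ties go to the lowest finite cutoff (maximizing sensitivity, the
    screening-oriented convention).
    """
    j = roc.sensitivity - roc.fpr
    best = float(np.max(j))
    winners = roc.thresholds[j == best]
    finite = winners[np.isfinite(winners)]
    cutoff = float(finite.min()) if finite.size else float(winners.min())
    return cutoff, best


def confusion_at(indices, labels, cutoff: float) -> ConfusionCounts:
    """Confusion counts with a positive call iff index >= cutoff."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    x = np.asarray(indices, dtype=float)
    y = _as_binary_labels(labels)
    call = x >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(call & (y == 1))),
        fp=int(np.sum(call & (y == 0))),
        tn=int(np.sum(~call & (y == 0))),
        fn=int(np.sum(~call & (y == 1))),
    )


# ---------------------------------------------------------------------------
# hypothesis tests

@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: float | None = None
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled two-proportion z-test (two-sided).

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    Degenerate pooled proportion (0 or 1) is reported as z = 0, p = 1.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n and n > 0 in both groups")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TestResult("two-proportion z", 0.0, 1.0)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = float(2 * stats.norm.sf(abs(z)))
    return TestResult("two-proportion z", float(z), p)


def welch_ttest(values_a, values_b) -> TestResult:
    """Unpaired two-tailed t-test with Welch's correction (Satterthwaite df)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch's t-test needs n >= 2 per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult("welch t", 0.0, 1.0, df=float(len(a) + len(b) - 2))
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult("welch t", float(res.statistic), float(res.pvalue), df=float(res.df))


def chi_square(table) -> TestResult:
    """Pearson chi-square of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every row and column margin must be positive")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult("pearson chi2", float(res.statistic), float(res.pvalue), df=float(res.dof))


# ---------------------------------------------------------------------------
# stratified cross-validation + logistic regression (IRLS)

def stratified_kfold(labels, k: int, seed: int) -> np.ndarray:
    """Fold assignment (0..k-1) by within-class shuffled round-robin.

    Guarantees a partition with per-fold class counts within one of exact
    proportionality.
    """
    y = _as_binary_labels(labels)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has fewer members ({len(idx)}) than folds ({k})")
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


@dataclass
class LogisticFit:
    coef: np.ndarray  # includes intercept as element 0
    converged: bool
    separated: bool
    n_iter: int


def fit_logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares, with a tiny ridge term for conditioning.

    Complete separation drives coefficients toward infinity; it is flagged
    (fitted probabilities saturating at the working-precision boundary) and
    the last iterate is returned.
    """
    X = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -500, 500)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-12, None)
        # Newton step: (X'WX + ridge I) d = X'(y - p)
        H = X.T @ (w[:, None] * X) + ridge * np.eye(X.shape[1])
        g = X.T @ (y - p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -500, 500)
    p = 1.0 / (1.0 + np.exp(-eta))
    separated = bool(np.all(np.abs(p - y) < 1e-6)) and np.max(np.abs(beta)) > 10
    if separated or not converged:
        logger.warning(
            "logistic fit %s after %d iterations",
            "separated" if separated else "did not converge",
            it,
        )
    return LogisticFit(coef=beta, converged=converged, separated=separated, n_iter=it)


def predict_proba(fit: LogisticFit, X: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
    return 1.0 / (1.0 + np.exp(-np.clip(X @ fit.coef, -500, 500)))


@dataclass
class CVReport:
    k: int
    seed: int
    fold_assignment: np.ndarray
    fold_auc: list[float]
    fold_accuracy: list[float]
    fold_coefs: list[np.ndarray]
    any_separation: bool

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "mean_auc": self.mean_auc,
            "mean_accuracy": self.mean_accuracy,
            "fold_auc": [float(a) for a in self.fold_auc],
            "fold_accuracy": [float(a) for a in self.fold_accuracy],
            "fold_coefficients": [list(map(float, c)) for c in self.fold_coefs],
            "any_separation": self.any_separation,
        }


def logistic_cv(features, labels, k: int = 5, seed: int = 0) -> CVReport:
    """Stratified k-fold CV of a logistic model.

    Features are standardized on each training fold (mean 0, sd 1; the
    frozen parameters are applied to the held-out fold). Reports test-fold
    AUC and accuracy at probability 0.5.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _as_binary_labels(labels)
    folds = stratified_kfold(y, k, seed)

    aucs, accs, coefs = [], [], []
    any_sep = False
    for f in range(k):
        test = folds == f
        train = ~test
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xtr = (X[train] - mu) / sd
        Xte = (X[test] - mu) / sd
        fit = fit_logistic_irls(Xtr, y[train])
        any_sep |= fit.separated
        p = predict_proba(fit, Xte)
        if len(np.unique(y[test])) == 2:
            aucs.append(roc_curve(p, y[test]).auc)
        else:  # cannot happen with stratified folds and both classes >= k
            aucs.append(float("nan"))
        accs.append(float(np.mean((p >= 0.5).astype(int) == y[test])))
        coefs.append(fit.coef)
    return CVReport(
        k=k, seed=seed, fold_assignment=folds,
        fold_auc=aucs, fold_accuracy=accs, fold_coefs=coefs,
        any_separation=any_sep,
    )


# ---------------------------------------------------------------------------
# one-call cohort evaluation

def evaluate_cohort(
    df: pd.DataFrame,
    scale: float = 1e9,
    cutoff: float | None = None,
    cv_k: int = 5,
    cv_seed: int = 0,
) -> dict:
    """Index construction + full diagnostic evaluation of a cohort table.

    With ``cutoff=None`` the operating point is chosen by the Youden index
    on this cohort; otherwise the supplied cutoff is evaluated as-is.
    """
    idx = derive_index(df, scale=scale).to_numpy()
    labels = _as_binary_labels(df["group"].to_numpy())
    roc = roc_curve(idx, labels)
    if cutoff is None:
        cutoff, j = youden_cutoff(roc)
    else:
        cm0 = confusion_at(idx, labels, cutoff)
        j = cm0.sensitivity + cm0.specificity - 1.0
    cm = confusion_at(idx, labels, cutoff)
    welch = welch_ttest(idx[labels == 1], idx[labels == 0])
    cv = logistic_cv(idx, labels, k=cv_k, seed=cv_seed)
    return {
        "n_healthy": int((labels == 0).sum()),
        "n_hcc": int((labels == 1).sum()),
        "median_index_healthy": float(np.median(idx[labels == 0])),
        "median_index_hcc": float(np.median(idx[labels == 1])),
        "auc": roc.auc,
        "cutoff": float(cutoff),
        "youden_j": float(j),
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "welch_t": {"statistic": welch.statistic, "df": welch.df, "p_value": welch.p_value},
        "cv": cv.to_dict(),
    }
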