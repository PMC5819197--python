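"""Prognostic-accuracy evaluation: logistic panels, ROC/AUC, DeLong, CV.

Marker panels (singles, pairs, and the full triple of the prognostic
candidates) are fitted as maximum-likelihood logistic regressions of the
binary scarring outcome on per-day min-max-normalised marker concentrations.
Each fit is summarised by coefficients, odds ratios, the empirical ROC curve,
the Mann-Whitney (midrank) AUC, and a Wald 95% CI using the DeLong
placement-value variance.  Panels are compared pairwise with DeLong's test
for correlated AUCs, and generalisation is checked by stratified tenfold
cross-validation with pooled out-of-fold probabilities.

Normalisation is a per-marker affine map, absorbed exactly by the logistic
coefficients and intercept, so fitted probabilities and AUCs are invariant
to it; it is applied for coefficient interpretability only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LogisticFit",
    "RocAnalysis",
    "DeLongComparison",
    "DayEvaluation",
    "normalize",
    "fit_logistic",
    "roc_auc",
    "delong_variance",
    "auc_ci",
    "delong_test",
    "cross_validate",
    "evaluate_panels",
]

POSITIVE_LABEL = "pathological"


# --------------------------------------------------------------------------
# feature preparation
# --------------------------------------------------------------------------

def normalize(features: pd.DataFrame) -> pd.DataFrame:
    """Per-column min-max scaling to [0, 1].

    Raises for constant columns (no spread to normalise), naming the marker.
    """
    out = {}
    for col in features.columns:
        v = features[col].to_numpy(dtype=float)
        lo, hi = v.min(), v.max()
        if hi <= lo:
            raise ValueError(f"marker {col!r} is constant; cannot normalise")
        out[col] = (v - lo) / (hi - lo)
    return pd.DataFrame(out, index=features.index)


# --------------------------------------------------------------------------
# logistic regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    markers: tuple[str, ...]
    intercept: float
    coefficients: pd.Series
    odds_ratios: pd.Series
    probabilities: np.ndarray
    deviance: float
    converged: bool
    separation_flag: bool


def _ridge_irls(design: np.ndarray, y01: np.ndarray, alpha: float = 1e-6,
                maxiter: int = 100) -> np.ndarray:
    """Weakly ridge-penalised IRLS, finite even under complete separation."""
    beta = np.zeros(design.shape[1])
    for _ in range(maxiter):
        eta = np.clip(design @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = design.T @ (y01 - mu) - alpha * beta
        hess = (design * w[:, None]).T @ design + alpha * np.eye(design.shape[1])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def fit_logistic(X: pd.DataFrame, y: np.ndarray, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic fit (Newton/IRLS, tol on coefficients).

    Complete or quasi-complete separation is detected (diverging
    coefficients / degenerate fitted probabilities) and flagged on the
    result rather than silently returned.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome must contain both classes")
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need more observations than predictors")
    y01 = (y == POSITIVE_LABEL).astype(float) if y.dtype.kind in "OUS" else y.astype(float)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y01, design).fit(
                method="newton", tol=tol, maxiter=200, disp=0
            )
            converged = bool(res.mle_retvals.get("converged", True))
            params = np.asarray(res.params, dtype=float)
            probs = np.asarray(res.predict(design), dtype=float)
        except Exception:  # (quasi-)separation: Newton Hessian degenerates
            separation = True
            converged = False
            params = _ridge_irls(design, y01)
            probs = 1.0 / (1.0 + np.exp(-design @ params))
    if np.max(np.abs(params)) > 1e3:  # diverging coefficients
        separation = True
    probs = np.clip(probs, 1e-12, 1 - 1e-12)
    llf = float(np.sum(y01 * np.log(probs) + (1 - y01) * np.log(1 - probs)))
    coef = pd.Series(params[1:], index=list(X.columns))
    return LogisticFit(
        markers=tuple(X.columns),
        intercept=float(params[0]),
        coefficients=coef,
        odds_ratios=np.exp(coef),
        probabilities=probs,
        deviance=-2.0 * llf,
        converged=converged,
        separation_flag=separation,
    )


# --------------------------------------------------------------------------
# ROC / AUC with DeLong placement values
# --------------------------------------------------------------------------

def _placements(scores: np.ndarray, y01: np.ndarray):
    """Midrank placement values V10 (cases) and V01 (controls), plus AUC."""
    pos = scores[y01 == 1]
    neg = scores[y01 == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    r_all = rankdata(np.concatenate([pos, neg]), method="average")
    r_pos = rankdata(pos, method="average")
    r_neg = rankdata(neg, method="average")
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n          # P(score_case > score_control)
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return auc, v10, v01


def _as01(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        return (labels == POSITIVE_LABEL).astype(int)
    return labels.astype(int)


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC points and Mann-Whitney (midrank) AUC.

    The midrank AUC equals the trapezoidal area under the empirical ROC
    curve; ties contribute 1/2 per tied case-control pair.
    Returns (fpr, tpr, auc).
    """
    y01 = _as01(labels)
    scores = np.asarray(scores, dtype=float)
    auc, _, _ = _placements(scores, y01)
    fpr, tpr, _ = roc_curve(y01, scores)
    return fpr, tpr, float(auc)


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance) for a single score vector."""
    y01 = _as01(labels)
    auc, v10, v01 = _placements(np.asarray(scores, dtype=float), y01)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, tuple[float, float], bool]:
    """Wald CI on the AUC scale with DeLong variance, clipped to [0, 1].

    Returns (auc, (lo, hi), degenerate_flag); a zero placement variance
    (e.g. perfect separation) yields the degenerate interval [auc, auc],
    flagged.
    """
    auc, var = delong_variance(scores, labels)
    if var <= 0:
        return auc, (auc, auc), True
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half)), False


@dataclass(frozen=True)
class DeLongComparison:
    panel_a: tuple[str, ...]
    panel_b: tuple[str, ...]
    auc_a: float
    auc_b: float
    diff: float
    z: float
    p: float
    degenerate: bool = False


def delong_test(scores_a, scores_b, labels) -> DeLongComparison:
    """DeLong's paired test for two correlated AUCs on the same labels.

    z = (auc_a - auc_b) / sqrt(var_a + var_b - 2 cov), two-sided normal p.
    A zero-variance difference with equal AUCs returns p = 1, flagged.
    """
    y01 = _as01(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y01.shape:
        raise ValueError("paired design requires equal-length score/label vectors")
    auc_a, v10a, v01a = _placements(a, y01)
    auc_b, v10b, v01b = _placements(b, y01)
    m, n = v10a.size, v01a.size
    s10 = np.cov(v10a, v10b, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01a, v01b, ddof=1) if n > 1 else np.zeros((2, 2))
    var_diff = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    diff = float(auc_a - auc_b)
    if var_diff <= 0:
        if abs(diff) < 1e-15:
            return DeLongComparison((), (), float(auc_a), float(auc_b), 0.0, 0.0, 1.0, True)
        # zero estimated variance but different AUCs: infinite z
        z = np.inf if diff > 0 else -np.inf
        return DeLongComparison((), (), float(auc_a), float(auc_b), diff, z, 0.0, True)
    z = diff / float(np.sqrt(var_diff))
    p = float(2.0 * norm.sf(abs(z)))
    return DeLongComparison((), (), float(auc_a), float(auc_b), diff, float(z), p)


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RocAnalysis:
    """Fitted panel with its ROC summary (optionally cross-validated)."""

    panel: tuple[str, ...]
    day: int
    intercept: float
    coefficients: pd.Series
    odds_ratios: pd.Series
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci95: tuple[float, float]
    deviance: float | None = None
    cross_validated: bool = False
    degenerate_ci: bool = False
    separation_flag: bool = False

    def to_record(self) -> dict:
        return {
            "panel": list(self.panel),
            "day": self.day,
            "intercept": self.intercept,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "odds_ratios": {k: float(v) for k, v in self.odds_ratios.items()},
            "auc": self.auc,
            "ci95": [self.ci95[0], self.ci95[1]],
            "deviance": self.deviance,
            "cross_validated": self.cross_validated,
            "roc_points": {
                "fpr": [float(v) for v in self.fpr],
                "tpr": [float(v) for v in self.tpr],
            },
        }


@dataclass
class DayEvaluation:
    day: int
    panels: list[RocAnalysis]
    comparisons: list[DeLongComparison]
    cv: RocAnalysis
    scores: dict[tuple[str, ...], np.ndarray] = field(default_factory=dict)

    def panel(self, *markers: str) -> RocAnalysis:
        key = tuple(markers)
        for p in self.panels:
            if p.panel == key:
                return p
        raise KeyError(key)


# --------------------------------------------------------------------------
# cross-validation and panel evaluation
# --------------------------------------------------------------------------

def cross_validate(
    X: pd.DataFrame, y: np.ndarray, k: int = 10, seed: int = 0, day: int = 0
) -> RocAnalysis:
    """Stratified k-fold CV; ROC/AUC from pooled out-of-fold probabilities.

    Every sample lands in exactly one test fold; fold sizes differ by at
    most one.  The pooled probabilities define a single CV ROC curve.
    """
    y = np.asarray(y)
    if len(X) < k:
        raise ValueError("need at least k observations")
    y01 = _as01(y)
    counts = np.bincount(y01, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"rarest class has {counts.min()} samples; stratified {k}-fold CV "
            f"needs at least {k} per class"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.empty(len(X), dtype=float)
    Xv = X.to_numpy(dtype=float)
    for train, test in skf.split(Xv, y01):
        fit = fit_logistic(X.iloc[train], y[train])
        design = sm.add_constant(Xv[test], has_constant="add")
        eta = design @ np.concatenate([[fit.intercept], fit.coefficients.to_numpy()])
        pooled[test] = 1.0 / (1.0 + np.exp(-eta))
    fpr, tpr, auc = roc_auc(pooled, y)
    _, ci, degen = auc_ci(pooled, y)
    return RocAnalysis(
        panel=tuple(X.columns),
        day=day,
        intercept=float("nan"),
        coefficients=pd.Series(dtype=float),
        odds_ratios=pd.Series(dtype=float),
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        ci95=ci,
        cross_validated=True,
        degenerate_ci=degen,
    )


def _panels(markers) -> list[tuple[str, ...]]:
    markers = tuple(markers)
    out = []
    for r in range(1, len(markers) + 1):
        out.extend(itertools.combinations(markers, r))
    return out


def evaluate_panels(
    marker_table: pd.DataFrame,
    labels: pd.DataFrame,
    days=(14, 21),
    markers=("I10", "T1", "FN"),
    cv_folds: int = 10,
    seed: int = 0,
) -> dict[int, DayEvaluation]:
    """Fit all marker panels per day and compare them.

    For the default three markers this gives 7 panels per day (3 singles,
    3 pairs, 1 triple), C(7,2)=21 pairwise DeLong comparisons per day, and a
    stratified tenfold-CV ROC for the full panel.  All successful draws with
    a binary label enter the regression (the four-way exclusion applies only
    to the distribution screen).  Raw DeLong p-values are reported without
    multiplicity correction.
    """
    merged = marker_table.merge(labels[["draw_id", "binary"]], on="draw_id")
    y = merged["binary"].to_numpy()
    results: dict[int, DayEvaluation] = {}
    for day in days:
        cols = {mk: f"{mk}_d{day}" for mk in markers}
        missing = [c for c in cols.values() if c not in merged.columns]
        if missing:
            raise ValueError(f"marker table lacks columns {missing}")
        feats = normalize(merged[list(cols.values())].rename(
            columns={v: k for k, v in cols.items()}
        ))
        panel_results: list[RocAnalysis] = []
        scores: dict[tuple[str, ...], np.ndarray] = {}
        for panel in _panels(markers):
            fit = fit_logistic(feats[list(panel)], y)
            fpr, tpr, auc = roc_auc(fit.probabilities, y)
            _, ci, degen = auc_ci(fit.probabilities, y)
            scores[panel] = fit.probabilities
            panel_results.append(
                RocAnalysis(
                    panel=panel,
                    day=int(day),
                    intercept=fit.intercept,
                    coefficients=fit.coefficients,
                    odds_ratios=fit.odds_ratios,
                    fpr=fpr,
                    tpr=tpr,
                    auc=auc,
                    ci95=ci,
                    deviance=fit.deviance,
                    degenerate_ci=degen,
                    separation_flag=fit.separation_flag,
                )
            )
        comparisons = []
        for pa, pb in itertools.combinations(scores.keys(), 2):
            cmp_ = delong_test(scores[pa], scores[pb], y)
            comparisons.append(
                DeLongComparison(
                    panel_a=pa,
                    panel_b=pb,
                    auc_a=cmp_.auc_a,
                    auc_b=cmp_.auc_b,
                    diff=cmp_.diff,
                    z=cmp_.z,
                    p=cmp_.p,
                    degenerate=cmp_.degenerate,
                )
            )
        cv = cross_validate(
            feats[list(markers)], y, k=cv_folds, seed=seed, day=int(day)
        )
        results[int(day)] = DayEvaluation(
            day=int(day),
            panels=panel_results,
            comparisons=comparisons,
            cv=cv,
            scores=scores,
        )
    return results
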