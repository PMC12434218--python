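"""Logistic regression for the Day +100 >=PN endpoint.

Bivariable and multivariable logistic models over the allogeneic subset:
maximum likelihood via iteratively reweighted least squares (IRLS), Wald
covariance from the inverse observed information, odds ratios with 95%
CIs, the per-100-unit odds-ratio transform for the score, ROC/AUC
discrimination, and plot-ready forest-plot rows.

Reference coding follows the published model: female, age 2-12, malignant
disease, cord-blood source and no-TBI are the reference levels, and the
score enters untransformed per unit.  Complete or quasi-complete
separation is detected and raised explicitly rather than returning huge
unstable estimates; a Firth (Jeffreys-prior) penalised fit is available as
a fallback flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_curve as _sk_roc_curve

from .scoring import (
    DEFAULT_WINDOW,
    PatientRecord,
    ScoreResult,
    ScoreWindow,
    SupportLevel,
    ValidationError,
    pn_outcome_at,
)
from .synthetic_cohort import covariate_dummy

__all__ = [
    "DesignSpec",
    "LogisticFit",
    "ROCResult",
    "DesignError",
    "SeparationError",
    "build_design",
    "fit_logistic",
    "bivariable_screen",
    "or_per_scale",
    "roc_curve",
    "forest_plot_data",
]

#: Predictor terms in published-table order.
DEFAULT_TERMS = (
    "male",
    "under2",
    "over12",
    "nonmalignant",
    "other_source",
    "tbi",
    "auc",
)


class DesignError(ValueError):
    """Raised when the design matrix cannot be built (rank/constancy problems)."""


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximiser (data separation)."""


@dataclass(frozen=True)
class DesignSpec:
    """Outcome and predictor set, with reference coding fixed by construction.

    Dummies: male (ref female), under2 and over12 (ref age 2-12),
    nonmalignant (ref malignant), other_source (ref cord blood), tbi
    (ref no TBI); ``auc`` is the continuous score per unit.
    """

    outcome: str = "pn_at_day100"
    terms: tuple[str, ...] = DEFAULT_TERMS

    def __post_init__(self) -> None:
        unknown = [t for t in self.terms if t not in DEFAULT_TERMS]
        if unknown:
            raise ValidationError(f"unknown predictor terms: {unknown}")
        if len(set(self.terms)) != len(self.terms):
            raise ValidationError("duplicate predictor terms")


@dataclass
class LogisticFit:
    """Coefficients, covariance and Wald inference for one logistic model."""

    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    iterations: int
    log_likelihood: float
    n_obs: int
    firth: bool = False

    @property
    def summary(self) -> pd.DataFrame:
        """Per-term estimate, OR, 95% Wald CI and p-value."""
        est = self.params.to_numpy()
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        z = est / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        zcrit = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": est,
                "std_error": se,
                "odds_ratio": np.exp(est),
                "ci_low": np.exp(est - zcrit * se),
                "ci_high": np.exp(est + zcrit * se),
                "p_value": p,
            }
        ).set_index("term")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return expit(X.to_numpy() @ self.params.to_numpy())


@dataclass(frozen=True)
class ROCResult:
    """ROC points (monotone, anchored at (0,0) and (1,1)) and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc_roc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc_roc <= 1.0:
            raise ValidationError("auc_roc outside [0, 1]")


def build_design(
    records: Sequence[PatientRecord],
    scores: Sequence[ScoreResult],
    spec: DesignSpec = DesignSpec(),
    window: ScoreWindow = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Dummy-coded design matrix (with intercept) and outcome vector.

    Restricted to the allogeneic subset (the model is defined on the
    conditioning covariates); records of other modalities are dropped.
    A constant predictor column raises :class:`DesignError` naming it.
    """
    by_id = {s.patient_id: s for s in scores}
    rows, y = [], []
    for rec in records:
        prof = rec.covariates
        if prof is None or prof.transplant_type != "allogeneic":
            continue
        score = by_id.get(rec.patient_id)
        if score is None:
            raise DesignError(f"no score for patient {rec.patient_id}")
        row = {"intercept": 1.0}
        for term in spec.terms:
            row[term] = score.auc if term == "auc" else covariate_dummy(prof, term)
        rows.append(row)
        y.append(float(pn_outcome_at(rec, window=window)))
    if not rows:
        raise DesignError("no allogeneic records to model")
    X = pd.DataFrame(rows)
    outcome = np.array(y)
    for col in X.columns:
        if col != "intercept" and X[col].nunique() <= 1:
            raise DesignError(f"predictor {col!r} is constant in this cohort")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError("design matrix is rank-deficient")
    return X, outcome


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    tol: float,
    max_iter: int,
    firth: bool,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        info = X.T @ (X * w[:, None])
        resid = y - mu
        if firth:
            # Jeffreys-prior score adjustment: shrink via hat-matrix leverages
            try:
                xw = X * np.sqrt(w)[:, None]
                h = np.einsum(
                    "ij,ij->i", xw @ np.linalg.inv(info), xw
                )
            except np.linalg.LinAlgError as exc:
                raise SeparationError("information matrix singular") from exc
            resid = resid + h * (0.5 - mu)
        score = X.T @ resid
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix singular (possible separation)"
            ) from exc
        beta = beta + delta
        if np.max(np.abs(beta)) > 40.0 and not firth:
            raise SeparationError(
                "coefficients diverging: data are (quasi-)separated"
            )
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov, converged, it


def fit_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    firth: bool = False,
) -> LogisticFit:
    """Maximum-likelihood logistic fit via IRLS with Wald covariance.

    Convergence: max absolute coefficient change < ``tol`` within
    ``max_iter`` Newton steps.  Separated data raise
    :class:`SeparationError`; re-fit with ``firth=True`` for a finite
    penalised estimate.  The outcome must contain both classes.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome has a single class; model is undefined")
    Xm = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise DesignError("design matrix is rank-deficient")
    beta, cov, converged, it = _irls(Xm, y, tol, max_iter, firth)
    mu = expit(Xm @ beta)
    eps = np.finfo(float).tiny
    loglik = float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
    return LogisticFit(
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        converged=converged,
        iterations=it,
        log_likelihood=loglik,
        n_obs=len(y),
        firth=firth,
    )


def or_per_scale(
    fit: LogisticFit, term: str, scale: float = 100.0
) -> dict[str, float]:
    """Odds ratio (with CI) per ``scale`` units of a continuous term.

    exp(scale * beta) and exp(scale * CI bounds); with scale 1 this is the
    per-unit OR.  Computed from the unrounded coefficient.
    """
    if term not in fit.params.index:
        raise ValidationError(f"term {term!r} not in fit")
    row = fit.summary.loc[term]
    return {
        "term": term,
        "scale": scale,
        "odds_ratio": float(np.exp(scale * row["estimate"])),
        "ci_low": float(np.exp(scale * np.log(row["ci_low"]))),
        "ci_high": float(np.exp(scale * np.log(row["ci_high"]))),
        "p_value": float(row["p_value"]),
    }


def bivariable_screen(
    records: Sequence[PatientRecord],
    scores: Sequence[ScoreResult],
    spec: DesignSpec = DesignSpec(),
    window: ScoreWindow = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Unadjusted (single-predictor) OR/CI/p per term.

    Each term is fitted alone against the outcome; terms whose fit fails
    (separation, constancy) are flagged in the ``error`` column while the
    rest are still returned.
    """
    frames = []
    for term in spec.terms:
        sub = DesignSpec(outcome=spec.outcome, terms=(term,))
        try:
            X, y = build_design(records, scores, sub, window)
            fit = fit_logistic(X, y)
            row = fit.summary.loc[term].to_dict()
            row.update(term=term, error="")
        except (DesignError, SeparationError, ValidationError) as exc:
            row = {
                "term": term,
                "estimate": np.nan,
                "std_error": np.nan,
                "odds_ratio": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p_value": np.nan,
                "error": str(exc),
            }
        frames.append(row)
    return pd.DataFrame(frames).set_index("term")


def roc_curve(
    fitted_probabilities: Sequence[float], outcomes: Sequence[float]
) -> ROCResult:
    """ROC points and trapezoidal AUC for fitted probabilities vs outcomes.

    Equal scores are grouped into a single step, so the curve (and its
    trapezoidal area) equals the Mann-Whitney U statistic scaled by
    n1*n0; constant scores therefore give AUC 0.5.
    """
    p = np.asarray(fitted_probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValidationError("both outcome classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y, p, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc_roc=auc)


def forest_plot_data(
    fit: LogisticFit, include_intercept: bool = False
) -> pd.DataFrame:
    """Plot-ready per-term rows (OR, CI, p) in published-table order.

    The returned frame carries ``attrs['log_scale'] = True`` as a hint
    that odds ratios belong on a logarithmic axis.
    """
    if not fit.converged:
        raise ValidationError("fit did not converge; refusing to plot")
    table = fit.summary.reset_index()
    order = ["intercept", *DEFAULT_TERMS]
    table["__order"] = table["term"].map({t: i for i, t in enumerate(order)})
    table = table.sort_values("__order").drop(columns="__order")
    if not include_intercept:
        table = table[table["term"] != "intercept"]
    out = table[["term", "odds_ratio", "ci_low", "ci_high", "p_value"]].reset_index(
        drop=True
    )
    out.attrs["log_scale"] = True
    return out
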