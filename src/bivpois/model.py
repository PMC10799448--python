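"""Bivariate Poisson regression with log-link marginal models.

The parallel (non-exchangeable) model gives each margin its own
coefficient vector over a shared design matrix:

.. math::

    \\log \\theta_{i1} = x_i^T \\beta_1, \\qquad
    \\log \\theta_{i2} = x_i^T \\beta_2, \\qquad
    \\theta_3 \\ge 0,

with the dependence rate ``theta3`` treated as a nuisance parameter: the
regression coefficients are estimated first by maximising the joint
log-likelihood at ``theta3 = 0`` (equivalent to two independent log-link
Poisson fits, done here by Newton iterations with step-halving), and a
constant ``theta3`` can optionally be profiled afterwards with the
coefficients held fixed.  Standard errors come from the inverse observed
information per margin; p-values are two-sided Wald normal tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm
from sklearn.base import BaseEstimator

from scipy.special import logsumexp

from .design import DesignEncoder, ModelSpec, encode_design

__all__ = [
    "BivPoisParams",
    "FitResult",
    "BivariatePoissonRegression",
    "log_likelihood",
    "score",
    "fit",
    "predict_means",
    "aic",
]

_ETA_MAX = 30.0  # |x'beta| beyond this means exp() is astronomically off-scale


@dataclass
class BivPoisParams:
    """Coefficients for both margins plus the nuisance dependence rate."""

    beta1: np.ndarray
    beta2: np.ndarray
    theta3: float = 0.0

    def __post_init__(self):
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        if self.theta3 < 0:
            raise ValueError("theta3 must be >= 0")


@dataclass
class FitResult:
    """A fitted bivariate Poisson regression.

    ``std_errors`` and ``wald_p`` concatenate margin 1 then margin 2 in
    design-column order; ``aic`` always satisfies ``-2*loglik + 2*n_params``.
    """

    params: BivPoisParams
    fitted_mean1: np.ndarray
    fitted_mean2: np.ndarray
    loglik: float
    n_params: int
    aic: float
    std_errors: np.ndarray
    wald_p: np.ndarray
    n_used: int
    converged: bool
    term_names: list[str]
    spec: ModelSpec
    encoder: DesignEncoder
    n_dropped: int = 0

    def coefficient_table(self) -> pd.DataFrame:
        """Long-format coefficient table: margin, term, estimate, SE, p."""
        p = len(self.term_names)
        rows = []
        for m, beta in ((1, self.params.beta1), (2, self.params.beta2)):
            off = (m - 1) * p
            name = self.spec.outcome1 if m == 1 else self.spec.outcome2
            for j, term in enumerate(self.term_names):
                rows.append(
                    {
                        "margin": name,
                        "term": term,
                        "estimate": beta[j],
                        "std_error": self.std_errors[off + j],
                        "p_value": self.wald_p[off + j],
                    }
                )
        return pd.DataFrame(rows)


def _linear_predictor(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    eta = X @ beta
    if np.any(np.abs(eta) > _ETA_MAX):
        raise FloatingPointError(
            f"linear predictor exceeds |{_ETA_MAX}|; the exponentiated mean "
            "would overflow — consider rescaling or centring covariates"
        )
    return eta


def log_likelihood(params: BivPoisParams, X: np.ndarray, y1, y2) -> float:
    """Joint log-likelihood sum_i log f(y_i1, y_i2 | theta_i1, theta_i2, theta3)."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    mu1 = np.exp(_linear_predictor(X, params.beta1))
    mu2 = np.exp(_linear_predictor(X, params.beta2))
    base = (
        y1 * np.log(mu1)
        - mu1
        - gammaln(y1 + 1)
        + y2 * np.log(mu2)
        - mu2
        - gammaln(y2 + 1)
    )
    if params.theta3 == 0.0:
        # independent-Poisson shortcut: only the k = 0 term survives
        return float(base.sum())
    logS = _ksum_log(y1, y2, mu1, mu2, params.theta3)
    # base already carries -log(y1!)-log(y2!), which is the k=0 term of logS
    extra = logS + gammaln(y1 + 1) + gammaln(y2 + 1)
    return float(np.sum(base - params.theta3 + extra))


def _ksum_terms(y1, y2, mu1, mu2, theta3):
    """(n, K+1) matrix of log k-sum terms with invalid k masked to -inf."""
    m = np.minimum(y1, y2).astype(int)
    K = int(m.max())
    k = np.arange(K + 1)[None, :]
    valid = k <= m[:, None]
    with np.errstate(invalid="ignore"):
        logt = (
            k * (np.log(theta3) - np.log(mu1)[:, None] - np.log(mu2)[:, None])
            - gammaln(k + 1)
            - gammaln(np.where(valid, y1[:, None] - k, 0) + 1)
            - gammaln(np.where(valid, y2[:, None] - k, 0) + 1)
        )
    return np.where(valid, logt, -np.inf), k


def _ksum_log(y1, y2, mu1, mu2, theta3) -> np.ndarray:
    logt, _ = _ksum_terms(y1, y2, mu1, mu2, theta3)
    return logsumexp(logt, axis=1)


def _ksum_mean(y1, y2, mu1, mu2, theta3) -> np.ndarray:
    """Posterior mean of the shared index k per record (0 when theta3 = 0)."""
    if theta3 == 0.0:
        return np.zeros(len(y1))
    logt, k = _ksum_terms(y1, y2, mu1, mu2, theta3)
    peak = logt.max(axis=1, keepdims=True)
    t = np.exp(logt - peak)
    return (t * k).sum(axis=1) / t.sum(axis=1)


def score(params: BivPoisParams, X: np.ndarray, y1, y2) -> np.ndarray:
    """Score vector of the joint log-likelihood over (beta1, beta2).

    Each margin's block is ``X'(y_j - theta_j - w)`` where ``w`` is the
    per-record posterior mean of the shared index ``k``; at ``theta3 = 0``
    this reduces to the ordinary Poisson GLM score ``X'(y_j - theta_j)``.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    mu1 = np.exp(_linear_predictor(X, params.beta1))
    mu2 = np.exp(_linear_predictor(X, params.beta2))
    w = _ksum_mean(y1, y2, mu1, mu2, params.theta3)
    g1 = X.T @ (y1 - mu1 - w)
    g2 = X.T @ (y2 - mu2 - w)
    return np.concatenate([g1, g2])


def _newton_poisson(
    X: np.ndarray, y: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximise a log-link Poisson log-likelihood by Newton with step-halving.

    Returns ``(beta, standard_errors, converged)``.
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(y.mean() + 0.1)  # assumes column 0 is the intercept

    def loglik(b):
        eta = _linear_predictor(X, b)
        mu = np.exp(eta)
        return float(np.sum(y * eta - mu - gammaln(y + 1)))

    ll = loglik(beta)
    converged = False
    for _ in range(max_iter):
        mu = np.exp(_linear_predictor(X, beta))
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) / n < tol:
            converged = True
            break
        info = X.T @ (X * mu[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "singular information matrix — check for collinear or "
                "degenerate design columns"
            ) from e
        # step-halving keeps the ascent monotone
        lam = 1.0
        for _ in range(40):
            cand = beta + lam * step
            try:
                ll_new = loglik(cand)
            except FloatingPointError:
                lam *= 0.5
                continue
            if ll_new >= ll - 1e-12:
                beta, ll = cand, ll_new
                break
            lam *= 0.5
        else:
            break
        if np.max(np.abs(beta)) > _ETA_MAX:
            raise FloatingPointError(
                "coefficients diverged (|beta| > 30) — quasi-separation or an "
                "unscaled covariate is the usual cause"
            )
    mu = np.exp(_linear_predictor(X, beta))
    info = X.T @ (X * mu[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se, converged


def _profile_theta3(X, y1, y2, beta1, beta2, grid_size: int = 101) -> float:
    """Maximise the joint log-likelihood over a constant theta3 >= 0, beta fixed."""
    upper = max(1e-6, min(np.mean(y1), np.mean(y2)))

    def negll(t3):
        return -log_likelihood(BivPoisParams(beta1, beta2, t3), X, y1, y2)

    grid = np.linspace(0.0, upper, grid_size)
    vals = np.array([negll(t) for t in grid])
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid_size - 1)]
    if hi <= lo:
        return float(grid[j])
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded")
    cands = [(negll(0.0), 0.0), (vals[j], grid[j]), (res.fun, float(res.x))]
    return float(min(cands)[1])


class BivariatePoissonRegression(BaseEstimator):
    """Bivariate Poisson regression over two count outcomes.

    Scikit-learn style estimator: ``fit(X, y)`` takes a covariate DataFrame
    ``X`` and an ``(n, 2)`` array (or two-column DataFrame) of counts ``y``
    in the order (outcome 1, outcome 2).

    Parameters
    ----------
    spec : ModelSpec
        Covariate encoding plan (kinds and reference categories).
    estimate_theta3 : bool, default False
        After the marginal fits, profile a constant common-shock rate
        ``theta3 >= 0`` with the coefficients held fixed; adds one counted
        parameter.
    tol : float, default 1e-8
        Convergence tolerance on the maximum component of the score divided
        by the sample size.
    max_iter : int, default 100
        Newton iteration cap per margin.

    Attributes
    ----------
    coef_ : ndarray of shape (2, p)
        Fitted coefficients (rows: margin 1, margin 2).
    theta3_ : float
        Dependence rate (0 unless ``estimate_theta3``).
    loglik_, aic_ : float
        Joint log-likelihood and Akaike information criterion.
    result_ : FitResult
        The full fit record, including the coefficient table.
    """

    def __init__(
        self,
        spec: ModelSpec | None = None,
        estimate_theta3: bool = False,
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        self.spec = spec
        self.estimate_theta3 = estimate_theta3
        self.tol = tol
        self.max_iter = max_iter

    def _records_from_xy(self, X: pd.DataFrame, y) -> pd.DataFrame:
        spec = self.spec
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of covariate columns")
        records = X.copy()
        if isinstance(y, pd.DataFrame):
            records[spec.outcome1] = y.iloc[:, 0].to_numpy()
            records[spec.outcome2] = y.iloc[:, 1].to_numpy()
        else:
            y = np.asarray(y)
            if y.ndim != 2 or y.shape[1] != 2:
                raise ValueError("y must have shape (n, 2): two count outcomes")
            records[spec.outcome1] = y[:, 0]
            records[spec.outcome2] = y[:, 1]
        return records

    def fit(self, X: pd.DataFrame, y) -> "BivariatePoissonRegression":
        if self.spec is None:
            raise ValueError("a ModelSpec is required")
        records = self._records_from_xy(X, y)
        self.result_ = fit(
            records,
            self.spec,
            estimate_theta3=self.estimate_theta3,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        r = self.result_
        self.coef_ = np.vstack([r.params.beta1, r.params.beta2])
        self.theta3_ = r.params.theta3
        self.loglik_ = r.loglik
        self.aic_ = r.aic
        self.converged_ = r.converged
        self.feature_names_ = list(r.term_names)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Per-record fitted means, shape ``(n, 2)``."""
        mu1, mu2 = predict_means(self.result_, X)
        return np.column_stack([mu1, mu2])

    def score(self, X: pd.DataFrame, y) -> float:
        """Mean joint log-likelihood per record (higher is better)."""
        records = self._records_from_xy(X, y)
        Xd, y1, y2, _, _ = self.result_.encoder.transform(records)
        return log_likelihood(self.result_.params, Xd, y1, y2) / len(y1)


def fit(
    records: pd.DataFrame,
    spec: ModelSpec,
    estimate_theta3: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Fit the parallel bivariate Poisson regression to woman-level records.

    The two marginal log-link models are maximised with ``theta3`` fixed at
    zero; when ``estimate_theta3`` is true a constant ``theta3`` is then
    profiled on a grid with the coefficients fixed.
    """
    X, y1, y2, encoder, n_dropped = encode_design(records, spec)
    if len(y1) == 0:
        raise ValueError("no complete-case records to fit")
    for name, y in ((spec.outcome1, y1), (spec.outcome2, y2)):
        if y.max() == 0:
            raise ValueError(f"outcome {name!r} has no positive counts")

    b1, se1, conv1 = _newton_poisson(X, y1, tol, max_iter)
    b2, se2, conv2 = _newton_poisson(X, y2, tol, max_iter)
    theta3 = 0.0
    n_params = 2 * X.shape[1]
    if estimate_theta3:
        theta3 = _profile_theta3(X, y1, y2, b1, b2)
        n_params += 1

    params = BivPoisParams(b1, b2, theta3)
    ll = log_likelihood(params, X, y1, y2)
    se = np.concatenate([se1, se2])
    z = np.concatenate([b1, b2]) / se
    pvals = 2.0 * norm.sf(np.abs(z))
    return FitResult(
        params=params,
        fitted_mean1=np.exp(X @ b1),
        fitted_mean2=np.exp(X @ b2),
        loglik=ll,
        n_params=n_params,
        aic=aic(ll, n_params),
        std_errors=se,
        wald_p=pvals,
        n_used=len(y1),
        converged=conv1 and conv2,
        term_names=list(encoder.columns_),
        spec=spec,
        encoder=encoder,
        n_dropped=n_dropped,
    )


def predict_means(fit_result: FitResult, records: pd.DataFrame):
    """Fitted marginal means ``exp(x'beta_j)`` for new records."""
    X, _, _, _, _ = fit_result.encoder.transform(records, require_outcomes=False)
    return np.exp(X @ fit_result.params.beta1), np.exp(X @ fit_result.params.beta2)


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, ``-2*loglik + 2*n_params``."""
    return -2.0 * loglik + 2.0 * n_params
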