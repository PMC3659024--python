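"""REML animal models over arbitrary lists of covariance structures.

The animal model is a mixed linear model ``y = X b + sum_k u_k + e`` in which
each random vector ``u_k`` has covariance ``sigma2_k * K_k`` for a known
structure matrix ``K_k`` — the additive genetic relationship matrix ``A``,
a cultural relationship matrix ``C``, their Hadamard interaction, or a
block-diagonal grouping structure (maternal identity, rearing brood,
environment) — and ``e`` is i.i.d. residual noise.  Variance components are
estimated by restricted maximum likelihood (REML), i.e. by maximizing

    l_R = -1/2 [ (n-p) log 2*pi + log|V| + log|X' V^-1 X| + y' P y ],

where ``V = sum_k sigma2_k K_k + sigma2_R I`` and ``P`` is the REML
projection ``V^-1 - V^-1 X (X'V^-1X)^-1 X' V^-1``.  Heritability ratios,
boundary-corrected likelihood-ratio tests for single components and AIC
model comparison are built on top.

:class:`AnimalModel` is a scikit-learn style estimator (``fit`` /
``get_params`` / fitted attributes with trailing underscores); the
module-level functions are thin wrappers kept for script use.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .relmatrix import PSD_EPSILON, RelationshipMatrix

_LOG2PI = float(np.log(2.0 * np.pi))
#: bounds for log variance ratios during optimization; the lower bound acts
#: as the (numerically indistinguishable from zero) boundary of the
#: nonnegative orthant
_LOG_RATIO_MIN, _LOG_RATIO_MAX = -18.0, 12.0


# ---------------------------------------------------------------------------
# restricted likelihood
# ---------------------------------------------------------------------------

def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def restricted_loglik(y: Sequence[float], X, K_list: Sequence[np.ndarray],
                      variances: Sequence[float]) -> float:
    """REML log-likelihood at the given variances.

    ``variances`` holds one variance per structure in ``K_list`` followed by
    the residual variance.  The constant ``-(n-p)/2 * log(2*pi)`` is
    included.  Raises on a rank-deficient fixed design or a non-positive-
    definite ``V``.
    """
    y = np.asarray(y, dtype=float)
    X = _as_2d(X)
    n, p = X.shape
    variances = [float(v) for v in variances]
    if len(variances) != len(K_list) + 1:
        raise ValueError("need one variance per structure plus residual")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("fixed-effect design is rank deficient")
    V = variances[-1] * np.eye(n)
    for s2, K in zip(variances[:-1], K_list):
        V += s2 * np.asarray(K, dtype=float)
    from scipy.linalg import cho_factor, cho_solve

    cf = cho_factor(V, lower=True)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ViX = cho_solve(cf, X)
    Viy = cho_solve(cf, y)
    XtViX = X.T @ ViX
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    ytPy = float(y @ Viy - (X.T @ Viy) @ beta)
    return -0.5 * ((n - p) * _LOG2PI + logdet_V + logdet_XtViX + ytPy)


class _REMLProblem:
    """Profiled REML: residual variance concentrated out analytically.

    With ``V = sigma2_R * (sum_k gamma_k K_k + I)`` the residual variance has
    the closed-form maximizer ``y'P_G y / (n - p)``, leaving an optimization
    over the ``m`` log variance ratios only.
    """

    def __init__(self, y, X, K_list):
        self.y = np.asarray(y, dtype=float)
        self.X = _as_2d(X)
        self.K = [np.asarray(K, dtype=float) for K in K_list]
        self.n, self.p = self.X.shape
        if np.linalg.matrix_rank(self.X) < self.p:
            raise np.linalg.LinAlgError(
                "fixed-effect design is rank deficient"
            )
        self.I = np.eye(self.n)

    def _pieces(self, log_gamma):
        from scipy.linalg import cho_factor, cho_solve

        G = self.I.copy()
        for lg, K in zip(log_gamma, self.K):
            G += np.exp(lg) * K
        try:
            cf = cho_factor(G, lower=True)
        except np.linalg.LinAlgError:
            cf = cho_factor(G + PSD_EPSILON * self.I, lower=True)
        logdet_G = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        GiX = cho_solve(cf, self.X)
        Giy = cho_solve(cf, self.y)
        XtGiX = self.X.T @ GiX
        sign, logdet_XtGiX = np.linalg.slogdet(XtGiX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'G^-1X not positive definite")
        beta = np.linalg.solve(XtGiX, self.X.T @ Giy)
        ytPy = float(self.y @ Giy - (self.X.T @ Giy) @ beta)
        return logdet_G, logdet_XtGiX, ytPy, beta

    def negloglik(self, log_gamma) -> float:
        try:
            logdet_G, logdet_XtGiX, ytPy, _ = self._pieces(log_gamma)
        except np.linalg.LinAlgError:
            return np.inf
        df = self.n - self.p
        if ytPy <= 0:
            return np.inf
        s2r = ytPy / df
        return 0.5 * (df * _LOG2PI + df * np.log(s2r) + df
                      + logdet_G + logdet_XtGiX)

    def solution(self, log_gamma):
        logdet_G, _, ytPy, beta = self._pieces(log_gamma)
        s2r = ytPy / (self.n - self.p)
        sigma2 = [float(np.exp(lg) * s2r) for lg in log_gamma]
        return sigma2, float(s2r), beta


# ---------------------------------------------------------------------------
# fit result container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Converged (or best-found) REML solution for one model."""

    estimates: dict[str, float]
    fixed_estimates: dict[str, float]
    loglik_restricted: float
    aic: float
    se: dict[str, float] | None
    converged: bool
    n_used: int
    term_names: tuple[str, ...]
    fixed_names: tuple[str, ...]
    data_hash: str
    vcov: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_variance_parameters(self) -> int:
        return len(self.estimates)


def _data_hash(y: np.ndarray, X: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class AnimalModel(BaseEstimator):
    """Variance-component animal model fitted by direct REML maximization.

    Parameters
    ----------
    random_effects :
        Mapping from term name to a :class:`RelationshipMatrix` (e.g.
        ``{"A": additive, "C": cultural}``); each matrix is aligned to the
        phenotyped individuals at fit time.
    group_effects :
        Column names of ``X`` treated as i.i.d. grouping random effects
        (``K = Z Z'`` with Z the membership indicator), e.g. maternal id or
        rearing brood.
    fixed_effects :
        Column names of ``X`` entering the fixed design; numeric columns
        are used as-is, non-numeric ones are dummy-encoded (first level as
        reference).  An intercept is always included.
    n_restarts :
        Number of seeded optimizer starts (the first from equal variance
        ratios, the rest perturbed); stops early once two starts agree.
    tol :
        Convergence tolerance on the relative change of the restricted
        log-likelihood.
    compute_se :
        Whether to compute standard errors from the observed information
        (numerical Hessian on the variance scale, invertible case only).

    Attributes
    ----------
    variance_components_ : dict  — REML estimates, residual included.
    fixed_effects_ : dict — GLS fixed-effect coefficients at the optimum.
    loglik_ : float — restricted log-likelihood at the optimum.
    aic_ : float — ``-2 loglik + 2 * (number of variance parameters)``
        (fixed effects excluded under REML).
    se_ : dict or None — standard errors of the variance components.
    converged_ : bool — optimizer success on the best start.
    n_used_ : int — number of phenotyped records used.
    result_ : FitResult — everything above in one container.
    """

    def __init__(self, random_effects: Mapping[str, RelationshipMatrix]
                 | None = None,
                 group_effects: Sequence[str] = (),
                 fixed_effects: Sequence[str] = (),
                 n_restarts: int = 3,
                 max_iter: int = 500,
                 tol: float = 1e-8,
                 compute_se: bool = True,
                 random_state: int = 0):
        self.random_effects = random_effects
        self.group_effects = group_effects
        self.fixed_effects = fixed_effects
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.compute_se = compute_se
        self.random_state = random_state

    # -- design assembly ----------------------------------------------------
    def _design(self, X: pd.DataFrame):
        ids = [str(i) for i in
               (X["id"] if "id" in X.columns else X.index)]
        cols = [np.ones(len(ids))]
        names = ["intercept"]
        for c in self.fixed_effects:
            col = X[c]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
                names.append(c)
            else:
                dummies = pd.get_dummies(col.astype(str), prefix=c,
                                         drop_first=True)
                for dc in dummies.columns:
                    cols.append(dummies[dc].to_numpy(dtype=float))
                    names.append(dc)
        design = np.column_stack(cols)

        K_list, term_names = [], []
        for name, mat in (self.random_effects or {}).items():
            K_list.append(mat.subset(ids).values)
            term_names.append(name)
        for c in self.group_effects:
            codes = pd.Categorical(X[c].astype(str)).codes
            Z = (codes[:, None] == np.unique(codes)[None, :]).astype(float)
            K_list.append(Z @ Z.T)
            term_names.append(c)
        return ids, design, names, K_list, term_names

    # -- fitting ------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "AnimalModel":
        """Fit the model; ``X`` carries ids, covariates and groupings."""
        y = np.asarray(y, dtype=float)
        ids, design, fixed_names, K_list, term_names = self._design(X)
        if len(y) != len(ids):
            raise ValueError("y length does not match X rows")
        n, p = design.shape
        m = len(K_list)
        if n < p + m + 1:
            raise ValueError("fewer records than parameters to estimate")
        prob = _REMLProblem(y, design, K_list)

        if m == 0:
            s2r, beta = _closed_form_residual(prob)
            sigma2 = []
            best_ll = restricted_loglik(y, design, [], [s2r])
            converged = True
        else:
            rng = np.random.default_rng(self.random_state)
            starts = [rng.uniform(-2.0, 2.0, size=m)
                      for _ in range(max(1, self.n_restarts))]
            best = None
            for x0 in starts:
                res = optimize.minimize(
                    prob.negloglik, x0, method="Nelder-Mead",
                    options=dict(maxiter=self.max_iter * max(1, m),
                                 fatol=self.tol * max(1.0, n),
                                 xatol=1e-6),
                )
                res.x = np.clip(res.x, _LOG_RATIO_MIN, _LOG_RATIO_MAX)
                res.fun = prob.negloglik(res.x)
                if best is None:
                    best = res
                    continue
                agree = abs(res.fun - best.fun) \
                    <= 1e-6 * max(1.0, abs(best.fun))
                if res.fun < best.fun:
                    best = res
                if agree:
                    break  # two starts agree on the optimum: accept
            best_x = best.x
            converged = bool(best.success) and np.isfinite(best.fun)
            sigma2, s2r, beta = prob.solution(best_x)
            best_ll = -float(best.fun)

        estimates = dict(zip(term_names, sigma2))
        estimates["residual"] = s2r
        se = vcov = None
        if self.compute_se:
            se, vcov = _observed_information_se(
                y, design, K_list, list(sigma2) + [s2r],
                list(estimates.keys())
            )
        aic = -2.0 * best_ll + 2.0 * len(estimates)

        self.ids_ = tuple(ids)
        self.term_names_ = tuple(term_names)
        self.variance_components_ = estimates
        self.fixed_effects_ = dict(zip(fixed_names, map(float, beta)))
        self.loglik_ = float(best_ll)
        self.aic_ = float(aic)
        self.se_ = se
        self.vcov_ = vcov
        self.converged_ = converged
        self.n_used_ = int(n)
        self._design_matrix = design
        self.result_ = FitResult(
            estimates=estimates,
            fixed_estimates=self.fixed_effects_,
            loglik_restricted=self.loglik_,
            aic=self.aic_,
            se=se,
            converged=converged,
            n_used=n,
            term_names=tuple(list(term_names) + ["residual"]),
            fixed_names=tuple(fixed_names),
            data_hash=_data_hash(y, design),
            vcov=vcov,
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Fixed-effect (population-mean) prediction for new records."""
        _, design, names, _, _ = self._design(X)
        beta = np.array([self.fixed_effects_.get(n, 0.0) for n in names])
        return design @ beta

    def heritability(self) -> dict[str, float]:
        return heritabilities(self.result_)


def _closed_form_residual(prob: _REMLProblem):
    """Residual-only model: REML variance with the n - p denominator."""
    Q, _ = np.linalg.qr(prob.X)
    resid = prob.y - Q @ (Q.T @ prob.y)
    s2 = float(resid @ resid) / (prob.n - prob.p)
    beta = np.linalg.lstsq(prob.X, prob.y, rcond=None)[0]
    return s2, beta


def _observed_information_se(y, X, K_list, sigma2, names):
    """SEs from a central-difference Hessian of the REML log-likelihood."""
    sigma2 = np.asarray(sigma2, dtype=float)
    k = len(sigma2)
    scale = max(np.max(sigma2), 1e-8)
    h = np.maximum(1e-4 * np.maximum(sigma2, 0.0), 1e-6 * scale)

    def ll(v):
        if np.any(v[-1:] <= 0):
            return -np.inf
        try:
            return restricted_loglik(y, X, K_list, np.maximum(v, 0.0))
        except np.linalg.LinAlgError:
            return -np.inf

    H = np.empty((k, k))
    f0 = ll(sigma2)
    if not np.isfinite(f0):
        return None, None
    for a in range(k):
        for b in range(a, k):
            ea = np.zeros(k); ea[a] = h[a]
            eb = np.zeros(k); eb[b] = h[b]
            if a == b:
                val = (ll(sigma2 + ea) - 2.0 * f0 + ll(sigma2 - ea)) \
                    / (h[a] ** 2)
            else:
                val = (ll(sigma2 + ea + eb) - ll(sigma2 + ea - eb)
                       - ll(sigma2 - ea + eb) + ll(sigma2 - ea - eb)) \
                    / (4.0 * h[a] * h[b])
            H[a, b] = H[b, a] = val
    if not np.all(np.isfinite(H)):
        return None, None
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None, None
    d = np.diag(cov)
    if np.any(d <= 0):
        return None, None
    return dict(zip(names, np.sqrt(d))), cov


# ---------------------------------------------------------------------------
# module-level wrappers and follow-up statistics
# ---------------------------------------------------------------------------

def fit_animal_model(phenotypes: pd.DataFrame, trait: str = "y",
                     random_effects: Mapping[str, RelationshipMatrix]
                     | None = None,
                     group_effects: Sequence[str] = (),
                     fixed_effects: Sequence[str] = (),
                     **config) -> FitResult:
    """Fit an animal model from a phenotype table (thin estimator wrapper).

    ``phenotypes`` must carry an ``id`` column (or index), the trait column
    and any covariate/grouping columns named in the effect lists.
    """
    est = AnimalModel(random_effects=random_effects,
                      group_effects=group_effects,
                      fixed_effects=fixed_effects, **config)
    est.fit(phenotypes, phenotypes[trait].to_numpy(dtype=float))
    return est.result_


def heritabilities(fit: FitResult) -> dict[str, float]:
    """Variance ratios component / total, e.g. h2 = s2_A / s2_P.

    Returns one ratio per estimated component (residual included); ratios
    sum to one.  Delta-method SEs are attached under ``"se_<name>"`` keys
    when the fit carries a variance-covariance matrix.
    """
    total = sum(fit.estimates.values())
    if total <= 0:
        raise ValueError("total estimated variance is zero")
    ratios = {k: v / total for k, v in fit.estimates.items()}
    if fit.vcov is not None:
        names = list(fit.estimates)
        s = np.array([fit.estimates[k] for k in names])
        for idx, k in enumerate(names):
            g = -s / total ** 2
            g[idx] += 1.0 / total
            var = float(g @ fit.vcov @ g)
            if var >= 0:
                ratios[f"se_{k}"] = float(np.sqrt(var))
    return ratios


@dataclass(frozen=True)
class LRTReport:
    statistic: float
    p_corrected: float
    p_naive: float
    dropped_term: str


def lrt_component(fit_full: FitResult, fit_reduced: FitResult) -> LRTReport:
    """Boundary-corrected likelihood-ratio test for one variance component.

    The null value lies on the boundary of the parameter space, so the LRT
    statistic is asymptotically a 50:50 mixture of a point mass at zero and
    chi-square with one degree of freedom; the corrected p-value halves the
    chi-square tail (and equals 0.5 at a zero statistic).  The naive
    chi-square(1) p-value is reported alongside.
    """
    if fit_full.data_hash != fit_reduced.data_hash:
        raise ValueError("fits are not on identical data")
    if fit_full.fixed_names != fit_reduced.fixed_names:
        raise ValueError("fits differ in fixed effects")
    full_terms = set(fit_full.term_names)
    red_terms = set(fit_reduced.term_names)
    dropped = full_terms - red_terms
    if not red_terms <= full_terms or len(dropped) != 1:
        raise ValueError(
            "reduced model must drop exactly one variance component"
        )
    stat = max(0.0, 2.0 * (fit_full.loglik_restricted
                           - fit_reduced.loglik_restricted))
    p_naive = float(stats.chi2.sf(stat, df=1))
    p_corrected = 0.5 * p_naive if stat > 0 else 0.5
    return LRTReport(stat, p_corrected, p_naive, dropped.pop())


def compare_models(fits: Mapping[str, FitResult]) -> pd.DataFrame:
    """AIC ranking of REML fits on identical data and fixed effects.

    Fits with different fixed-effect structures are refused: REML
    likelihoods are computed on residual contrasts and are not comparable
    across fixed designs.
    """
    fits = dict(fits)
    items = list(fits.items())
    ref = items[0][1]
    for name, f in items[1:]:
        if f.data_hash != ref.data_hash:
            raise ValueError(f"fit {name!r} is on different data")
        if f.fixed_names != ref.fixed_names:
            raise ValueError(
                f"fit {name!r} has different fixed effects; REML AICs are "
                "not comparable across fixed-effect structures"
            )
    df = pd.DataFrame({
        "model": list(fits),
        "loglik": [f.loglik_restricted for f in fits.values()],
        "n_parameters": [f.n_variance_parameters for f in fits.values()],
        "aic": [f.aic for f in fits.values()],
    })
    df["delta_aic"] = df["aic"] - df["aic"].min()
    df["rank"] = df["aic"].rank(method="min").astype(int)
    return df.sort_values("rank").reset_index(drop=True)


def gxc_interaction_matrix(A: RelationshipMatrix, C: RelationshipMatrix
                           ) -> RelationshipMatrix:
    """Gene-by-culture interaction structure as the Hadamard product A∘C.

    The elementwise product of PSD matrices is PSD (Schur product theorem),
    so A∘C is a valid covariance structure for the interaction random
    effect, directly mirroring how gene-by-environment interactions are
    given an interaction covariance structure.
    """
    if A.ids != C.ids:
        raise ValueError("A and C must share the same id ordering")
    return RelationshipMatrix(A.ids, A.values * C.values)
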