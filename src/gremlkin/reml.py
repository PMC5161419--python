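"""Multi-component REML by average-information updates.

The model is the linear mixed model

    y = X b + sum_c u_c + e,      Var(y) = sum_c sigma2_c A_c + sigma2_e I,

with each random effect u_c governed by a relationship matrix A_c
(genomic G/K or environmental F/S/C indicator).  The REML log-likelihood
(constant dropped) is

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P    = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

Maximization uses Newton-type steps with the average-information matrix

    AI_pq = 1/2 y' P D_p P D_q P y,     D_p = dV/d theta_p,

step-halved against the likelihood, with an expectation-maximization
fallback when an AI step cannot improve.  Variance components are
clamped at a small positive floor rather than allowed negative, so a
boundary estimate reports as the floor (printed as 0.00).

The engine is written for any *linear* covariance structure
V = sum_p theta_p D_p, which also serves the bivariate model where D_p
are Kronecker products of 2x2 trait blocks with relationship matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .matrices import RelationshipMatrix

__all__ = [
    "VarianceComponentSpec",
    "REMLOptions",
    "REMLFit",
    "ComponentTest",
    "fit_reml",
    "reml_loglik",
    "lrt_component",
    "wald_component",
]

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponentSpec:
    """Ordered (label, RelationshipMatrix) pairs; residual is implicit."""

    components: list[tuple[str, RelationshipMatrix]]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.components]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate component labels: {labels}")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.components]

    @property
    def model_code(self) -> str:
        return "".join(self.labels)

    def drop(self, label: str) -> "VarianceComponentSpec":
        if label not in self.labels:
            raise ValueError(f"component {label!r} not in spec {self.model_code}")
        return VarianceComponentSpec(
            [(lab, A) for lab, A in self.components if lab != label]
        )

    def matrices_for(self, sample_ids: list[str]) -> list[np.ndarray]:
        return [A.reorder(sample_ids).values for _, A in self.components]


@dataclass
class REMLOptions:
    max_iter: int = 200
    tol_logl: float = 1e-6
    tol_grad: float = 1e-4
    floor_frac: float = 1e-6  # component floor as a fraction of var(y)
    max_halvings: int = 15


@dataclass
class ComponentTest:
    component: str
    lrt_stat: float | None = None
    lrt_p: float | None = None
    wald_z: float | None = None
    wald_p: float | None = None


@dataclass
class REMLFit:
    """Variance-component estimates with AI-based sampling covariance."""

    labels: list[str]  # component labels, residual excluded
    sigma2: np.ndarray  # per component + residual last
    proportions: np.ndarray  # sigma2 / total, residual last
    prop_se: np.ndarray
    ai_cov: np.ndarray  # covariance of sigma2 estimates (AI inverse)
    fixed_effects: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    trace: list[dict] = field(default_factory=list)
    n_used: int = 0
    sample_ids: list[str] = field(default_factory=list)

    def proportion(self, label: str) -> tuple[float, float]:
        i = self.labels.index(label)
        return float(self.proportions[i]), float(self.prop_se[i])


class REMLError(RuntimeError):
    def __init__(self, message: str, trace: list[dict] | None = None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# generic linear-covariance engine


def _loglik_terms(y, X, D, theta):
    """Return (logL, Py, Vinv, ViX, XtViX_chol) or None if V/XtViX not PD."""
    n = y.shape[0]
    V = np.zeros((n, n))
    for t, Dp in zip(theta, D):
        V += t * Dp
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    try:
        cx = linalg.cho_factor(XtViX, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_X = 2.0 * np.sum(np.log(np.diag(cx[0])))
    ViY = Vinv @ y
    beta = linalg.cho_solve(cx, X.T @ ViY, check_finite=False)
    Py = ViY - ViX @ beta
    ll = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    return ll, Py, Vinv, ViX, cx, beta


def _project(w, X, ViX, cx):
    """Apply P to a vector given V^-1 w precomputed pieces."""
    return w - X @ linalg.cho_solve(cx, ViX.T @ w, check_finite=False)


def _maximize(y, X, D, theta0, floors, opts: REMLOptions):
    """AI-REML with step-halving and EM fallback on V = sum theta_p D_p.

    ``floors[p]`` is the lower clamp for parameter p (-inf leaves it
    free, used for covariance parameters).  Returns a dict with theta,
    loglik, ai (information matrix), beta, trace, converged, n_iter.
    """
    n = y.shape[0]
    theta = np.maximum(np.asarray(theta0, float), floors)
    terms = _loglik_terms(y, X, D, theta)
    if terms is None:
        raise REMLError("initial covariance matrix not positive definite")
    ll, Py, Vinv, ViX, cx, beta = terms
    trace = [{"iter": 0, "loglik": ll, "theta": theta.copy()}]
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        DPy = [Dp @ Py for Dp in D]
        PDPy = [Vinv @ w - ViX @ linalg.cho_solve(cx, ViX.T @ w, check_finite=False)
                for w in DPy]
        # tr(P D_p) = tr(Vinv D_p) - tr((X'ViX)^-1 X'Vi D_p Vi X)
        grad = np.empty(len(D))
        trPD = np.empty(len(D))
        for p, Dp in enumerate(D):
            tr1 = float(np.sum(Vinv * Dp))
            M = ViX.T @ (Dp @ ViX)
            tr2 = float(np.trace(linalg.cho_solve(cx, M, check_finite=False)))
            trPD[p] = tr1 - tr2
            grad[p] = -0.5 * (trPD[p] - float(Py @ DPy[p]))
        ai = 0.5 * np.array([[float(DPy[p] @ PDPy[q]) for q in range(len(D))]
                             for p in range(len(D))])
        # convergence: ignore gradient pushing a floored parameter downward
        active = ~((theta <= floors + 1e-12) & (grad < 0))
        gmax = np.max(np.abs(grad[active])) if active.any() else 0.0
        dll_prev = trace[-1]["loglik"] - trace[-2]["loglik"] if len(trace) > 1 else np.inf
        if gmax < opts.tol_grad and abs(dll_prev) < opts.tol_logl:
            converged = True
            break

        # active-set Newton: hold floored parameters whose gradient points
        # further below the floor, solve the reduced AI system for the rest
        free = np.flatnonzero(active)
        delta = np.zeros(len(D))
        if free.size:
            ai_f = ai[np.ix_(free, free)]
            try:
                delta[free] = np.linalg.solve(
                    ai_f + 1e-9 * np.eye(free.size) * max(np.trace(ai_f), 1.0),
                    grad[free],
                )
            except np.linalg.LinAlgError:
                delta[free] = grad[free]
        new = None
        step = 1.0
        for _ in range(opts.max_halvings):
            cand = np.maximum(theta + step * delta, floors)
            t = _loglik_terms(y, X, D, cand)
            if t is not None and t[0] >= ll - 1e-10:
                new = (cand, t)
                break
            step *= 0.5
        if new is not None and step == 1.0:
            # guarded extrapolation: boundary-divergent likelihoods (e.g. a
            # correlation tending to 1) advance far too slowly at unit steps
            for _ in range(10):
                cand = np.maximum(theta + 2.0 * step * delta, floors)
                t = _loglik_terms(y, X, D, cand)
                if t is None or t[0] <= new[1][0]:
                    break
                step *= 2.0
                new = (cand, t)
        if new is None:
            # EM fallback: valid update for PSD D_p; for free-sign
            # parameters fall back to a damped gradient step
            cand = theta.copy()
            for p in range(len(D)):
                if np.isfinite(floors[p]):
                    cand[p] = theta[p] + theta[p] ** 2 * (
                        float(Py @ DPy[p]) - trPD[p]
                    ) / n
                else:
                    cand[p] = theta[p] + grad[p] / max(ai[p, p], 1.0)
            cand = np.maximum(cand, floors)
            t = _loglik_terms(y, X, D, cand)
            step = 1.0
            while t is None and step > 1e-6:
                step *= 0.5
                cand_h = theta + step * (cand - theta)
                cand_h = np.maximum(cand_h, floors)
                t = _loglik_terms(y, X, D, cand_h)
                cand = cand_h
            if t is None:
                raise REMLError(
                    f"REML failed to find an admissible step at iteration {it}",
                    trace,
                )
            new = (cand, t)
        theta, (ll, Py, Vinv, ViX, cx, beta) = new
        trace.append({"iter": it, "loglik": ll, "theta": theta.copy()})
    return {
        "theta": theta,
        "loglik": ll,
        "ai": ai,
        "beta": beta,
        "trace": trace,
        "converged": converged,
        "n_iter": it,
    }


# ---------------------------------------------------------------------------
# univariate interface


def _align(y, X, spec: VarianceComponentSpec, sample_ids):
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    keep = ~np.isnan(y)
    if (~keep).any():
        logger.info("dropping %d samples with missing phenotype", int((~keep).sum()))
    if np.isnan(X).any():
        keep &= ~np.isnan(X).any(axis=1)
    ids = [s for s, k in zip(sample_ids, keep) if k]
    idx = np.flatnonzero(keep)
    D = [Dp[np.ix_(idx, idx)] for Dp in spec.matrices_for(sample_ids)]
    return y[keep], X[keep], D, ids


def fit_reml(
    y,
    X,
    spec: VarianceComponentSpec,
    sample_ids: list[str] | None = None,
    options: REMLOptions | None = None,
) -> REMLFit:
    """Fit the variance-component LMM by AI-REML.

    ``y`` may contain NaN (those samples are dropped, along with any with
    missing covariates).  ``X`` should include an intercept column.
    Binary traits are analyzed as 0/1 on the observed scale; transform the
    resulting proportions with :func:`gremlkin.liability.observed_to_liability`.
    """
    opts = options or REMLOptions()
    if sample_ids is None:
        sample_ids = spec.components[0][1].sample_ids
    y, X, A_list, ids = _align(y, X, spec, sample_ids)
    n = y.shape[0]
    n_par = len(A_list) + 1
    if n <= X.shape[1] + n_par:
        raise REMLError(f"n_used={n} too small for {X.shape[1]} fixed effects "
                        f"and {n_par} variance parameters")
    Ident = np.eye(n)
    for i, Ai in enumerate(A_list):
        if np.allclose(Ai, Ident, atol=1e-10):
            raise REMLError(
                f"component {spec.labels[i]!r} is the identity: confounded "
                "with the residual, not identifiable"
            )
        for j in range(i):
            if np.allclose(Ai, A_list[j], atol=1e-10):
                raise REMLError(
                    f"components {spec.labels[j]!r} and {spec.labels[i]!r} "
                    "have identical matrices: not identifiable"
                )
    D = A_list + [Ident]
    vary = float(np.var(y))
    if vary == 0:
        raise REMLError("phenotype has zero variance")
    floor = opts.floor_frac * vary
    theta0 = np.full(n_par, vary / n_par)
    res = _maximize(y, X, D, theta0, np.full(n_par, floor), opts)
    if not res["converged"]:
        logger.warning("REML did not converge in %d iterations", res["n_iter"])
    theta = res["theta"]
    total = theta.sum()
    props = theta / total
    try:
        ai_cov = np.linalg.inv(res["ai"])
    except np.linalg.LinAlgError:
        ai_cov = np.linalg.pinv(res["ai"])
    # delta method for h_c = theta_c / sum(theta)
    J = (np.eye(n_par) * total - theta[:, None]) / total**2
    prop_cov = J @ ai_cov @ J.T
    prop_se = np.sqrt(np.clip(np.diag(prop_cov), 0, None))
    return REMLFit(
        labels=list(spec.labels),
        sigma2=theta,
        proportions=props,
        prop_se=prop_se,
        ai_cov=ai_cov,
        fixed_effects=res["beta"],
        loglik=res["loglik"],
        converged=res["converged"],
        n_iter=res["n_iter"],
        trace=res["trace"],
        n_used=n,
        sample_ids=ids,
    )


def reml_loglik(y, X, spec: VarianceComponentSpec, sigma2,
                sample_ids: list[str] | None = None) -> float:
    """REML log-likelihood (constant dropped) at a given sigma^2 vector.

    ``sigma2`` orders as spec components then residual.  Pure function.
    """
    if sample_ids is None:
        sample_ids = spec.components[0][1].sample_ids
    y, X, A_list, _ = _align(y, X, spec, sample_ids)
    sigma2 = np.asarray(sigma2, float)
    if sigma2.shape[0] != len(A_list) + 1:
        raise ValueError(
            f"expected {len(A_list) + 1} variance parameters, got {sigma2.shape[0]}"
        )
    D = A_list + [np.eye(y.shape[0])]
    terms = _loglik_terms(y, X, D, sigma2)
    if terms is None:
        V_ok = all(s >= 0 for s in sigma2)
        if V_ok:
            # pinpoint collinear covariates for a diagnosable error
            r = np.linalg.matrix_rank(X)
            if r < X.shape[1]:
                raise REMLError(
                    f"X'V^-1X singular: design matrix rank {r} < {X.shape[1]} "
                    "columns (collinear covariates)"
                )
        raise REMLError("covariance matrix not positive definite at sigma2")
    return terms[0]


# ---------------------------------------------------------------------------
# component tests


def lrt_component(full: REMLFit, reduced: REMLFit, component: str) -> ComponentTest:
    """Boundary LRT of one variance component.

    The null puts sigma2_c on the boundary, so the statistic is referred
    to the 50:50 mixture of chi2_0 and chi2_1: p = 0.5 P(chi2_1 > stat).
    """
    if set(reduced.labels) != set(full.labels) - {component}:
        raise ValueError(
            f"reduced model {reduced.labels} is not full model {full.labels} "
            f"minus {component!r}"
        )
    if reduced.n_used != full.n_used or reduced.sample_ids != full.sample_ids:
        raise ValueError("full and reduced fits use different samples")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 0.5 * float(stats.chi2.sf(stat, df=1))
    return ComponentTest(component=component, lrt_stat=stat, lrt_p=p)


def wald_component(fit: REMLFit, label: str) -> ComponentTest:
    """One-sided Wald test of a variance proportion against zero."""
    est, se = fit.proportion(label)
    if se == 0:
        if est > 0:
            logger.warning("Wald test for %s: SE is 0 with positive estimate", label)
            return ComponentTest(component=label, wald_z=np.inf, wald_p=0.0)
        return ComponentTest(component=label, wald_z=0.0, wald_p=0.5)
    z = est / se
    return ComponentTest(component=label, wald_z=z, wald_p=float(stats.norm.sf(z)))
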