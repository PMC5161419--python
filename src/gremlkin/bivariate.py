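"""Two-trait REML with per-component cross-trait correlations.

Traits are stacked and each variance component c carries a 2x2
(co)variance block (v_c1, v_c2, cov_c), giving the component-specific
correlation r_c = cov_c / sqrt(v_c1 v_c2) — e.g. the common-variant
genetic correlation from the G block, the pedigree-associated genetic
correlation from K, and the couple-environment correlation from C.  The
stacked covariance is

    V = sum_c B_c (x) A_c + B_e (x) I,

restricted to the observed trait-sample entries: samples missing one
trait still contribute to the other, and the residual covariance is
informed only by jointly phenotyped samples.

Free fits use the same average-information engine as the univariate
model.  Correlation tests against 0 and 1 use Wald statistics from
delta-method SEs and constrained-refit LRTs: cov_c = 0 stays within the
linear parameterization, while r_c = 1 refits under the rank-1
reparameterization cov_c = sqrt(v_c1 v_c2) with a quasi-Newton
optimizer on the REML likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .reml import (
    REMLError,
    REMLOptions,
    VarianceComponentSpec,
    _loglik_terms,
    _maximize,
)

__all__ = ["BivariateFit", "fit_bivariate_reml", "test_correlation", "wald_correlation"]

logger = logging.getLogger(__name__)


@dataclass
class BivariateFit:
    """Per-component 2x2 blocks, correlations, and the data needed to refit."""

    labels: list[str]  # component labels; residual handled separately
    blocks: dict  # label -> (v1, v2, cov); includes "residual"
    correlations: dict  # label -> dict(r, se, projected, defined)
    loglik: float
    ai_cov: np.ndarray
    converged: bool
    n_iter: int
    n_used: tuple[int, int, int]  # trait1, trait2, overlap
    _data: dict = field(repr=False, default_factory=dict)

    def correlation(self, label: str) -> tuple[float, float]:
        c = self.correlations[label]
        return c["r"], c["se"]


def _stack(y1, y2, X, A_list):
    """Stack two traits; subset covariance blocks to observed entries."""
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n = y1.shape[0]
    obs1 = ~np.isnan(y1)
    obs2 = ~np.isnan(y2)
    if np.isnan(X).any():
        ok = ~np.isnan(X).any(axis=1)
        obs1 &= ok
        obs2 &= ok
    i1 = np.flatnonzero(obs1)
    i2 = np.flatnonzero(obs2)
    y = np.concatenate([y1[i1], y2[i2]])
    Xs = linalg.block_diag(X[i1], X[i2])
    n1, n2 = len(i1), len(i2)
    overlap = int((obs1 & obs2).sum())

    def expand(A, which):
        """Place an n x n block into the stacked (n1+n2) frame."""
        out = np.zeros((n1 + n2, n1 + n2))
        if which == "11":
            out[:n1, :n1] = A[np.ix_(i1, i1)]
        elif which == "22":
            out[n1:, n1:] = A[np.ix_(i2, i2)]
        else:  # symmetric cross block
            out[:n1, n1:] = A[np.ix_(i1, i2)]
            out[n1:, :n1] = out[:n1, n1:].T
        return out

    D = []
    for A in A_list + [np.eye(n)]:
        D.extend([expand(A, "11"), expand(A, "22"), expand(A, "12")])
    return y, Xs, D, (n1, n2, overlap)


def fit_bivariate_reml(
    y1,
    y2,
    X,
    spec: VarianceComponentSpec,
    sample_ids: list[str] | None = None,
    options: REMLOptions | None = None,
) -> BivariateFit:
    """Fit the stacked two-trait REML model.

    ``y1``/``y2`` align with ``sample_ids`` (NaN = missing); ``X`` is the
    per-trait fixed-effect design, block-diagonalized internally.
    """
    opts = options or REMLOptions()
    if sample_ids is None:
        sample_ids = spec.components[0][1].sample_ids
    A_list = spec.matrices_for(sample_ids)
    y, Xs, D, (n1, n2, overlap) = _stack(y1, y2, X, A_list)
    if n1 == 0 or n2 == 0:
        raise REMLError("one of the traits has no observed phenotypes")
    labels = list(spec.labels)
    n_comp = len(labels) + 1  # + residual
    v1 = float(np.var(np.asarray(y1, float)[~np.isnan(np.asarray(y1, float))]))
    v2 = float(np.var(np.asarray(y2, float)[~np.isnan(np.asarray(y2, float))]))
    floors = []
    theta0 = []
    for _ in range(n_comp):
        floors.extend([opts.floor_frac * v1, opts.floor_frac * v2, -np.inf])
        theta0.extend([v1 / n_comp, v2 / n_comp, 0.0])
    floors = np.array(floors)
    theta0 = np.array(theta0)
    fixed_resid_cov = overlap == 0
    if fixed_resid_cov:
        warnings.warn(
            "no sample has both traits: residual covariance fixed at 0"
        )
        D = D[:-1]
        floors = floors[:-1]
        theta0 = theta0[:-1]
    res = _maximize(y, Xs, D, theta0, floors, opts)
    theta = res["theta"]
    if fixed_resid_cov:
        theta = np.append(theta, 0.0)
    try:
        ai_cov = np.linalg.inv(res["ai"])
    except np.linalg.LinAlgError:
        ai_cov = np.linalg.pinv(res["ai"])
    blocks = {}
    correlations = {}
    for c, lab in enumerate(labels + ["residual"]):
        b1, b2, cv = theta[3 * c : 3 * c + 3]
        blocks[lab] = (float(b1), float(b2), float(cv))
        at_floor = b1 <= floors[3 * c] * (1 + 1e-6) or b2 <= floors[3 * c + 1] * (1 + 1e-6)
        if at_floor:
            correlations[lab] = {
                "r": np.nan, "se": np.nan, "projected": False, "defined": False,
                "note": "component variance at floor in at least one trait",
            }
            continue
        r = cv / np.sqrt(b1 * b2)
        # delta method on (v1, v2, cov)
        g = np.array([-r / (2 * b1), -r / (2 * b2), 1.0 / np.sqrt(b1 * b2)])
        sl = slice(3 * c, 3 * c + 3)
        if fixed_resid_cov and lab == "residual":
            se = np.nan
        else:
            se = float(np.sqrt(max(0.0, g @ ai_cov[sl, sl] @ g)))
        projected = abs(r) > 1
        correlations[lab] = {
            "r": float(np.clip(r, -1.0, 1.0)),
            "se": se,
            "projected": projected,
            "defined": True,
        }
        if projected:
            logger.info("correlation for %s projected from %.4f to +/-1", lab, r)
    return BivariateFit(
        labels=labels,
        blocks=blocks,
        correlations=correlations,
        loglik=res["loglik"],
        ai_cov=ai_cov,
        converged=res["converged"],
        n_iter=res["n_iter"],
        n_used=(n1, n2, overlap),
        _data={
            "y": y, "X": Xs, "D": D, "floors": floors,
            "theta": res["theta"], "opts": opts,
            "fixed_resid_cov": fixed_resid_cov,
        },
    )


def _constrained_r1_loglik(fit: BivariateFit, comp: int) -> float:
    """Maximized REML log-likelihood with r_comp fixed at 1.

    Reparameterizes the component block as (a^2, b^2, ab) and maximizes
    over all remaining parameters with L-BFGS-B using analytic
    gradients; non-PD proposals are penalized.
    """
    d = fit._data
    y, X, D, floors, opts = d["y"], d["X"], d["D"], d["floors"], d["opts"]
    theta_hat = d["theta"].copy()
    n_par = len(theta_hat)
    sl = slice(3 * comp, 3 * comp + 3)
    free_idx = [i for i in range(n_par) if i not in range(3 * comp, 3 * comp + 3)]

    v1, v2, _ = theta_hat[sl]
    a0, b0 = np.sqrt(max(v1, 1e-12)), np.sqrt(max(v2, 1e-12))
    x0 = np.concatenate([[a0, b0], theta_hat[free_idx]])

    def unpack(x):
        a, b = x[0], x[1]
        theta = np.empty(n_par)
        theta[free_idx] = x[2:]
        theta[3 * comp] = a * a
        theta[3 * comp + 1] = b * b
        theta[3 * comp + 2] = a * b
        return theta, a, b

    def negll(x):
        theta, a, b = unpack(x)
        terms = _loglik_terms(y, X, D, theta)
        if terms is None:
            return 1e8, np.zeros_like(x)
        ll, Py, Vinv, ViX, cx, _ = terms
        # dL/d theta_p for every linear coefficient
        g_lin = np.empty(n_par)
        for p, Dp in enumerate(D):
            DPy = Dp @ Py
            tr1 = float(np.sum(Vinv * Dp))
            M = ViX.T @ (Dp @ ViX)
            tr2 = float(np.trace(linalg.cho_solve(cx, M, check_finite=False)))
            g_lin[p] = -0.5 * ((tr1 - tr2) - float(Py @ DPy))
        grad = np.empty_like(x)
        grad[0] = 2 * a * g_lin[3 * comp] + b * g_lin[3 * comp + 2]
        grad[1] = 2 * b * g_lin[3 * comp + 1] + a * g_lin[3 * comp + 2]
        grad[2:] = g_lin[free_idx]
        return -ll, -grad

    bounds = [(np.sqrt(max(floors[3 * comp], 1e-12)), None),
              (np.sqrt(max(floors[3 * comp + 1], 1e-12)), None)]
    for i in free_idx:
        lo = floors[i]
        bounds.append((None if not np.isfinite(lo) else lo, None))
    res = optimize.minimize(
        negll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-10},
    )
    return -float(res.fun)


def _constrained_r0_loglik(fit: BivariateFit, comp: int) -> float:
    """Maximized REML log-likelihood with cov_comp fixed at 0 (AI engine)."""
    d = fit._data
    idx = [i for i in range(len(d["theta"])) if i != 3 * comp + 2]
    D = [d["D"][i] for i in idx]
    floors = d["floors"][idx]
    theta0 = np.maximum(d["theta"][idx], floors)
    res = _maximize(d["y"], d["X"], D, theta0, floors, d["opts"])
    return float(res["loglik"])


def test_correlation(fit: BivariateFit, component: str, null_value: float):
    """Wald and constrained-refit LRT p-values for r_component vs 0 or 1.

    Wald is two-sided on (r - null)/SE.  The LRT refits with the
    component's covariance constrained to the null and refers
    2*(logL_free - logL_constrained), clipped at 0, to chi2_1.
    Returns ``(wald_p, lrt_p)``.
    """
    if null_value not in (0, 1):
        raise ValueError("null_value must be 0 or 1")
    info = fit.correlations[component]
    if not info["defined"] or not np.isfinite(info["se"]) or info["se"] == 0:
        logger.warning(
            "correlation test skipped for %s: SE undefined (%s)",
            component, info.get("note", "zero/degenerate SE"),
        )
        return None, None
    z = (info["r"] - null_value) / info["se"]
    wald_p = float(2 * stats.norm.sf(abs(z)))
    comp = (fit.labels + ["residual"]).index(component)
    if null_value == 0:
        ll0 = _constrained_r0_loglik(fit, comp)
    else:
        ll0 = _constrained_r1_loglik(fit, comp)
    stat = max(0.0, 2.0 * (fit.loglik - ll0))
    lrt_p = float(stats.chi2.sf(stat, df=1))
    return wald_p, lrt_p


def wald_correlation(r: float, se: float, null_value: float) -> float:
    """Two-sided Wald p-value for a reported correlation vs 0 or 1."""
    if se <= 0:
        raise ValueError("SE must be positive")
    z = (r - null_value) / se
    return float(2 * stats.norm.sf(abs(z)))
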