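"""Extended linear mixed modeling (ELMM).

ELMM maximizes the likelihood-like function jointly over
theta = (beta, beta', rho) — mean coefficients, dispersion coefficients and
the working-correlation parameter — by Newton's method with the analytic
gradient and Hessian.  Unlike the GEE approaches, every derivative here is a
true partial derivative of the likelihood-like function, so at a converged
interior solution the parameter covariance is -H^-1 and Wald z tests are
available.  If the counts were normal with unit variance function this would
be exactly linear mixed modeling, hence the name.

For the independence structure theta carries no rho (the derivative in rho
is identically zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .basis import PowerSpec, ThetaParams, disp_design, evaluate_model, mean_design
from .correlation import (
    CorrelationSpec,
    corr_derivative,
    corr_matrix,
    rho_bounds,
)
from .gee import fit_gee, initial_beta
from .likelihood import loglike
from .results import FitResult
from .series import CountSeries

__all__ = ["elmm_gradient", "elmm_hessian", "fit_elmm", "wald_tests", "WaldRow"]


def _theta_dim(spec: PowerSpec, corr_spec: CorrelationSpec) -> int:
    return spec.n_mean + spec.n_disp + (1 if corr_spec.has_rho else 0)


def _unpack(p: np.ndarray, spec: PowerSpec, corr_spec: CorrelationSpec) -> ThetaParams:
    j, jp = spec.n_mean, spec.n_disp
    rho = float(p[j + jp]) if corr_spec.has_rho else 0.0
    return ThetaParams(p[:j], p[j : j + jp], rho)


def _system(series, spec, theta, corr_spec, want_hessian=True):
    """Likelihood-like value, gradient and (optionally) Hessian at theta."""
    with np.errstate(over="raise", invalid="raise", divide="raise"):
        return _system_impl(series, spec, theta, corr_spec, want_hessian)


def _system_impl(series, spec, theta, corr_spec, want_hessian):
    X = mean_design(series, spec)
    Xp = disp_design(series, spec)
    n, j, jp = series.n, X.shape[1], Xp.shape[1]
    state = evaluate_model(series, spec, theta)
    stde = state.stde
    sigma = state.sd_ext
    y, mu = series.counts, state.mu

    ind = corr_spec.structure == "ind"
    if ind:
        R_inv = None
        w = stde  # R^-1 stde
        quad = float(stde @ stde)
        logdet = 0.0
    else:
        R = corr_matrix(corr_spec, theta.rho, series.times)
        c = cho_factor(R, lower=True)
        R_inv = cho_solve(c, np.eye(n))
        w = R_inv @ stde
        quad = float(stde @ w)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    ll = -0.5 * quad - 0.5 * logdet - float(np.sum(np.log(sigma))) - 0.5 * n * math.log(2 * math.pi)

    # stdex_{ij} = x_{ij} (y_i + mu_i) / (2 sigma_i); stdex'_{ij} = x'_{ij} stde_i / 2
    stdex = X * ((y + mu) / (2.0 * sigma))[:, None]
    stdexp = Xp * (stde / 2.0)[:, None]

    g_beta = stdex.T @ w - X.sum(axis=0) / 2.0
    g_bp = stdexp.T @ w - Xp.sum(axis=0) / 2.0

    if corr_spec.has_rho:
        Rp = corr_derivative(corr_spec, theta.rho, series.times, order=1)
        RinvRp = R_inv @ Rp
        # d R^-1 / d rho = -R^-1 Rp R^-1
        dRinv_stde = -R_inv @ (Rp @ w)
        g_rho = -0.5 * float(stde @ dRinv_stde) - 0.5 * float(np.trace(RinvRp))
        g = np.concatenate([g_beta, g_bp, [g_rho]])
    else:
        g = np.concatenate([g_beta, g_bp])

    if not want_hessian:
        return ll, g, None, state

    def rmul(M):  # R^-1 @ M
        return M if ind else R_inv @ M

    Rw_stdex = rmul(stdex)
    Rw_stdexp = rmul(stdexp)
    # H(beta): -stdexx_{jj'}' R^-1 stde - stdex_j' R^-1 stdex_{j'}
    H_bb = -X.T @ (X * (stde * w / 4.0)[:, None]) - stdex.T @ Rw_stdex
    # H(beta'): same shape with the dispersion design
    H_pp = -Xp.T @ (Xp * (stde * w / 4.0)[:, None]) - stdexp.T @ Rw_stdexp
    # H(beta, beta'): -stdexx'_{jj'}' R^-1 stde - stdex_j' R^-1 stdex'_{j'}
    # with stdexx'_{i,j,j'} = x'_{ij'} stdex_{ij} / 2
    H_bp = -stdex.T @ (Xp * (w / 2.0)[:, None]) - stdex.T @ Rw_stdexp

    dim = j + jp + (1 if corr_spec.has_rho else 0)
    H = np.empty((dim, dim))
    H[:j, :j] = H_bb
    H[:j, j : j + jp] = H_bp
    H[j : j + jp, :j] = H_bp.T
    H[j : j + jp, j : j + jp] = H_pp
    if corr_spec.has_rho:
        Rpp = corr_derivative(corr_spec, theta.rho, series.times, order=2)
        # d2 R^-1/d rho2 = 2 R^-1 Rp R^-1 Rp R^-1 - R^-1 Rpp R^-1
        d2Rinv_stde = 2.0 * R_inv @ (Rp @ (R_inv @ (Rp @ w))) - R_inv @ (Rpp @ w)
        tr1 = float(np.sum(RinvRp * RinvRp.T))  # tr(R^-1 Rp R^-1 Rp)
        tr2 = float(np.trace(R_inv @ Rpp))
        H_rr = -0.5 * float(stde @ d2Rinv_stde) - 0.5 * (-tr1 + tr2)
        H_brho = stdex.T @ dRinv_stde
        H_prho = stdexp.T @ dRinv_stde
        H[: j + jp, -1] = np.concatenate([H_brho, H_prho])
        H[-1, : j + jp] = H[: j + jp, -1]
        H[-1, -1] = H_rr
    H = 0.5 * (H + H.T)  # exact symmetry (diagonal blocks only to round-off)
    return ll, g, H, state


def elmm_gradient(
    series: CountSeries,
    spec: PowerSpec,
    theta: ThetaParams,
    corr_spec: CorrelationSpec,
) -> np.ndarray:
    """Gradient of the likelihood-like function in theta = (beta, beta'[, rho])."""
    _, g, _, _ = _system(series, spec, theta, corr_spec, want_hessian=False)
    return g


def elmm_hessian(
    series: CountSeries,
    spec: PowerSpec,
    theta: ThetaParams,
    corr_spec: CorrelationSpec,
) -> np.ndarray:
    """Hessian of the likelihood-like function in theta (symmetric by construction)."""
    _, _, H, _ = _system(series, spec, theta, corr_spec, want_hessian=True)
    return H


def fit_elmm(
    series: CountSeries,
    spec: PowerSpec,
    corr_spec: CorrelationSpec,
    init: ThetaParams | None = None,
    max_iter: int = 200,
    gtol: float = 1e-6,
    lltol: float = 1e-7,
    warm_gee: bool = True,
) -> FitResult:
    """Maximize the likelihood-like function by safeguarded Newton ascent.

    Initialization follows the extended-GEE solution when available (and no
    explicit ``init`` is given); otherwise a cheap least-squares start.  Steps
    are halved until the likelihood-like value does not decrease and the rho
    component stays interior to its validity interval.  Convergence is
    declared at ``max|g| < gtol`` or when an accepted step changes the value
    by less than ``lltol``.  The parameter covariance -H^-1 is attached when
    the final Hessian is invertible.
    """
    attempts = []
    if init is not None:
        attempts.append(init)
    else:
        if warm_gee:
            try:
                gee = fit_gee(series, spec, corr_spec, mode="extended")
                if gee.converged and np.all(np.isfinite(gee.theta.beta)):
                    attempts.append(gee.theta)
            except Exception:
                pass
        attempts.append(_default_init(series, spec))

    last_exc = None
    for theta0 in attempts:
        try:
            return _newton_elmm(series, spec, corr_spec, theta0, max_iter, gtol, lltol)
        except (np.linalg.LinAlgError, OverflowError, FloatingPointError, ValueError) as exc:
            last_exc = exc
            continue
    raise RuntimeError(f"ELMM fit failed from all starts: {last_exc}")


def _default_init(series: CountSeries, spec: PowerSpec) -> ThetaParams:
    beta = initial_beta(series, spec)
    bprime = np.zeros(spec.n_disp)
    state = evaluate_model(series, spec, ThetaParams(beta, bprime, 0.0))
    if spec.disp_intercept:
        phi0 = max(float(np.sum(state.pearson**2)) / max(series.n - spec.n_mean, 1), 1e-4)
        bprime[0] = math.log(phi0) - float(np.mean(np.log(state.phi)))
    return ThetaParams(beta, bprime, 0.0)


def _rho_pinned(p, g, lo, hi, has_rho) -> bool:
    """True when rho sits against a validity boundary with an outward gradient.

    The boundary zone is 0.5% of the interval: for EXCH the likelihood-like
    value has a log-singular spike as R degenerates at -1/(N-1), and treating
    the zone as the boundary stops the optimizer from crawling into it.
    """
    if not has_rho:
        return False
    zone = 5e-3 * (hi - lo)
    return (p[-1] - lo < zone and g[-1] < 0) or (hi - p[-1] < zone and g[-1] > 0)


def _newton_elmm(series, spec, corr_spec, theta0, max_iter, gtol, lltol) -> FitResult:
    j, jp = spec.n_mean, spec.n_disp
    has_rho = corr_spec.has_rho
    lo, hi = rho_bounds(corr_spec, series.n) if has_rho else (0.0, 0.0)
    p = np.concatenate(
        [theta0.beta, theta0.beta_prime, [min(max(theta0.rho, lo), hi)] if has_rho else []]
    )
    ll, g, H, _ = _system(series, spec, _unpack(p, spec, corr_spec), corr_spec)
    converged = False
    iters = 0
    for it in range(max_iter):
        iters = it + 1
        # a rho pinned at its validity boundary with an outward gradient is a
        # constrained optimum: drop that coordinate from the active system
        pinned = _rho_pinned(p, g, lo, hi, has_rho)
        g_act = g[:-1] if pinned else g
        if np.max(np.abs(g_act)) < gtol:
            converged = True
            break
        if pinned:
            step = np.zeros_like(p)
            step[:-1] = _newton_step(H[:-1, :-1], g[:-1])
            if not np.all(np.isfinite(step)) or float(g[:-1] @ step[:-1]) <= 0.0:
                step[:-1] = g[:-1] / max(1.0, float(np.max(np.abs(g[:-1]))))
        else:
            step = _newton_step(H, g)
            if not np.all(np.isfinite(step)) or float(g @ step) <= 0.0:
                # singular/indefinite Hessian: fall back to a gradient step
                step = g / max(1.0, float(np.max(np.abs(g))))
        if has_rho and not pinned:
            # a rho step leaving the validity interval is shortened to stop
            # at the interval's interior margin (the bounds carry epsilon)
            rho_new = p[-1] + step[-1]
            if not (lo <= rho_new <= hi):
                step[-1] = float(np.clip(rho_new, lo, hi)) - p[-1]
        accepted = False
        scale = 1.0
        for _half in range(20):
            try:
                cand = p + scale * step
                ll_new, g_new, H_new, _ = _system(
                    series, spec, _unpack(cand, spec, corr_spec), corr_spec
                )
            except (OverflowError, FloatingPointError, ValueError, np.linalg.LinAlgError):
                scale /= 2.0
                continue
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:  # monotone ascent (to round-off)
                accepted = True
                delta = ll_new - ll
                p, ll, g, H = cand, ll_new, g_new, H_new
                break
            scale /= 2.0
        if not accepted:
            break
        if delta < lltol:
            converged = True  # early stop: the value no longer increases by much
            break
    theta = _unpack(p, spec, corr_spec)
    pinned = _rho_pinned(p, g, lo, hi, has_rho)
    max_grad = float(np.max(np.abs(g[:-1] if pinned else g)))
    cov = None
    try:
        cov = -np.linalg.inv(H)
    except np.linalg.LinAlgError:
        pass
    from .gee import _names

    return FitResult(
        theta=theta,
        spec=spec,
        corr_spec=corr_spec,
        loglike=ll,
        converged=bool(converged),
        iterations=iters,
        approach="elmm",
        max_grad=max_grad,
        cov=cov,
        param_names=_names(spec, with_rho=has_rho),
    )


def _newton_step(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    """-H^-1 g with a one-shot diagonal ridge on singular H."""
    try:
        return -np.linalg.solve(H, g)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * max(1.0, float(np.max(np.abs(np.diag(H)))))
        return -np.linalg.solve(H - ridge * np.eye(H.shape[0]), g)


@dataclass
class WaldRow:
    name: str
    estimate: float
    se: float
    z: float
    p: float


def wald_tests(fit: FitResult) -> list[WaldRow]:
    """Per-parameter Wald z tests from the -H^-1 covariance.

    For adaptively selected models these are post-selection quantities, not
    confirmatory tests.  Parameters whose -H^-1 diagonal entry is not
    positive get undefined (NaN) standard errors.
    """
    if fit.cov is None:
        raise ValueError("fit carries no covariance (-H^-1); refit with ELMM")
    est = fit.flat_params()
    var = np.diag(fit.cov)
    rows = []
    names = fit.param_names or tuple(f"theta[{i}]" for i in range(est.size))
    for name, e, v in zip(names, est, var):
        if v > 0:
            se = math.sqrt(v)
            z = e / se
            pval = 2.0 * float(norm.sf(abs(z)))
        else:
            se, z, pval = float("nan"), float("nan"), float("nan")
        rows.append(WaldRow(name=name, estimate=float(e), se=se, z=z, p=pval))
    return rows
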