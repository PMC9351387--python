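"""Standard and extended generalized estimating equations (GEE) fitting.

Standard GEE estimates the mean coefficients beta from the estimating
equations ``g(beta) = D' Sigma^-1 e = 0`` with a constant dispersion phi0
(bias-adjusted Pearson moment estimate) and a moment-estimated working
correlation.  Extended GEE augments these with estimating equations for the
dispersion coefficients beta' obtained by differentiating the likelihood-like
function in beta' while holding rho fixed ("partial" derivatives), and solves
jointly for (beta, beta') by Newton's method, refreshing rho by moments at
every iteration.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .basis import (
    ModelState,
    PowerSpec,
    ThetaParams,
    disp_design,
    evaluate_model,
    mean_design,
)
from .correlation import CorrelationSpec, corr_matrix, moment_rho, pearson_phi0
from .likelihood import loglike
from .results import FitResult
from .series import CountSeries

__all__ = [
    "gee_score_beta",
    "gee_score_dispersion",
    "gee_hessian_blocks",
    "fit_gee",
    "initial_beta",
]


def initial_beta(series: CountSeries, spec: PowerSpec) -> np.ndarray:
    """Least-squares start on the log scale: log(y + 1/2) - o ~ X beta."""
    X = mean_design(series, spec)
    z = np.log(series.counts + 0.5) - series.offsets
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    return beta


def _rinv_solve(R: np.ndarray):
    c = cho_factor(R, lower=True)
    return lambda v: cho_solve(c, v)


# ---------------------------------------------------------------------------
# estimating-equation pieces (exposed for direct checking)
# ---------------------------------------------------------------------------


def gee_score_beta(state: ModelState, design: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """g(beta) = D' Sigma^-1 e with D = Diag(mu) X."""
    D = design * state.mu[:, None]
    c = cho_factor(Sigma, lower=True)
    return D.T @ cho_solve(c, state.resid)


def gee_score_dispersion(
    state: ModelState, disp_design: np.ndarray, R_inv: np.ndarray
) -> np.ndarray:
    """g_j(beta') = stdex'_j R^-1 stde - sum_i x'_{ij} / 2."""
    stdexp = disp_design * (state.stde / 2.0)[:, None]
    return stdexp.T @ (R_inv @ state.stde) - disp_design.sum(axis=0) / 2.0


def gee_hessian_blocks(
    state: ModelState,
    design: np.ndarray,
    disp_design: np.ndarray,
    R_inv: np.ndarray,
) -> np.ndarray:
    """Joint (J+J') x (J+J') Hessian-role matrix for extended GEE.

    Blocks: H(beta) = -D' Sigma^-1 D;
    H(beta')_{jj'} = -stdexx''_{jj'} R^-1 stde - stdex'_j R^-1 stdex'_{j'};
    H(beta,beta')_j = -D' Diag(x'_j/(2 sigma)) R^-1 stde
                      -D' Diag(1/sigma) R^-1 stdex'_j;
    and H(beta',beta) = H(beta,beta')'.
    """
    sigma = state.sd_ext
    stde = state.stde
    A = design * (state.mu / sigma)[:, None]  # Diag(1/sigma) D
    stdexp = disp_design * (stde / 2.0)[:, None]
    w = R_inv @ stde
    H_bb = -A.T @ R_inv @ A
    # H(beta'): both addends carry stde
    H_pp = -disp_design.T @ (disp_design * (stde * w / 4.0)[:, None]) - stdexp.T @ R_inv @ stdexp
    # H(beta, beta'): entries -sum_i A_ij x'_{ij'} w_i / 2 - (A' R^-1 stdex')_{jj'}
    # since Diag(1/sigma) D = A
    H_bp = -A.T @ (disp_design * (w / 2.0)[:, None]) - A.T @ (R_inv @ stdexp)
    j, jp = design.shape[1], disp_design.shape[1]
    H = np.empty((j + jp, j + jp))
    H[:j, :j] = H_bb
    H[:j, j:] = H_bp
    H[j:, :j] = H_bp.T
    H[j:, j:] = H_pp
    return H


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_gee(
    series: CountSeries,
    spec: PowerSpec,
    corr_spec: CorrelationSpec,
    mode: str = "extended",
    init: ThetaParams | None = None,
    max_iter: int = 100,
    gtol: float = 1e-8,
    xtol: float = 1e-8,
) -> FitResult:
    if mode == "standard":
        return _fit_standard(series, spec, corr_spec, init, max_iter, gtol, xtol)
    if mode == "extended":
        return _fit_extended(series, spec, corr_spec, init, max_iter, gtol, xtol)
    raise ValueError(f"unknown GEE mode {mode!r}")


def _fit_standard(series, spec, corr_spec, init, max_iter, gtol, xtol) -> FitResult:
    """Standard GEE: Newton on beta at fixed (phi0, rho), then moment updates.

    The outer loop alternates (beta -> phi0 -> rho) until joint stability.
    The likelihood-like value is computed with theta = (beta, log phi0, rho)
    under the implied constant-dispersion spec (no dispersion offset), so the
    fit can be scored by LCV.
    """
    eval_spec = replace(
        spec, disp_powers=(), disp_intercept=True, offsets_in_dispersion=False
    )
    X = mean_design(series, spec)
    j = X.shape[1]
    beta = np.array(init.beta, dtype=float) if init is not None else initial_beta(series, spec)
    phi0, rho = 1.0, 0.0
    if init is not None and init.beta_prime.size:
        phi0 = float(np.exp(init.beta_prime[0]))
    converged = False
    iters = 0
    max_g = np.inf
    for outer in range(max_iter):
        iters = outer + 1
        R = corr_matrix(corr_spec, rho, series.times)
        rinv = _rinv_solve(R)
        beta, max_g, ok = _newton_beta(series, eval_spec, X, beta, phi0, rinv, gtol)
        state = evaluate_model(
            series, eval_spec, ThetaParams(beta, [np.log(phi0)], rho)
        )
        phi_new = pearson_phi0(state.pearson, j)
        stde_adj = state.pearson / np.sqrt(phi_new)
        rho_new = (
            moment_rho(stde_adj, series.times, corr_spec, j)
            if corr_spec.has_rho
            else 0.0
        )
        delta = max(abs(phi_new - phi0), abs(rho_new - rho))
        phi0, rho = phi_new, rho_new
        if ok and delta < xtol:
            converged = True
            break
    theta = ThetaParams(beta, [np.log(phi0)], rho)
    ll = loglike(series, eval_spec, theta, corr_spec)
    return FitResult(
        theta=theta,
        spec=eval_spec,
        corr_spec=corr_spec,
        loglike=ll,
        converged=converged,
        iterations=iters,
        approach="gee",
        max_grad=max_g,
        phi0=phi0,
        param_names=_names(eval_spec, with_rho=False),
    )


def _newton_beta(series, eval_spec, X, beta, phi0, rinv, gtol, max_inner=50):
    """Inner Newton solve of g(beta)=0 at fixed (phi0, rho), with step-halving."""

    def score(b):
        with np.errstate(over="raise", invalid="raise", divide="raise"):
            state = evaluate_model(series, eval_spec, ThetaParams(b, [np.log(phi0)], 0.0))
            s = state.sd_ext
            A = X * (state.mu / s)[:, None]
            g = A.T @ rinv(state.resid / s)
        return g, A

    g, A = score(beta)
    ok = False
    for _ in range(max_inner):
        if np.max(np.abs(g)) < gtol:
            ok = True
            break
        H = A.T @ rinv(A)  # = -H(beta)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            H = H + 1e-8 * max(1.0, np.max(np.abs(np.diag(H)))) * np.eye(H.shape[0])
            step = np.linalg.solve(H, g)
        scale = 1.0
        for _half in range(20):
            try:
                g_new, A_new = score(beta + scale * step)
            except (OverflowError, FloatingPointError):
                scale /= 2.0
                continue
            if np.max(np.abs(g_new)) < np.max(np.abs(g)) or scale < 1e-6:
                beta = beta + scale * step
                g, A = g_new, A_new
                break
            scale /= 2.0
        else:
            break
    return beta, float(np.max(np.abs(g))), ok or np.max(np.abs(g)) < gtol


def _fit_extended(series, spec, corr_spec, init, max_iter, gtol, xtol) -> FitResult:
    """Joint Newton on (beta, beta'), rho refreshed by moments each iteration."""
    X = mean_design(series, spec)
    Xp = disp_design(series, spec)
    j, jp = X.shape[1], Xp.shape[1]
    if init is not None:
        beta = np.array(init.beta, dtype=float)
        bprime = np.array(init.beta_prime, dtype=float)
    else:
        beta = initial_beta(series, spec)
        state0 = evaluate_model(series, spec, ThetaParams(beta, np.zeros(jp), 0.0))
        bprime = np.zeros(jp)
        if spec.disp_intercept:
            # start the dispersion intercept at the log moment estimate,
            # net of any dispersion offset already in the model
            off = np.mean(np.log(state0.phi))
            bprime[0] = np.log(max(pearson_phi0(state0.pearson, j), 1e-4)) - off

    def system(p):
        with np.errstate(over="raise", invalid="raise", divide="raise"):
            return _system_at(p)

    def _system_at(p):
        theta = ThetaParams(p[:j], p[j:], 0.0)
        state = evaluate_model(series, spec, theta)
        rho = (
            moment_rho(state.stde, series.times, corr_spec, j)
            if corr_spec.has_rho
            else 0.0
        )
        R = corr_matrix(corr_spec, rho, series.times)
        R_inv = np.linalg.inv(R) if R.shape[0] > 1 else np.ones((1, 1))
        sigma = state.sd_ext
        A = X * (state.mu / sigma)[:, None]
        g = np.concatenate(
            [
                A.T @ (R_inv @ state.stde),
                gee_score_dispersion(state, Xp, R_inv),
            ]
        )
        H = gee_hessian_blocks(state, X, Xp, R_inv)
        return g, H, rho

    p = np.concatenate([beta, bprime])
    g, H, rho = system(p)
    converged = False
    iters = 0
    for it in range(max_iter):
        iters = it + 1
        if np.max(np.abs(g)) < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, g)  # theta_new = theta - H^-1 g
        except np.linalg.LinAlgError:
            ridge = 1e-8 * max(1.0, np.max(np.abs(np.diag(H))))
            try:
                step = np.linalg.solve(H - ridge * np.eye(H.shape[0]), g)
            except np.linalg.LinAlgError:
                break
        scale = 1.0
        accepted = False
        for _half in range(20):
            try:
                g_new, H_new, rho_new = system(p - scale * step)
            except (OverflowError, FloatingPointError, np.linalg.LinAlgError):
                scale /= 2.0
                continue
            if np.max(np.abs(g_new)) < np.max(np.abs(g)) or scale < 1e-6:
                p = p - scale * step
                if np.max(np.abs(scale * step)) < xtol:
                    converged = np.max(np.abs(g_new)) < max(gtol, 1e-6)
                g, H, rho = g_new, H_new, rho_new
                accepted = True
                break
            scale /= 2.0
        if not accepted:
            break
        if converged:
            break
    theta = ThetaParams(p[:j], p[j:], rho)
    ll = loglike(series, spec, theta, corr_spec)
    return FitResult(
        theta=theta,
        spec=spec,
        corr_spec=corr_spec,
        loglike=ll,
        converged=bool(converged or np.max(np.abs(g)) < 1e-6),
        iterations=iters,
        approach="gee-extended",
        max_grad=float(np.max(np.abs(g))),
        param_names=_names(spec, with_rho=False),
    )


def _names(spec: PowerSpec, with_rho: bool) -> tuple:
    names = []
    if spec.mean_intercept:
        names.append("mean:1")
    names += [f"mean:t^{p:g}" for p in spec.mean_powers]
    if spec.disp_intercept:
        names.append("disp:1")
    names += [f"disp:t^{p:g}" for p in spec.disp_powers]
    if with_rho:
        names.append("rho")
    return tuple(names)
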