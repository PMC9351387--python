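"""Working correlation structures and moment estimators.

Three structures are supported for the N x N working correlation R(rho):

* ``ind`` — identity (a Poisson-process assumption, no parameter);
* ``exch`` — exchangeable, constant off-diagonal rho, valid for
  rho in (-1/(N-1), 1);
* ``ar1`` — autoregressive of order 1.  The spatial variant (default) decays
  with the actual time distance, ``R_{t,t'} = rho^|t - t'|``, which handles
  missing days naturally; the non-spatial variant uses index distance.

Also here: the bias-adjusted moment estimators for the constant dispersion
(from Pearson residuals) and for rho (from standardized residuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor

__all__ = [
    "CorrelationSpec",
    "corr_matrix",
    "corr_derivative",
    "rho_bounds",
    "moment_rho",
    "pearson_phi0",
]

_EPS = 1e-6  # interior margin on open validity intervals

_STRUCTURES = ("ind", "exch", "ar1")


@dataclass(frozen=True)
class CorrelationSpec:
    """Working correlation structure; ``spatial`` applies to AR1 only."""

    structure: str = "ind"
    spatial: bool = True

    def __post_init__(self) -> None:
        s = self.structure.lower()
        if s not in _STRUCTURES:
            raise ValueError(f"unknown correlation structure {self.structure!r}")
        object.__setattr__(self, "structure", s)

    @property
    def has_rho(self) -> bool:
        return self.structure != "ind"


def _gaps(spec: CorrelationSpec, times: np.ndarray) -> np.ndarray:
    """Pairwise |t(i) - t(i')| matrix (index distance when non-spatial)."""
    t = np.asarray(times, dtype=float)
    if spec.structure == "ar1" and not spec.spatial:
        t = np.arange(1.0, t.size + 1.0)
    return np.abs(t[:, None] - t[None, :])


def corr_matrix(spec: CorrelationSpec, rho: float, times) -> np.ndarray:
    """Working correlation R(rho) at the given observation times."""
    times = np.asarray(times, dtype=float)
    n = times.size
    if spec.structure == "ind" or n == 1:
        return np.eye(n)
    lo, hi = rho_bounds(spec, n)
    if not (lo <= rho <= hi):
        raise ValueError(
            f"rho={rho:g} outside the {spec.structure} validity interval ({lo:g}, {hi:g})"
        )
    if spec.structure == "exch":
        return np.full((n, n), rho) + (1.0 - rho) * np.eye(n)
    gaps = _gaps(spec, times)
    if rho < 0 and np.any(np.abs(gaps - np.round(gaps)) > 1e-9):
        raise ValueError("negative AR1 rho requires integer time gaps")
    if rho == 0.0:
        return np.eye(n)
    return np.sign(rho) ** np.round(gaps) * np.abs(rho) ** gaps if rho < 0 else rho**gaps


def corr_derivative(spec: CorrelationSpec, rho: float, times, order: int = 1) -> np.ndarray:
    """First or second derivative of R(rho) in rho (zero diagonal)."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    times = np.asarray(times, dtype=float)
    n = times.size
    if spec.structure == "ind":
        return np.zeros((n, n))
    if spec.structure == "exch":
        if order == 1:
            return np.ones((n, n)) - np.eye(n)
        return np.zeros((n, n))
    gaps = _gaps(spec, times)
    off = ~np.eye(n, dtype=bool)
    out = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        if order == 1:
            out[off] = gaps[off] * _signed_power(rho, gaps[off] - 1.0)
        else:
            out[off] = gaps[off] * (gaps[off] - 1.0) * _signed_power(rho, gaps[off] - 2.0)
    return out


def _signed_power(rho: float, expo: np.ndarray) -> np.ndarray:
    """rho**expo for possibly negative rho with (near-)integer exponents."""
    if rho == 0.0:
        return np.where(expo == 0.0, 1.0, np.where(expo > 0.0, 0.0, np.nan))
    if rho > 0:
        return rho**expo
    e = np.round(expo)
    if np.any(np.abs(expo - e) > 1e-9):
        raise ValueError("negative AR1 rho requires integer time gaps")
    return np.sign(rho) ** e * np.abs(rho) ** expo


def rho_bounds(spec: CorrelationSpec, n: int) -> tuple[float, float]:
    """Open interval of rho values keeping R positive definite (with margin)."""
    if spec.structure == "ind":
        return (0.0, 0.0)
    if n < 2:
        raise ValueError("rho bounds require at least 2 observations")
    if spec.structure == "exch":
        return (-1.0 / (n - 1) + _EPS, 1.0 - _EPS)
    return (-1.0 + _EPS, 1.0 - _EPS)


def clip_rho(spec: CorrelationSpec, rho: float, n: int, warn: bool = True) -> float:
    """Clip rho to the interior of its validity interval."""
    if spec.structure == "ind":
        return 0.0
    if n < 2:
        return rho
    lo, hi = rho_bounds(spec, n)
    clipped = min(max(rho, lo), hi)
    if warn and clipped != rho:
        warnings.warn(
            f"moment estimate rho={rho:.4g} outside ({lo:.4g}, {hi:.4g}); clipped",
            stacklevel=2,
        )
    return clipped


def eval_rho(spec: CorrelationSpec, rho: float, n: int) -> float:
    """Clip rho for *evaluating* the likelihood-like value on n observations.

    A rho estimated on one subset can be invalid (or nearly singular) on a
    larger one — for EXCH the smallest eigenvalue of R is 1 + (n-1) rho.
    Evaluation keeps that eigenvalue at least 0.01 so a boundary estimate
    does not blow up the quadratic form.
    """
    if spec.structure == "ind" or n < 2:
        return 0.0 if spec.structure == "ind" else rho
    lo, hi = rho_bounds(spec, n)
    if spec.structure == "exch":
        lo = max(lo, -(1.0 - 1e-2) / (n - 1))
    return min(max(rho, lo), hi)


def moment_rho(stde, times, spec: CorrelationSpec, n_mean_params: int) -> float:
    """Bias-adjusted moment estimate of rho from standardized residuals.

    EXCH averages all distinct cross-products with denominator
    ``N(N-1)/2 - J``; AR1 averages lag-1 products with denominator
    ``N - 1 - J``, each product raised to ``1/|t(i)-t(i+1)|`` in the spatial
    case so that gap-separated pairs contribute on the lag-1 scale.  Negative
    products under fractional roots use the signed root
    ``sign(p) |p|^{1/gap}``, which reduces to the plain product at unit gaps.
    Estimates outside the validity interval are clipped (with a warning).
    """
    stde = np.asarray(stde, dtype=float)
    times = np.asarray(times, dtype=float)
    n = stde.size
    j = int(n_mean_params)
    if spec.structure == "ind":
        return 0.0
    if spec.structure == "exch":
        denom = n * (n - 1) / 2 - j
        if denom <= 0:
            raise ValueError(f"N(N-1)/2 - J = {denom:g} must be positive")
        total = (np.sum(stde) ** 2 - np.sum(stde**2)) / 2.0
        return clip_rho(spec, total / denom, n)
    denom = n - 1 - j
    if denom <= 0:
        raise ValueError(f"N - 1 - J = {denom} must be positive")
    prods = stde[:-1] * stde[1:]
    if spec.spatial:
        gaps = np.abs(np.diff(times))
        terms = np.sign(prods) * np.abs(prods) ** (1.0 / gaps)
    else:
        terms = prods
    return clip_rho(spec, float(np.sum(terms)) / denom, n)


def pearson_phi0(pearson, n_mean_params: int) -> float:
    """Bias-adjusted constant dispersion estimate sum(Pe^2) / (N - J)."""
    pe = np.asarray(pearson, dtype=float)
    n, j = pe.size, int(n_mean_params)
    if n - j <= 0:
        raise ValueError(f"N - J = {n - j} must be positive")
    return float(np.sum(pe**2) / (n - j))


def assert_positive_definite(R: np.ndarray, label: str = "R") -> None:
    try:
        cho_factor(R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(f"{label} is not positive definite") from exc
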