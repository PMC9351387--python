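"""Shared fit-result container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import PowerSpec, ThetaParams
from .correlation import CorrelationSpec

__all__ = ["FitResult"]


@dataclass
class FitResult:
    """Outcome of one model fit.

    ``spec`` is the power spec under which ``theta`` is interpreted; for
    standard GEE the dispersion side is the implied intercept-only model with
    ``beta_prime = [log(phi0)]`` so that the likelihood-like value is always
    computable from ``(spec, theta)`` alone.  ``cov`` (= -H^{-1}) is present
    only for fully likelihood-based (ELMM) fits.
    """

    theta: ThetaParams
    spec: PowerSpec
    corr_spec: CorrelationSpec
    loglike: float
    converged: bool
    iterations: int
    approach: str
    max_grad: float = np.nan
    phi0: float | None = None
    cov: np.ndarray | None = None
    param_names: tuple = ()

    @property
    def rho(self) -> float:
        return self.theta.rho

    def flat_params(self) -> np.ndarray:
        """theta as one vector (beta, beta', and rho when the structure has one)."""
        parts = [self.theta.beta, self.theta.beta_prime]
        if self.corr_spec.has_rho and self.approach == "elmm":
            parts.append([self.theta.rho])
        return np.concatenate([np.atleast_1d(p) for p in parts])
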