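"""Fractional-polynomial design construction and model-state evaluation.

The mean model is log-linear in real-power transforms of time,
``log mu = sum_j beta_j t^{p_j} (+ offset)``, and the dispersion model is
log-linear in its own set of transforms, ``log phi = sum_j beta'_j t^{p'_j}``
(optionally carrying the offset as well).  The extended variance is
``sigma^2 = phi * mu`` — the Poisson variance inflated by a time-varying
dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .series import CountSeries

__all__ = [
    "PowerSpec",
    "ThetaParams",
    "ModelState",
    "build_design",
    "evaluate_model",
    "rates_view",
]

# exp() overflows double precision just above 709; fail loudly before that.
_ETA_CAP = 700.0


@dataclass(frozen=True)
class PowerSpec:
    """Power-transform design for the mean and dispersion submodels.

    ``mean_powers`` / ``disp_powers`` list the real exponents ``p`` of the
    transforms ``t^p``; the intercept flags prepend a column of ones.  A
    power of 0 duplicates the intercept column and is rejected when the
    corresponding intercept is present.  ``offsets_in_dispersion=None``
    resolves to True exactly when the series carries totals, which makes the
    rate variance factor as ``sigma'^2 = phi' * mu'``.
    """

    mean_powers: tuple = ()
    mean_intercept: bool = True
    disp_powers: tuple = ()
    disp_intercept: bool = True
    offsets_in_dispersion: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_powers", tuple(float(p) for p in self.mean_powers))
        object.__setattr__(self, "disp_powers", tuple(float(p) for p in self.disp_powers))
        for powers, intercept, label in (
            (self.mean_powers, self.mean_intercept, "mean"),
            (self.disp_powers, self.disp_intercept, "dispersion"),
        ):
            if len(set(powers)) != len(powers):
                raise ValueError(f"duplicate powers in {label} model")
            if not all(np.isfinite(p) for p in powers):
                raise ValueError(f"non-finite power in {label} model")
            if intercept and 0.0 in powers:
                raise ValueError(f"power 0 duplicates the {label} intercept column")
            if not intercept and len(powers) == 0:
                raise ValueError(f"{label} model has no intercept and no transforms")

    @property
    def n_mean(self) -> int:
        """Number of mean coefficients J."""
        return len(self.mean_powers) + int(self.mean_intercept)

    @property
    def n_disp(self) -> int:
        """Number of dispersion coefficients J'."""
        return len(self.disp_powers) + int(self.disp_intercept)

    def constant_dispersion(self) -> "PowerSpec":
        """The same mean model with an intercept-only dispersion."""
        return replace(self, disp_powers=(), disp_intercept=True)


@dataclass
class ThetaParams:
    """Parameter vector theta = (beta, beta', rho)."""

    beta: np.ndarray
    beta_prime: np.ndarray
    rho: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.beta_prime = np.atleast_1d(np.asarray(self.beta_prime, dtype=float))
        self.rho = float(self.rho)


@dataclass
class ModelState:
    """Means, dispersions, extended variances and residuals at one theta."""

    mu: np.ndarray
    phi: np.ndarray
    var_ext: np.ndarray
    sd_ext: np.ndarray
    resid: np.ndarray
    stde: np.ndarray
    pearson: np.ndarray


def build_design(times, powers, intercept: bool) -> np.ndarray:
    """N x J design matrix: optional leading ones column, then ``t^p`` columns.

    Powers are evaluated as ``exp(p * log t)``, so times must be strictly
    positive whenever any power is fractional or negative (always, here:
    the container enforces positive times).
    """
    t = np.asarray(times, dtype=float)
    powers = tuple(float(p) for p in powers)
    if not intercept and len(powers) == 0:
        raise ValueError("design needs an intercept or at least one power")
    if powers and np.any(t <= 0):
        raise ValueError("power transforms require strictly positive times")
    cols = []
    if intercept:
        cols.append(np.ones_like(t))
    for p in powers:
        cols.append(np.exp(p * np.log(t)) if p != 0.0 else np.ones_like(t))
    return np.column_stack(cols)


def mean_design(series: CountSeries, spec: PowerSpec) -> np.ndarray:
    return build_design(series.times, spec.mean_powers, spec.mean_intercept)


def disp_design(series: CountSeries, spec: PowerSpec) -> np.ndarray:
    return build_design(series.times, spec.disp_powers, spec.disp_intercept)


def _disp_offsets(series: CountSeries, spec: PowerSpec) -> np.ndarray:
    use = spec.offsets_in_dispersion
    if use is None:
        use = series.totals is not None
    return series.offsets if use else np.zeros(series.n)


def evaluate_model(series: CountSeries, spec: PowerSpec, theta: ThetaParams) -> ModelState:
    """Evaluate mu, phi, sigma and the residual vectors at ``theta``.

    ``mu = exp(X beta + o)`` and ``phi = exp(X' beta' + o')`` where ``o`` is
    the log-total offset and ``o'`` is the same offset when it enters the
    dispersion model.  Raises on linear predictors that would overflow.
    """
    X = mean_design(series, spec)
    Xp = disp_design(series, spec)
    if X.shape[1] != theta.beta.size:
        raise ValueError(f"beta has {theta.beta.size} entries, design has {X.shape[1]} columns")
    if Xp.shape[1] != theta.beta_prime.size:
        raise ValueError(
            f"beta' has {theta.beta_prime.size} entries, design has {Xp.shape[1]} columns"
        )
    eta = X @ theta.beta + series.offsets
    eta_d = Xp @ theta.beta_prime + _disp_offsets(series, spec)
    for name, vec in (("mean", eta), ("dispersion", eta_d)):
        bad = np.abs(vec) > _ETA_CAP
        if np.any(bad):
            t_bad = series.times[np.argmax(bad)]
            raise OverflowError(
                f"{name} linear predictor overflows exp() at time {t_bad:g}"
            )
    mu = np.exp(eta)
    phi = np.exp(eta_d)
    var_ext = phi * mu
    sd_ext = np.sqrt(var_ext)
    resid = series.counts - mu
    return ModelState(
        mu=mu,
        phi=phi,
        var_ext=var_ext,
        sd_ext=sd_ext,
        resid=resid,
        stde=resid / sd_ext,
        pearson=resid / np.sqrt(mu),
    )


def rates_view(state: ModelState, series: CountSeries):
    """Rate-scale view (mu', phi', sigma'^2) of a count-scale state.

    mu' = mu / Y and sigma'^2 = sigma^2 / Y^2 = phi' * mu' with
    phi' = phi / Y (the dispersion model carrying one offset copy).
    """
    if series.totals is None:
        raise ValueError("rates require totals")
    mu_rate = state.mu / series.totals
    phi_rate = state.phi / series.totals
    var_rate = state.var_ext / series.totals**2
    return mu_rate, phi_rate, var_rate
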