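"""Correlated overdispersed count-series simulation with known ground truth.

The generator draws from a Gaussian copula: a latent multivariate-normal
vector with correlation R(rho) is pushed through the standard-normal CDF and
the resulting uniforms through count quantile functions matched to the model
moments — negative binomial with mean mu_i and variance phi_i * mu_i when
phi_i > 1, Poisson when phi_i = 1.  The working model specifies only first
and second moments plus a correlation, so any count law matching them is
admissible; the copula supplies lag-decaying dependence.  Note the induced
count-scale correlation is attenuated relative to the latent rho, so
recovery checks should fit the model rather than match raw count
correlations.

Fixture generators emulate the shapes of three example patient series
(daily symptom flares, as-needed medication counts, and per-dose medication
rates over subperiods); they are synthetic stand-ins, not real patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .basis import build_design
from .correlation import CorrelationSpec, corr_matrix
from .series import CountSeries

__all__ = ["SimSpec", "simulate_series", "patient_fixtures"]


@dataclass(frozen=True)
class SimSpec:
    """Ground-truth specification for one simulated series.

    Times default to 1..n; ``missing`` lists times dropped *after*
    generation (emulating missed days).  ``beta`` / ``beta_prime`` are the
    true log-linear coefficients for means and dispersions on the power
    transforms listed next to them.  ``rho`` is the latent-normal copula
    correlation parameter for ``structure``.
    """

    n: int
    mean_powers: tuple = ()
    mean_intercept: bool = True
    beta: tuple = (1.0,)
    disp_powers: tuple = ()
    disp_intercept: bool = True
    beta_prime: tuple = (0.0,)
    structure: CorrelationSpec = field(default_factory=CorrelationSpec)
    rho: float = 0.0
    totals: float | tuple | None = None
    missing: tuple = ()
    seed: int = 0


def simulate_series(sim: SimSpec):
    """Draw one series; returns ``(CountSeries, truth)``.

    ``truth`` records the realized mu, phi and the generating parameters on
    the kept (non-missing) grid.  Raises if any implied dispersion is below 1
    (the matched negative binomial cannot represent under-dispersion).
    """
    times = np.arange(1.0, sim.n + 1.0)
    X = build_design(times, sim.mean_powers, sim.mean_intercept)
    Xp = build_design(times, sim.disp_powers, sim.disp_intercept)
    beta = np.asarray(sim.beta, dtype=float)
    bprime = np.asarray(sim.beta_prime, dtype=float)
    if X.shape[1] != beta.size or Xp.shape[1] != bprime.size:
        raise ValueError("coefficient lengths do not match the power specs")
    totals = None
    offsets = np.zeros(sim.n)
    if sim.totals is not None:
        totals = np.broadcast_to(np.asarray(sim.totals, dtype=float), (sim.n,)).copy()
        if np.any(totals <= 0):
            raise ValueError("totals must be positive")
        offsets = np.log(totals)
    mu = np.exp(X @ beta + offsets)
    phi = np.exp(Xp @ bprime + offsets)
    if np.any(phi < 1.0 - 1e-12):
        raise ValueError(
            f"dispersion below 1 (min {phi.min():.4g}): under-dispersion unsupported"
        )

    rng = np.random.default_rng(sim.seed)
    R = corr_matrix(sim.structure, sim.rho, times)
    L = np.linalg.cholesky(R)
    z = L @ rng.standard_normal(sim.n)
    u = stats.norm.cdf(z)
    # guard against u == 0/1 at extreme latent draws
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    y = np.empty(sim.n)
    for i in range(sim.n):
        if phi[i] <= 1.0 + 1e-8:
            y[i] = stats.poisson.ppf(u[i], mu[i])
        else:
            size = mu[i] / (phi[i] - 1.0)  # NB(size, p): mean mu, variance phi*mu
            p = 1.0 / phi[i]
            y[i] = stats.nbinom.ppf(u[i], size, p)

    keep = ~np.isin(times, np.asarray(sim.missing, dtype=float))
    series = CountSeries(
        times=times[keep],
        counts=y[keep],
        totals=None if totals is None else totals[keep],
    )
    truth = {
        "mu": mu[keep],
        "phi": phi[keep],
        "beta": beta,
        "beta_prime": bprime,
        "rho": sim.rho,
        "structure": sim.structure.structure,
    }
    return series, truth


# ---------------------------------------------------------------------------
# patient-shaped fixtures (synthetic)
# ---------------------------------------------------------------------------

_PRN_MISSING = (4.0, 14.0, 52.0, 56.0, 74.0, 81.0, 85.0, 89.0)


def patient_fixtures(which: str, seed: int = 0) -> CountSeries:
    """Synthetic series shaped like the three example patients.

    * ``flares`` — 34-day grid minus day 33 (N=33), small counts with an
      increasing trend and mildly time-varying dispersion, independent.
    * ``prn`` — 100-day grid minus 8 scattered days (N=92), decreasing
      counts, spatial AR1 correlation 0.45.
    * ``atc`` — 30 subperiods of 3.03 days with 5 scheduled doses per day
      (totals 15.15), counts 0-18 decreasing, spatial AR1 correlation 0.75
      and dispersion shrinking over time.
    """
    if which == "flares":
        sim = SimSpec(
            n=34,
            mean_powers=(0.5,),
            mean_intercept=False,
            beta=(0.14,),
            disp_powers=(0.5,),
            disp_intercept=False,
            beta_prime=(0.05,),
            structure=CorrelationSpec("ind"),
            missing=(33.0,),
            seed=seed,
        )
    elif which == "prn":
        sim = SimSpec(
            n=100,
            mean_powers=(0.4,),
            mean_intercept=True,
            beta=(1.32, -0.40),
            disp_powers=(),
            disp_intercept=True,
            beta_prime=(0.18,),
            structure=CorrelationSpec("ar1", spatial=True),
            rho=0.45,
            missing=_PRN_MISSING,
            seed=seed,
        )
    elif which == "atc":
        sim = SimSpec(
            n=30,
            mean_powers=(1.1,),
            mean_intercept=False,
            beta=(-0.030,),
            disp_powers=(-1.5,),
            disp_intercept=True,
            beta_prime=(-2.6, 0.7),
            structure=CorrelationSpec("ar1", spatial=True),
            rho=0.75,
            totals=5.0 * (91.0 / 30.0),  # doses/day times subperiod length
            seed=seed,
        )
    else:
        raise ValueError(f"unknown fixture {which!r}; use flares, prn or atc")
    series, _ = simulate_series(sim)
    return series
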