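"""Simulate a correlated overdispersed count series and recover its truth.

Draws counts from a Gaussian copula with negative-binomial margins (mean
exp(0.5 + 0.08 sqrt t), dispersion phi = exp(0.5), latent AR1 correlation
0.5) and fits the matching model by extended linear mixed modeling.  Note
the fitted correlation targets the count-scale correlation, which the
copula attenuates below the latent 0.5.
"""

import numpy as np

from countraj import CorrelationSpec, PowerSpec, SimSpec, fit_elmm, simulate_series

sim = SimSpec(n=200, mean_powers=(0.5,), beta=(0.5, 0.08), beta_prime=(0.5,),
              structure=CorrelationSpec("ar1"), rho=0.5, seed=4)
series, truth = simulate_series(sim)
fit = fit_elmm(series, PowerSpec(mean_powers=(0.5,)), CorrelationSpec("ar1"))

print(f"N = {series.n}, counts range {int(series.counts.min())}..{int(series.counts.max())}")
print(f"truth:    beta = {truth['beta']}, log-dispersion = {truth['beta_prime']}, latent rho = {truth['rho']}")
print(f"estimate: beta = {np.round(fit.theta.beta, 3)}, "
      f"log-dispersion = {np.round(fit.theta.beta_prime, 3)}, rho = {fit.rho:.3f}")
print("Estimates should sit near truth; rho lands slightly below 0.5 because")
print("pushing a latent normal through count quantiles attenuates correlation.")
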