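"""Likelihood-like function and k-fold likelihood-like cross-validation (LCV).

The likelihood-like function applies the multivariate-normal log-density to
the counts with the model's mean vector and covariance
``Sigma = Diag(sigma) R(rho) Diag(sigma)``; the data are not normal, but the
function is used like a likelihood for estimation and scoring.

LCV partitions the observation times into k random folds, refits the model
with each fold deleted, and scores the deleted fold conditionally on all
earlier folds.  The score is the geometric mean per observation of those
conditional terms; larger is better.  Models are comparable only when scored
with the same fold seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .basis import ModelState, PowerSpec, ThetaParams, evaluate_model
from .correlation import CorrelationSpec, corr_matrix, eval_rho
from .results import FitResult
from .series import CountSeries

__all__ = ["loglike", "FoldPlan", "make_folds", "LCVResult", "lcv_score"]

_LOG_2PI = math.log(2.0 * math.pi)


def loglike(
    series: CountSeries,
    spec: PowerSpec,
    theta: ThetaParams,
    corr_spec: CorrelationSpec,
) -> float:
    """Log likelihood-like value ell = -e' Sigma^-1 e/2 - log|Sigma|/2 - N log(2 pi)/2.

    Computed in standardized form: with stde = e / sigma,
    ``ell = -stde' R^-1 stde / 2 - log|R| / 2 - sum(log sigma) - N log(2 pi) / 2``
    using a Cholesky factorization of R (never a raw determinant).
    """
    state = evaluate_model(series, spec, theta)
    return _loglike_state(state, series, theta.rho, corr_spec)


def _loglike_state(
    state: ModelState, series: CountSeries, rho: float, corr_spec: CorrelationSpec
) -> float:
    n = series.n
    stde = state.stde
    if corr_spec.structure == "ind" or n == 1:
        quad = float(stde @ stde)
        logdet_r = 0.0
    else:
        R = corr_matrix(corr_spec, rho, series.times)
        try:
            c, low = cho_factor(R, lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"R(rho={rho:g}, {corr_spec.structure}) is not positive definite"
            ) from exc
        quad = float(stde @ cho_solve((c, low), stde))
        logdet_r = 2.0 * float(np.sum(np.log(np.diag(c))))
    return -0.5 * quad - 0.5 * logdet_r - float(np.sum(np.log(state.sd_ext))) - 0.5 * n * _LOG_2PI


@dataclass(frozen=True)
class FoldPlan:
    """Random fold assignment of the N observation times.

    Each time gets an independent uniform label in 1..k, so fold sizes vary
    and folds can be empty (empty folds are skipped when scoring).  The
    cumulative unions T+(f) collect all times with label <= f.
    """

    k: int
    seed: int
    labels: np.ndarray  # fold label in 1..k per observation, in time order

    def fold_idx(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.labels == f)

    def complement_idx(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.labels != f)

    def union_idx(self, f: int) -> np.ndarray:
        """Indices of T+(f), the union of folds 1..f (empty for f=0)."""
        return np.flatnonzero(self.labels <= f)

    @property
    def sizes(self) -> list[int]:
        return [int(np.sum(self.labels == f)) for f in range(1, self.k + 1)]


def make_folds(times, k: int, seed: int) -> FoldPlan:
    """Assign each observation an iid uniform fold label in 1..k."""
    if k < 2:
        raise ValueError("at least 2 folds are required")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    labels = rng.integers(1, k + 1, size=times.size)
    return FoldPlan(k=int(k), seed=int(seed), labels=labels)


@dataclass
class LCVResult:
    """LCV score with its per-fold log terms.

    ``score = exp(sum(log_terms) / n_used)``; NaN when any deleted fit failed
    (``valid=False``), in which case the model is rejected in searches.
    """

    score: float
    log_terms: dict
    n_used: int
    seed: int
    k: int
    valid: bool = True


def lcv_score(
    series: CountSeries,
    fold_plan: FoldPlan,
    fitter: Callable[[CountSeries], FitResult | None],
) -> LCVResult:
    """k-fold likelihood-like cross-validation score.

    For each non-empty fold f the model is refit on the complement, and the
    fold is scored conditionally on the union of earlier folds as a
    difference of joint log likelihood-like values on nested unions:
    ``log LCV_f = ell(T+(f); theta_del) - ell(T+(f-1); theta_del)`` with
    ``ell(empty) = 0``.  The score is ``exp(sum_f log LCV_f / N)``.
    """
    n = series.n
    log_terms: dict[int, float] = {}
    for f in range(1, fold_plan.k + 1):
        if fold_plan.fold_idx(f).size == 0:
            continue  # empty folds are dropped
        comp = fold_plan.complement_idx(f)
        fit = fitter(series.subset(comp))
        if fit is None or not fit.converged:
            return LCVResult(
                score=float("nan"),
                log_terms=log_terms,
                n_used=n,
                seed=fold_plan.seed,
                k=fold_plan.k,
                valid=False,
            )
        log_terms[f] = _conditional_term(series, fold_plan, f, fit)
    total = float(sum(log_terms.values()))
    return LCVResult(
        score=math.exp(total / n),
        log_terms=log_terms,
        n_used=n,
        seed=fold_plan.seed,
        k=fold_plan.k,
    )


def _conditional_term(
    series: CountSeries, fold_plan: FoldPlan, f: int, fit: FitResult
) -> float:
    ell = {}
    for g, idx in (("now", fold_plan.union_idx(f)), ("prev", fold_plan.union_idx(f - 1))):
        if idx.size == 0:
            ell[g] = 0.0
            continue
        sub = series.subset(idx)
        # a rho estimated on the complement can sit outside the (EXCH)
        # validity interval of a differently-sized union; evaluate at the
        # nearest point that keeps R safely positive definite
        rho = eval_rho(fit.corr_spec, fit.theta.rho, sub.n)
        theta = ThetaParams(fit.theta.beta, fit.theta.beta_prime, rho)
        ell[g] = loglike(sub, fit.spec, theta, fit.corr_spec)
    return ell["now"] - ell["prev"]
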