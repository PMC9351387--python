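"""High-level fitting and scoring entry points.

``fit_model`` dispatches on the estimation approach; ``score_model`` fits the
full data, then computes the k-fold LCV score with deleted fits warm-started
at the full-data estimate (retrying once from the default initializer before
declaring the score invalid).
"""

from __future__ import annotations

import numpy as np

from .basis import PowerSpec, ThetaParams
from .correlation import CorrelationSpec
from .elmm import fit_elmm
from .gee import fit_gee
from .likelihood import FoldPlan, LCVResult, lcv_score, make_folds
from .results import FitResult
from .series import CountSeries

__all__ = ["APPROACHES", "fit_model", "score_model", "make_folds"]

APPROACHES = ("gee", "gee-extended", "elmm")


def fit_model(
    series: CountSeries,
    spec: PowerSpec,
    corr_spec: CorrelationSpec,
    approach: str = "elmm",
    init: ThetaParams | None = None,
    **opts,
) -> FitResult:
    """Fit one model with the chosen approach.

    ``gee`` — standard GEE (constant moment-estimated dispersion);
    ``gee-extended`` — joint mean/dispersion estimating equations;
    ``elmm`` — full Newton maximization of the likelihood-like function.
    """
    if approach == "gee":
        return fit_gee(series, spec, corr_spec, mode="standard", init=init, **opts)
    if approach == "gee-extended":
        return fit_gee(series, spec, corr_spec, mode="extended", init=init, **opts)
    if approach == "elmm":
        return fit_elmm(series, spec, corr_spec, init=init, **opts)
    raise ValueError(f"unknown approach {approach!r}; choose from {APPROACHES}")


def _deleted_fitter(spec, corr_spec, approach, warm: ThetaParams | None):
    """Fold-complement fitter: warm start, one cold retry, else invalid."""

    def fitter(sub: CountSeries) -> FitResult | None:
        for init in (warm, None):
            try:
                fit = fit_model(sub, spec, corr_spec, approach, init=init)
            except Exception:
                continue
            if fit.converged and np.isfinite(fit.loglike):
                return fit
        return None

    return fitter


def score_model(
    series: CountSeries,
    spec: PowerSpec,
    corr_spec: CorrelationSpec,
    approach: str = "elmm",
    fold_plan: FoldPlan | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[LCVResult, FitResult | None]:
    """Full-data fit plus k-fold LCV score for one model.

    Returns ``(lcv, full_fit)``; ``full_fit`` is None (and the score NaN)
    when even the full-data fit fails.
    """
    if fold_plan is None:
        fold_plan = make_folds(series.times, k, seed)
    try:
        full = fit_model(series, spec, corr_spec, approach)
    except Exception:
        full = None
    if full is None or not full.converged:
        return (
            LCVResult(
                score=float("nan"),
                log_terms={},
                n_used=series.n,
                seed=fold_plan.seed,
                k=fold_plan.k,
                valid=False,
            ),
            full,
        )
    fitter = _deleted_fitter(spec, corr_spec, approach, full.theta)
    try:
        lcv = lcv_score(series, fold_plan, fitter)
    except (OverflowError, FloatingPointError, np.linalg.LinAlgError, ValueError):
        # evaluating a deleted estimate on a union can overflow for extreme
        # candidate transforms; such a model is simply not scoreable
        lcv = LCVResult(
            score=float("nan"), log_terms={}, n_used=series.n,
            seed=fold_plan.seed, k=fold_plan.k, valid=False,
        )
    return lcv, full
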