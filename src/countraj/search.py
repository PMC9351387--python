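"""Adaptive fractional-polynomial model search driven by LCV scores.

Model selection runs in two phases.  The *expansion* phase grows the model,
repeatedly proposing the best new power transform of time for the mean model
and then for the dispersion model — the candidate power is grid-searched on a
coarse grid and refined locally to two decimals.  The *contraction* phase
prunes toward parsimony: it tries removing each transform (and each
intercept) in turn, re-refines the remaining powers, and accepts the best
tolerable removal.  All comparisons use the same fold seed so scores are
comparable.

Both phases prefer the simpler model unless the richer one is *significantly*
better under an LCV ratio test: a relative LCV difference is substantial when
it exceeds the cutoff ``1 - exp(-chi2_{1,0.95} / (2N))`` (the per-observation
geometric-mean analogue of a 1-df likelihood-ratio test).  Expansion adds a
transform only when the incumbent falls more than the cutoff below the
candidate; contraction removes one whenever the drop stays within the cutoff.
Maximizing a single cross-validation split over many candidate powers
inflates the winning score by selection noise, so a flat near-zero tolerance
would overfit null data; the significance cutoff counters exactly that.

The grid, refinement steps and cutoffs are this package's concrete choices
and are all overridable in :class:`SearchConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .api import score_model
from .basis import PowerSpec
from .correlation import CorrelationSpec
from .likelihood import FoldPlan, LCVResult, make_folds
from .results import FitResult
from .series import CountSeries

__all__ = [
    "SearchConfig",
    "SearchStep",
    "SearchTrace",
    "lcv_ratio_cutoff",
    "expand_phase",
    "contract_phase",
    "adaptive_fit",
]


def lcv_ratio_cutoff(n: int, comparisons: int = 1) -> float:
    """Substantial relative LCV difference for n observations.

    ``1 - exp(-chi2_{1, 1-0.05/m} / (2 n))``: two models whose
    per-observation scores differ by less than this are statistically
    indistinguishable under a 1-df likelihood-ratio-style comparison, so the
    simpler one is preferred.  ``comparisons`` Bonferroni-adjusts the level
    when the richer model was chosen as the best of m candidates — the
    maximum of m scores on one cross-validation split is inflated by
    selection noise, and an unadjusted cutoff would admit spurious
    transforms on null data.
    """
    from scipy.stats import chi2

    q = float(chi2.ppf(1.0 - 0.05 / max(comparisons, 1), 1))
    return 1.0 - math.exp(-q / (2.0 * n))


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the two-phase search.

    ``tol_expand`` / ``tol_contract`` are relative LCV cutoffs.  A transform
    is *added* only when the incumbent's score falls more than ``tol_expand``
    below the candidate's (the gain is substantial); a transform is *removed*
    whenever the score falls at most ``tol_contract`` below the incumbent's
    (the loss is insubstantial).  ``None`` (the default) resolves both to the
    sample-size-dependent LCV ratio cutoff :func:`lcv_ratio_cutoff`.
    ``tol_expand = -inf`` accepts every proposal; ``tol_contract = 0`` keeps
    any transform whose removal strictly lowers the score.
    """

    grid_step: float = 0.5
    refine_steps: tuple = (0.1, 0.01)
    power_min: float = -3.0
    power_max: float = 10.0
    max_transforms: int = 3
    tol_expand: float | None = None
    tol_contract: float | None = None
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol_contract is not None and self.tol_contract < 0:
            raise ValueError("tol_contract must be nonnegative")
        steps = (self.grid_step, *self.refine_steps)
        if any(s <= 0 for s in steps) or any(
            later >= earlier for later, earlier in zip(steps[1:], steps[:-1])
        ):
            raise ValueError("grid steps must be positive and decreasing")

    @property
    def n_grid(self) -> int:
        return int(np.floor((self.power_max - self.power_min) / self.grid_step + 1e-9)) + 1

    def expand_cutoff(self, n: int) -> float:
        if self.tol_expand is not None:
            return self.tol_expand
        return lcv_ratio_cutoff(n, comparisons=self.n_grid)

    def contract_cutoff(self, n: int) -> float:
        return lcv_ratio_cutoff(n) if self.tol_contract is None else self.tol_contract


@dataclass
class SearchStep:
    phase: str
    spec: PowerSpec
    lcv: float
    accepted: bool
    note: str = ""


@dataclass
class SearchTrace:
    steps: list = field(default_factory=list)
    seed: int = 0

    def record(self, phase, spec, lcv, accepted, note=""):
        self.steps.append(SearchStep(phase, spec, float(lcv), bool(accepted), note))


class _Scorer:
    """Caches (LCV, fit) per spec so repeated proposals are free."""

    def __init__(self, series, corr_spec, approach, fold_plan: FoldPlan):
        self.series = series
        self.corr_spec = corr_spec
        self.approach = approach
        self.fold_plan = fold_plan
        self._cache: dict = {}

    def key(self, spec: PowerSpec):
        return (
            spec.mean_powers,
            spec.mean_intercept,
            spec.disp_powers,
            spec.disp_intercept,
            spec.offsets_in_dispersion,
        )

    def __call__(self, spec: PowerSpec) -> tuple[float, FitResult | None]:
        k = self.key(spec)
        if k not in self._cache:
            lcv, fit = score_model(
                self.series,
                spec,
                self.corr_spec,
                self.approach,
                fold_plan=self.fold_plan,
            )
            self._cache[k] = (lcv.score if lcv.valid else float("nan"), fit)
        return self._cache[k]


def _with_power(spec: PowerSpec, submodel: str, p: float) -> PowerSpec | None:
    """spec with transform t^p added to the given submodel; None if invalid."""
    powers = spec.mean_powers if submodel == "mean" else spec.disp_powers
    intercept = spec.mean_intercept if submodel == "mean" else spec.disp_intercept
    p = round(p, 6)
    if p in powers or (p == 0.0 and intercept):
        return None
    new = tuple(sorted(powers + (p,)))
    try:
        if submodel == "mean":
            return replace(spec, mean_powers=new)
        return replace(spec, disp_powers=new)
    except ValueError:
        return None


def _replace_power(spec: PowerSpec, submodel: str, old: float, new: float) -> PowerSpec | None:
    powers = spec.mean_powers if submodel == "mean" else spec.disp_powers
    intercept = spec.mean_intercept if submodel == "mean" else spec.disp_intercept
    new = round(new, 6)
    if new == old:
        return spec
    if new in powers or (new == 0.0 and intercept):
        return None
    upd = tuple(sorted(new if q == old else q for q in powers))
    try:
        if submodel == "mean":
            return replace(spec, mean_powers=upd)
        return replace(spec, disp_powers=upd)
    except ValueError:
        return None


def _refine_power(
    scorer: _Scorer, spec: PowerSpec, submodel: str, p: float, config: SearchConfig
) -> tuple[PowerSpec, float, float]:
    """Hill-climb one power on successively finer grids; returns (spec, p, lcv)."""
    best_spec = spec
    best_lcv, _ = scorer(spec)
    for step in config.refine_steps:
        improved = True
        while improved:
            improved = False
            for cand_p in (p - step, p + step):
                if not (config.power_min <= cand_p <= config.power_max):
                    continue
                cand = _replace_power(best_spec, submodel, round(p, 6), cand_p)
                if cand is None or cand is best_spec:
                    continue
                lcv, _ = scorer(cand)
                if np.isfinite(lcv) and lcv > best_lcv:
                    best_spec, best_lcv, p = cand, lcv, round(cand_p, 6)
                    improved = True
                    break
    return best_spec, p, best_lcv


def _best_new_transform(
    scorer: _Scorer, spec: PowerSpec, submodel: str, config: SearchConfig
) -> tuple[PowerSpec, float] | None:
    """Best single added transform for one submodel, grid then refined."""
    grid = np.arange(config.power_min, config.power_max + 1e-9, config.grid_step)
    best = None
    for p in grid:
        cand = _with_power(spec, submodel, p)
        if cand is None:
            continue
        lcv, _ = scorer(cand)
        if np.isfinite(lcv) and (best is None or lcv > best[2]):
            best = (cand, round(float(p), 6), lcv)
    if best is None:
        return None
    cand, p, _ = best
    refined, p, lcv = _refine_power(scorer, cand, submodel, p, config)
    return refined, lcv


def expand_phase(
    series: CountSeries,
    incumbent: PowerSpec,
    approach: str,
    corr_spec: CorrelationSpec,
    config: SearchConfig,
    scorer: _Scorer | None = None,
    trace: SearchTrace | None = None,
) -> PowerSpec:
    """Grow the model while the LCV tolerance rule admits new transforms."""
    fold_plan = make_folds(series.times, config.k, config.seed)
    scorer = scorer or _Scorer(series, corr_spec, approach, fold_plan)
    trace = trace if trace is not None else SearchTrace(seed=config.seed)
    best_lcv, _ = scorer(incumbent)
    if not np.isfinite(best_lcv):
        raise RuntimeError("incumbent model has no valid LCV score")
    trace.record("expand", incumbent, best_lcv, True, "incumbent")
    current = incumbent
    while True:
        grew = False
        for submodel in ("mean", "disp"):
            n_tr = len(current.mean_powers if submodel == "mean" else current.disp_powers)
            if n_tr >= config.max_transforms:
                continue
            proposal = _best_new_transform(scorer, current, submodel, config)
            if proposal is None:
                continue
            cand, lcv = proposal
            # grow only when the incumbent is substantially worse
            accept = best_lcv < (1.0 - config.expand_cutoff(series.n)) * lcv
            trace.record("expand", cand, lcv, accept, f"add {submodel} transform")
            if accept:
                current, best_lcv = cand, lcv
                grew = True
        if not grew:
            break
    return current


def _removals(spec: PowerSpec):
    """All single-removal candidates (transforms and intercepts)."""
    out = []
    for p in spec.mean_powers:
        try:
            out.append((replace(spec, mean_powers=tuple(q for q in spec.mean_powers if q != p)), f"drop mean t^{p:g}"))
        except ValueError:
            pass
    for p in spec.disp_powers:
        try:
            out.append((replace(spec, disp_powers=tuple(q for q in spec.disp_powers if q != p)), f"drop disp t^{p:g}"))
        except ValueError:
            pass
    if spec.mean_intercept and spec.mean_powers:
        out.append((replace(spec, mean_intercept=False), "drop mean intercept"))
    if spec.disp_intercept and spec.disp_powers:
        out.append((replace(spec, disp_intercept=False), "drop disp intercept"))
    return out


def _refine_all(scorer: _Scorer, spec: PowerSpec, config: SearchConfig) -> tuple[PowerSpec, float]:
    """Re-refine every remaining power on the fine grids."""
    lcv, _ = scorer(spec)
    for submodel in ("mean", "disp"):
        for p in list(spec.mean_powers if submodel == "mean" else spec.disp_powers):
            spec, _, lcv = _refine_power(scorer, spec, submodel, p, config)
    return spec, lcv


def contract_phase(
    series: CountSeries,
    spec: PowerSpec,
    approach: str,
    corr_spec: CorrelationSpec,
    config: SearchConfig,
    scorer: _Scorer | None = None,
    trace: SearchTrace | None = None,
) -> PowerSpec:
    """Prune transforms/intercepts while the LCV drop stays within tolerance."""
    fold_plan = make_folds(series.times, config.k, config.seed)
    scorer = scorer or _Scorer(series, corr_spec, approach, fold_plan)
    trace = trace if trace is not None else SearchTrace(seed=config.seed)
    current = spec
    best_lcv, _ = scorer(current)
    while True:
        candidates = []
        for cand, note in _removals(current):
            refined, lcv = _refine_all(scorer, cand, config)
            if np.isfinite(lcv):
                candidates.append((lcv, refined, note))
        if not candidates:
            break
        lcv, cand, note = max(candidates, key=lambda c: c[0])
        # prune whenever the loss is insubstantial
        accept = lcv >= (1.0 - config.contract_cutoff(series.n)) * best_lcv
        trace.record("contract", cand, lcv, accept, note)
        if not accept:
            break
        current, best_lcv = cand, lcv
    return current


def adaptive_fit(
    series: CountSeries,
    approach: str = "elmm",
    corr_spec: CorrelationSpec | None = None,
    config: SearchConfig | None = None,
    incumbent: PowerSpec | None = None,
) -> tuple[PowerSpec, FitResult, LCVResult, SearchTrace]:
    """Run expansion then contraction and refit the winning model.

    Starts from an intercept-only mean and dispersion model unless an
    incumbent is supplied.  Returns the selected spec, its full-data fit, the
    LCV result under the shared fold seed, and the full search trace.
    """
    corr_spec = corr_spec or CorrelationSpec("ind")
    config = config or SearchConfig()
    incumbent = incumbent or PowerSpec()
    fold_plan = make_folds(series.times, config.k, config.seed)
    scorer = _Scorer(series, corr_spec, approach, fold_plan)
    trace = SearchTrace(seed=config.seed)
    expanded = expand_phase(series, incumbent, approach, corr_spec, config, scorer, trace)
    selected = contract_phase(series, expanded, approach, corr_spec, config, scorer, trace)
    from .api import score_model as _score

    lcv, fit = _score(series, selected, corr_spec, approach, fold_plan=fold_plan)
    trace.record("final", selected, lcv.score, True, "selected model")
    return selected, fit, lcv, trace
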