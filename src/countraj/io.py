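"""CSV series I/O and serializable fit reports."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .basis import PowerSpec
from .correlation import CorrelationSpec
from .likelihood import LCVResult
from .results import FitResult
from .series import CountSeries

__all__ = ["read_series_csv", "write_series_csv", "FitReport", "write_fitted_csv"]


def read_series_csv(path) -> CountSeries:
    """Read a ``time,count[,total]`` CSV into a :class:`CountSeries`.

    Rows are sorted by time; duplicate times, non-numeric fields, negative
    counts and non-positive totals are rejected with the offending row
    number (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    for required in ("time", "count"):
        if required not in cols:
            raise ValueError(f"missing required column {required!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"non-numeric value in column {col!r} at data row {row}")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 1
            raise ValueError(f"empty value in column {col!r} at data row {row}")
        df[col] = coerced
    dup = df["time"].duplicated()
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise ValueError(f"duplicate time {df['time'][dup.idxmax()]:g} at data row {row}")
    if (df["count"] < 0).any():
        row = int((df["count"] < 0).idxmax()) + 1
        raise ValueError(f"negative count at data row {row}")
    if "total" in cols and (df["total"] <= 0).any():
        row = int((df["total"] <= 0).idxmax()) + 1
        raise ValueError(f"non-positive total at data row {row}")
    df = df.sort_values("time").reset_index(drop=True)
    return CountSeries(
        times=df["time"].to_numpy(float),
        counts=df["count"].to_numpy(float),
        totals=df["total"].to_numpy(float) if "total" in cols else None,
    )


def write_series_csv(series: CountSeries, path) -> None:
    data = {"time": series.times, "count": series.counts.astype(int)}
    if series.totals is not None:
        data["total"] = series.totals
    pd.DataFrame(data).to_csv(path, index=False)


def write_fitted_csv(series: CountSeries, state, path) -> None:
    """Fitted-values CSV: time, y, mu, sigma, standardized residual."""
    pd.DataFrame(
        {
            "time": series.times,
            "y": series.counts,
            "mu": state.mu,
            "sigma": state.sd_ext,
            "stde": state.stde,
        }
    ).to_csv(path, index=False)


@dataclass
class FitReport:
    """JSON-serializable summary of one fit (mirrors one results-table row)."""

    n: int
    time_range: tuple
    approach: str
    structure: str
    spatial: bool
    mean_powers: tuple
    mean_intercept: bool
    disp_powers: tuple
    disp_intercept: bool
    estimates: dict
    rho: float
    phi0: float | None
    loglike: float
    lcv: float | None
    lcv_k: int | None
    lcv_seed: int | None
    lcv_log_terms: dict | None
    converged: bool
    iterations: int
    adaptive: bool = False
    post_selection: bool = False
    wald: list | None = None
    wall_time_s: float | None = None

    @classmethod
    def from_fit(
        cls,
        series: CountSeries,
        fit: FitResult,
        lcv: LCVResult | None = None,
        adaptive: bool = False,
        wald: list | None = None,
        wall_time_s: float | None = None,
    ) -> "FitReport":
        spec = fit.spec
        names = fit.param_names or tuple(
            f"theta[{i}]" for i in range(fit.flat_params().size)
        )
        estimates = {n: float(v) for n, v in zip(names, fit.flat_params())}
        return cls(
            n=series.n,
            time_range=(float(series.times[0]), float(series.times[-1])),
            approach=fit.approach,
            structure=fit.corr_spec.structure,
            spatial=fit.corr_spec.spatial,
            mean_powers=spec.mean_powers,
            mean_intercept=spec.mean_intercept,
            disp_powers=spec.disp_powers,
            disp_intercept=spec.disp_intercept,
            estimates=estimates,
            rho=float(fit.rho),
            phi0=fit.phi0,
            loglike=float(fit.loglike),
            lcv=None if lcv is None else float(lcv.score),
            lcv_k=None if lcv is None else lcv.k,
            lcv_seed=None if lcv is None else lcv.seed,
            lcv_log_terms=None if lcv is None else {str(f): float(v) for f, v in lcv.log_terms.items()},
            converged=fit.converged,
            iterations=fit.iterations,
            adaptive=adaptive,
            post_selection=adaptive,
            wald=wald,
            wall_time_s=wall_time_s,
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_jsonify)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "FitReport":
        with open(path) as fh:
            data = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown report keys: {sorted(unknown)}")
        for key in ("time_range", "mean_powers", "disp_powers"):
            data[key] = tuple(data[key])
        return cls(**data)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
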