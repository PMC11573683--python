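"""Bootstrap propagation of parameter uncertainty into model predictions.

Each parameter estimate carries its per-source values (one per study or
proteomics sample).  A bootstrap iteration independently resamples every
parameter's source set with replacement to its original size and recomputes
the derived quantities exactly as in the original estimation (specific
activity from the resampled rates and proteome fractions; phi_total_atp
from the resampled per-sample fraction sums).  The resampled parameter
vectors are pushed through the flux model over a glucose-uptake grid and
the mean and 2.5/97.5 percentiles of every observable form the 95%
prediction bands.

Percentile (not bias-corrected) intervals are used, and parameters are
resampled independently of one another.  The production default is 10,000
resamples; tests use fewer for speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CellModel,
    PathwayParams,
    byproduct_rates,
    solve_three_pathway,
    solve_two_pathway,
)
from .estimation import ParamEstimate

__all__ = [
    "BootstrapSummary",
    "bootstrap_params",
    "summarize_params",
    "models_from_resamples",
    "bootstrap_predictions",
    "DEFAULT_N_RESAMPLES",
]

DEFAULT_N_RESAMPLES = 10_000


@dataclass(frozen=True)
class BootstrapSummary:
    """Point estimate with a percentile 95% CI for one target."""

    target: str
    point: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError(f"{self.target}: ci_low > ci_high")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


def _resample_mean(values: np.ndarray, n_resamples: int, rng: np.random.Generator) -> np.ndarray:
    """(n_resamples,) vector of means of with-replacement resamples of
    ``values`` at its original size."""
    n = values.shape[0]
    idx = rng.integers(0, n, size=(n_resamples, n))
    return values[idx].mean(axis=1)


def bootstrap_params(
    estimates: Mapping[str, ParamEstimate],
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Resampled parameter values, name -> (n_resamples,) array.

    Mean-kind estimates resample their source values directly; ratio-kind
    estimates (specific activities) resample their rate and proteome
    fraction components independently and recompute the ratio of means.
    Deterministic given the seed: estimates are processed in sorted name
    order with one child RNG stream each, so adding a parameter does not
    perturb the draws of the others.
    """
    if n_resamples < 1:
        raise ValueError(f"n_resamples must be >= 1, got {n_resamples}")
    root = np.random.default_rng(seed)
    streams = {name: rng for name, rng in zip(sorted(estimates), root.spawn(len(estimates)))}
    out: dict[str, np.ndarray] = {}
    for name in sorted(estimates):
        est = estimates[name]
        rng = streams[name]
        if est.kind == "ratio":
            rates = np.asarray(est.components["rate"], dtype=float)
            phis = np.asarray(est.components["phi"], dtype=float)
            num = _resample_mean(rates, n_resamples, rng)
            den = _resample_mean(phis, n_resamples, rng)
            out[name] = num / den
        else:
            out[name] = _resample_mean(np.asarray(est.sources, dtype=float), n_resamples, rng)
    return out


def summarize_params(
    resamples: Mapping[str, np.ndarray],
    estimates: Mapping[str, ParamEstimate],
    n_resamples: int,
    seed: int,
) -> dict[str, BootstrapSummary]:
    """Percentile 95% CIs for every resampled parameter."""
    out = {}
    for name, draws in resamples.items():
        lo, hi = np.percentile(draws, [2.5, 97.5])
        out[name] = BootstrapSummary(
            target=name,
            point=estimates[name].value,
            ci_low=float(lo),
            ci_high=float(hi),
            n_resamples=n_resamples,
            seed=seed,
        )
    return out


def models_from_resamples(
    template: CellModel, resamples: Mapping[str, np.ndarray]
) -> list[CellModel]:
    """Materialize one CellModel per bootstrap iteration.

    ``template`` fixes the pathway structure (names, stoichiometries); the
    resampled vmax/gamma/phi values are substituted in.  Parameter keys
    follow the estimation naming: vmax_glyc / vmax_resp / vmax_pta,
    gamma_glyc / gamma_resp / gamma_pta, phi_total_atp.
    """
    key_by_pathway = {"fermentation": "glyc", "respiration": "resp", "pta_acka": "pta",
                      "glycolysis": "glyc"}
    n = len(next(iter(resamples.values())))
    models = []
    for i in range(n):
        pathways = []
        for p in template.pathways:
            suffix = key_by_pathway.get(p.name, p.name)
            vmax = resamples.get(f"vmax_{suffix}")
            gamma = resamples.get(f"gamma_{suffix}")
            pathways.append(
                PathwayParams(
                    name=p.name,
                    atp_yield=float(gamma[i]) if gamma is not None else p.atp_yield,
                    specific_activity=(
                        float(vmax[i]) if vmax is not None else p.specific_activity
                    ),
                    o2_per_glucose=p.o2_per_glucose,
                    byproduct_per_glucose=p.byproduct_per_glucose,
                    byproduct_name=p.byproduct_name,
                )
            )
        phi = resamples.get("phi_total_atp")
        phi_val = float(phi[i]) if phi is not None else template.phi_total_atp
        models.append(CellModel(tuple(pathways), min(max(phi_val, 1e-12), 1.0)))
    return models


def _solve(model: CellModel, v: float):
    if len(model.pathways) == 2:
        return solve_two_pathway(model, v)
    return solve_three_pathway(model, v)


def bootstrap_predictions(
    models: Sequence[CellModel],
    v_glucose_grid: Sequence[float],
    n_resamples: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Prediction bands over a glucose-uptake grid.

    For each grid point and observable (by-product production and O2
    consumption), returns the mean over bootstrap models and the 2.5/97.5
    percentiles.  Output columns: v_glucose, observable, mean, lo, hi.

    Note the band mean equals the prediction at the mean parameters only
    inside linear regimes; near regime boundaries the piecewise-linear
    model makes the resample mean differ from the plug-in prediction.
    """
    models = list(models)
    if not models:
        raise ValueError("empty model stream")
    grid = np.asarray(list(v_glucose_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty v_glucose grid")
    if np.any(grid < 0):
        raise ValueError("v_glucose grid must be non-negative")

    observables = sorted(
        {"o2"} | {p.byproduct_name for m in models for p in m.pathways if p.byproduct_name}
    )
    values = {obs: np.zeros((len(models), grid.size)) for obs in observables}
    for i, model in enumerate(models):
        for j, v in enumerate(grid):
            rates = byproduct_rates(_solve(model, float(v)), model)
            for obs in observables:
                values[obs][i, j] = rates.get(obs, 0.0)

    rows = []
    for obs in observables:
        arr = values[obs]
        lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
        mean = arr.mean(axis=0)
        for j, v in enumerate(grid):
            rows.append(
                {
                    "v_glucose": float(v),
                    "observable": obs,
                    "mean": float(mean[j]),
                    "lo": float(lo[j]),
                    "hi": float(hi[j]),
                }
            )
    return pd.DataFrame(rows)
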