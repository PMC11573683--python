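"""Headline comparison: predicted observables across a glucose-uptake grid
versus observed physiology, plus diagnostics.

The model's only input is the glucose uptake rate; for each grid point the
flux optimum is converted into the observables actually measured in the
laboratory — by-product production (acetate/ethanol/lactate) and oxygen
consumption.  Each observation's glucose uptake is reconstructed from the
same observables (O2/6 + by-product/2), so predictions and data live on a
common axis.  The comparison reports residuals, the fraction of
observations inside the bootstrap 95% band, and Spearman rank correlations
of by-product rate against growth rate and against uptake rate per
condition group — the diagnostic separating glucose availability from
growth rate as the driver of the glycolytic switch.

Predictions are interpolated piecewise-linearly; since the model itself is
piecewise linear and all regime breakpoints (phi * Vmax_i) are inserted
into the grid, interpolation is exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    CellModel,
    byproduct_rates,
    glucose_uptake_from_rates,
    solve_three_pathway,
    solve_two_pathway,
)

__all__ = [
    "ObservationRecord",
    "ComparisonReport",
    "predict_curve",
    "compare_to_observations",
    "phi_sensitivity",
    "plot_predictions",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ObservationRecord:
    """One observed (O2, by-product) pair in canonical units, with its
    reconstructed energy-directed glucose uptake."""

    organism: str
    study_id: str
    o2_rate: float
    byproduct_rate: float
    limitation: str = "none"
    substrate: str = "glucose"
    growth_rate: float = math.nan  # h^-1, nan when not reported

    def __post_init__(self) -> None:
        if self.o2_rate < 0 or self.byproduct_rate < 0:
            raise ValueError("rates must be >= 0")

    @property
    def glucose_uptake(self) -> float:
        return glucose_uptake_from_rates(self.o2_rate, self.byproduct_rate)


@dataclass(frozen=True)
class ComparisonReport:
    residuals: pd.DataFrame
    in_band_fraction: float | None
    correlations: Mapping[tuple[str, str], Mapping[str, float]]
    n_excluded: int

    def __post_init__(self) -> None:
        if self.in_band_fraction is not None and not 0 <= self.in_band_fraction <= 1:
            raise ValueError("in_band_fraction must be in [0, 1]")


def _solve(model: CellModel, v: float):
    if len(model.pathways) == 2:
        return solve_two_pathway(model, v)
    return solve_three_pathway(model, v)


def _with_breakpoints(model: CellModel, grid: np.ndarray) -> np.ndarray:
    caps = [model.capacity(name) for name in model.names]
    lo, hi = grid.min(), grid.max()
    extra = [c for c in caps if lo < c < hi]
    return np.unique(np.concatenate([grid, extra]))


def predict_curve(model: CellModel, v_glucose_grid: Sequence[float]) -> pd.DataFrame:
    """Solve the model per grid point and tabulate fluxes and observables.

    Regime breakpoints (phi * Vmax per pathway) inside the grid range are
    added so piecewise-linear interpolation between rows is exact.  Columns:
    v_glucose, flux_<pathway> for each pathway, atp_rate, regime, o2 and one
    column per by-product name.
    """
    grid = np.asarray(list(v_glucose_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty v_glucose grid")
    if np.any(grid < 0):
        raise ValueError("v_glucose grid must be non-negative")
    grid = _with_breakpoints(model, grid)
    rows = []
    for v in grid:
        sol = _solve(model, float(v))
        obs = byproduct_rates(sol, model)
        row = {"v_glucose": float(v), "atp_rate": sol.atp_rate, "regime": sol.regime}
        for name in model.names:
            row[f"flux_{name}"] = sol.flux_per_pathway[name]
        row.update(obs)
        rows.append(row)
    return pd.DataFrame(rows)


def _byproduct_columns(pred: pd.DataFrame) -> list[str]:
    reserved = {"v_glucose", "atp_rate", "regime", "o2"}
    return [c for c in pred.columns if c not in reserved and not c.startswith("flux_")]


def compare_to_observations(
    predicted: pd.DataFrame,
    records: Sequence[ObservationRecord],
    bands: pd.DataFrame | None = None,
) -> ComparisonReport:
    """Interpolate predictions at each record's glucose uptake and score.

    ``predicted`` is a :func:`predict_curve` table.  ``bands``, if given, is
    a :func:`atpmax.bootstrap.bootstrap_predictions` table; the in-band
    fraction counts (record, observable) pairs falling inside [lo, hi].
    Records whose uptake falls outside the prediction grid are excluded
    (with a logged count) rather than extrapolated.
    """
    grid = predicted["v_glucose"].to_numpy()
    byp_cols = _byproduct_columns(predicted)
    pred_byp = predicted[byp_cols].sum(axis=1).to_numpy() if byp_cols else np.zeros(grid.size)
    pred_o2 = predicted["o2"].to_numpy()

    lo, hi = grid.min(), grid.max()
    kept = [r for r in records if lo <= r.glucose_uptake <= hi]
    n_excluded = len(records) - len(kept)
    if n_excluded:
        log.warning("%d observation(s) outside prediction grid excluded", n_excluded)

    rows = []
    for r in kept:
        v = r.glucose_uptake
        p_byp = float(np.interp(v, grid, pred_byp))
        p_o2 = float(np.interp(v, grid, pred_o2))
        rows.append(
            {
                "organism": r.organism,
                "study_id": r.study_id,
                "limitation": r.limitation,
                "glucose_uptake": v,
                "growth_rate": r.growth_rate,
                "observed_byproduct": r.byproduct_rate,
                "predicted_byproduct": p_byp,
                "residual_byproduct": r.byproduct_rate - p_byp,
                "observed_o2": r.o2_rate,
                "predicted_o2": p_o2,
                "residual_o2": r.o2_rate - p_o2,
            }
        )
    residuals = pd.DataFrame(rows)

    in_band_fraction = None
    if bands is not None and not residuals.empty:
        n_checked = 0
        n_inside = 0
        band_by_obs = {name: df for name, df in bands.groupby("observable")}
        byp_bands = [df for name, df in band_by_obs.items() if name != "o2"]
        checks: list[tuple[pd.DataFrame, str]] = [(band_by_obs["o2"], "observed_o2")] if "o2" in band_by_obs else []
        if byp_bands:
            checks.append((byp_bands[0] if len(byp_bands) == 1 else
                           pd.concat(byp_bands).groupby("v_glucose", as_index=False).sum(),
                           "observed_byproduct"))
        for band, col in checks:
            bgrid = band["v_glucose"].to_numpy()
            blo = band["lo"].to_numpy()
            bhi = band["hi"].to_numpy()
            for _, row in residuals.iterrows():
                v = row["glucose_uptake"]
                if v < bgrid.min() or v > bgrid.max():
                    continue
                lo_v = np.interp(v, bgrid, blo)
                hi_v = np.interp(v, bgrid, bhi)
                n_checked += 1
                if lo_v - 1e-12 <= row[col] <= hi_v + 1e-12:
                    n_inside += 1
        in_band_fraction = n_inside / n_checked if n_checked else None

    correlations: dict[tuple[str, str], dict[str, float]] = {}
    if not residuals.empty:
        for (org, limitation), group in residuals.groupby(["organism", "limitation"]):
            entry: dict[str, float] = {}
            if group.shape[0] >= 3:
                with_growth = group.dropna(subset=["growth_rate"])
                if with_growth.shape[0] >= 3:
                    rho, _ = sps.spearmanr(
                        with_growth["growth_rate"], with_growth["observed_byproduct"]
                    )
                    entry["growth_vs_byproduct"] = float(rho)
                rho, _ = sps.spearmanr(group["glucose_uptake"], group["observed_byproduct"])
                entry["uptake_vs_byproduct"] = float(rho)
            if entry:
                correlations[(org, limitation)] = entry

    return ComparisonReport(
        residuals=residuals,
        in_band_fraction=in_band_fraction,
        correlations=correlations,
        n_excluded=n_excluded,
    )


def phi_sensitivity(
    model: CellModel,
    phi_values: Sequence[float],
    v_glucose_grid: Sequence[float],
) -> dict[float, dict]:
    """Family of predicted curves under varying ATP proteome budgets.

    Enlarging phi_total_atp raises the ATP production capacity at every
    uptake rate and delays the respiration-to-glycolysis switch: the
    glycolytic onset sits at phi * Vmax of the high-yield pathway, exactly
    linear in phi.  Returns phi -> {"curve": DataFrame, "switch_onset": float}.
    """
    out = {}
    for phi in phi_values:
        if not 0 < phi <= 1:
            raise ValueError(f"phi values must be in (0, 1], got {phi}")
        m = model.replace_phi(phi)
        high_yield = max(m.pathways, key=lambda p: p.atp_yield)
        out[phi] = {
            "curve": predict_curve(m, v_glucose_grid),
            "switch_onset": phi * high_yield.specific_activity,
        }
    return out


def plot_predictions(
    predicted: pd.DataFrame,
    bands: pd.DataFrame | None = None,
    records: Sequence[ObservationRecord] = (),
    ax=None,
):
    """Observed points over predicted curves (and optional bootstrap bands)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    byp_cols = _byproduct_columns(predicted)
    byp = predicted[byp_cols].sum(axis=1) if byp_cols else 0 * predicted["v_glucose"]
    ax.plot(predicted["v_glucose"], byp, color="firebrick", label="glycolytic by-product")
    ax.plot(predicted["v_glucose"], predicted["o2"], color="steelblue", label="O2 consumption")
    if bands is not None:
        for obs, df in bands.groupby("observable"):
            color = "steelblue" if obs == "o2" else "firebrick"
            ax.fill_between(df["v_glucose"], df["lo"], df["hi"], color=color, alpha=0.2)
    if records:
        ax.scatter(
            [r.glucose_uptake for r in records],
            [r.byproduct_rate for r in records],
            color="firebrick", marker="o", s=18, zorder=3,
        )
        ax.scatter(
            [r.glucose_uptake for r in records],
            [r.o2_rate for r in records],
            color="steelblue", marker="s", s=18, zorder=3,
        )
    ax.set_xlabel("glucose uptake rate (umol min$^{-1}$ mg$^{-1}$)")
    ax.set_ylabel("rate (umol min$^{-1}$ mg$^{-1}$)")
    ax.legend()
    return ax
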