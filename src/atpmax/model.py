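"""Model/Results interface over the full estimation and prediction chain.

:class:`WarburgModel` is constructed from the raw data (proteomics samples,
physiology measurements, pathway definitions); :meth:`WarburgModel.fit`
runs parameter estimation and the bootstrap and returns a
:class:`WarburgResults` carrying the point estimates, their percentile 95%
confidence intervals, the assembled flux model, a ``summary()`` table, and
``predict`` / ``predict_bands`` / ``compare`` methods for the downstream
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bootstrap as bs
from .core import CellModel
from .estimation import (
    ParamEstimate,
    PathwayDefinition,
    PhysiologyMeasurement,
    ProteomicsSample,
    estimate_all,
    read_physiology,
    read_proteomics,
)
from .pipeline import ComparisonReport, ObservationRecord, compare_to_observations, predict_curve

__all__ = ["WarburgModel", "WarburgResults"]


class WarburgModel:
    """Proteome-allocation model of energy metabolism, built from data.

    Parameters
    ----------
    proteomics : sequence of ProteomicsSample
        Absolute-quantification MS samples.
    physiology : sequence of PhysiologyMeasurement
        Maximal-rate measurements under pathway-maximizing conditions.
    pathway_defs : mapping
        Pathway name -> PathwayDefinition ("glycolysis", "respiration",
        optionally "pta_acka").
    organism : str
        One of "ecoli", "yeast", "mammalian"; fixes the canonical ATP
        yields and the by-product identity.

    Examples
    --------
    >>> model = WarburgModel(samples, measurements, defs, organism="yeast")
    >>> res = model.fit(n_resamples=2000, seed=0)
    >>> print(res.summary())
    >>> curve = res.predict(np.linspace(0, 0.5, 50))
    """

    def __init__(
        self,
        proteomics: Sequence[ProteomicsSample],
        physiology: Sequence[PhysiologyMeasurement],
        pathway_defs: Mapping[str, PathwayDefinition],
        organism: str,
        gammas: Mapping[str, float] | None = None,
    ) -> None:
        self.proteomics = list(proteomics)
        self.physiology = list(physiology)
        self.pathway_defs = dict(pathway_defs)
        self.organism = organism
        self.gammas = gammas

    @classmethod
    def from_files(
        cls,
        signals_tsv,
        annotations_tsv,
        physiology_tsv,
        pathway_defs: Mapping[str, PathwayDefinition],
        organism: str,
    ) -> "WarburgModel":
        """Build from the on-disk TSV dialects (wide signal table +
        annotation table + long physiology table)."""
        return cls(
            read_proteomics(signals_tsv, annotations_tsv),
            read_physiology(physiology_tsv),
            pathway_defs,
            organism,
        )

    def fit(self, n_resamples: int = bs.DEFAULT_N_RESAMPLES, seed: int = 0) -> "WarburgResults":
        estimates, cell_model = estimate_all(
            self.proteomics, self.physiology, self.pathway_defs, self.organism,
            gammas=self.gammas,
        )
        resamples = bs.bootstrap_params(estimates, n_resamples=n_resamples, seed=seed)
        summaries = bs.summarize_params(resamples, estimates, n_resamples, seed)
        return WarburgResults(self, estimates, cell_model, resamples, summaries, seed)


@dataclass
class WarburgResults:
    """Fitted parameters, uncertainties and prediction interface."""

    model: WarburgModel
    estimates: dict[str, ParamEstimate]
    cell_model: CellModel
    resamples: dict[str, np.ndarray]
    conf_int: dict[str, bs.BootstrapSummary]
    seed: int

    @property
    def params(self) -> pd.Series:
        return pd.Series({k: v.value for k, v in self.estimates.items()})

    def predict(self, v_glucose_grid: Sequence[float]) -> pd.DataFrame:
        """Deterministic predicted curve at the point estimates."""
        return predict_curve(self.cell_model, v_glucose_grid)

    def predict_bands(self, v_glucose_grid: Sequence[float]) -> pd.DataFrame:
        """Bootstrap 95% prediction bands for the observables."""
        models = bs.models_from_resamples(self.cell_model, self.resamples)
        return bs.bootstrap_predictions(models, v_glucose_grid, seed=self.seed)

    def compare(
        self,
        records: Sequence[ObservationRecord],
        v_glucose_grid: Sequence[float] | None = None,
        bands: pd.DataFrame | None = None,
    ) -> ComparisonReport:
        """Score observations against the fitted predictions."""
        if v_glucose_grid is None:
            hi = max((r.glucose_uptake for r in records), default=1.0)
            v_glucose_grid = np.linspace(0.0, hi * 1.05, 200)
        return compare_to_observations(self.predict(v_glucose_grid), records, bands=bands)

    def summary(self) -> str:
        lines = [
            "Proteome-constrained ATP-rate maximization model",
            f"organism: {self.model.organism}   "
            f"proteomics samples: {len(self.model.proteomics)}   "
            f"physiology records: {len(self.model.physiology)}",
            f"bootstrap: {next(iter(self.conf_int.values())).n_resamples} resamples, "
            f"seed {self.seed}",
            "",
            f"{'parameter':<14}{'estimate':>12}{'ci 2.5%':>12}{'ci 97.5%':>12}"
            f"{'n src':>7}  unit",
        ]
        for name in sorted(self.estimates):
            est = self.estimates[name]
            ci = self.conf_int[name]
            lines.append(
                f"{name:<14}{est.value:>12.4g}{ci.ci_low:>12.4g}{ci.ci_high:>12.4g}"
                f"{est.n_sources:>7d}  {est.unit}"
            )
        caps = ", ".join(
            f"{n}: {self.cell_model.capacity(n):.4g}" for n in self.cell_model.names
        )
        lines += [
            "",
            f"phi * Vmax capacities (umol glucose min^-1 mg^-1): {caps}",
        ]
        return "\n".join(lines)
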