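"""Synthetic proteomics, physiology and observation data with known truth.

Every stage of the estimation and prediction chain is testable without
external downloads: the generators here emit tables in exactly the shapes
the estimators consume, built from a known parameter truth so that
round-trip recovery can be asserted.

What is emulated
----------------
* MS-signal proteomics tables: a protein universe of glycolytic enzymes,
  TCA enzymes, multisubunit ETC complexes (with realistic subunit
  stoichiometries) and a lumped background proteome, with per-sample
  signals whose expected pathway mass fractions equal the configured truth;
  multiplicative lognormal noise and missing-at-random ETC subunit signals
  mimic the poor extraction of membrane proteins.
* Physiology measurement sets: maximal by-product and oxygen consumption
  rates under the condition vocabulary the estimator filters on, reported
  in a configurable mix of original literature units with correct
  conversion metadata.
* Observation curves: (glucose uptake, by-product, O2) triples generated
  from a flux model plus noise, with an optional growth-rate column that is
  either tied to the ATP rate or shuffled against uptake to emulate
  nitrogen/phosphorus-limited growth decoupling.

All generators are deterministic under a fixed seed.  Noise is
multiplicative lognormal (positivity-preserving); the background proteome
is a lumped set of untagged proteins with no attempt to mimic real
abundance distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import CellModel, byproduct_rates, solve_three_pathway, solve_two_pathway
from .estimation import (
    MG_PROTEIN_PER_L_PER_OD600,
    PG_PROTEIN_PER_CELL,
    PROTEIN_PER_GCDW,
    EnzymeSlot,
    PathwayDefinition,
    PhysiologyMeasurement,
    ProteinEntry,
    ProteomicsSample,
)
from .pipeline import ObservationRecord

__all__ = [
    "SyntheticConfig",
    "default_pathway_definitions",
    "generate_proteomics",
    "generate_physiology",
    "generate_observations",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and nuisance settings for the generators.

    ``true_phi`` / ``true_vmax`` / ``true_gamma`` map pathway names
    ("glycolysis", "respiration", optionally "pta_acka") to the truth;
    ``noise_cv`` is the coefficient of variation of the multiplicative
    lognormal noise applied to signals and rates; ``missing_rate_etc`` is
    the per-(subunit, sample) probability that an ETC signal is missing;
    ``unit_mix`` is a distribution over original physiology units.
    """

    true_phi: Mapping[str, float]
    true_vmax: Mapping[str, float]
    true_gamma: Mapping[str, float]
    organism: str = "mammalian"
    n_proteomics_samples: int = 20
    n_measurements_per_kind: int = 20
    noise_cv: float = 0.10
    missing_rate_etc: float = 0.0
    unit_mix: Mapping[str, float] = field(
        default_factory=lambda: {"umol/mgProtein/min": 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_phi", dict(self.true_phi))
        object.__setattr__(self, "true_vmax", dict(self.true_vmax))
        object.__setattr__(self, "true_gamma", dict(self.true_gamma))
        object.__setattr__(self, "unit_mix", dict(self.unit_mix))
        if sum(self.true_phi.values()) > 1:
            raise ValueError("sum of true_phi must be <= 1")
        for d, label in ((self.true_phi, "true_phi"), (self.true_vmax, "true_vmax"),
                         (self.true_gamma, "true_gamma")):
            if any(v <= 0 for v in d.values()):
                raise ValueError(f"{label} values must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.missing_rate_etc <= 1:
            raise ValueError("missing_rate_etc must be in [0, 1]")
        if abs(sum(self.unit_mix.values()) - 1.0) > 1e-9:
            raise ValueError("unit_mix probabilities must sum to 1")

    def cell_model(self) -> CellModel:
        """The true flux model implied by the configuration."""
        from .core import PathwayParams
        from .estimation import _BYPRODUCT_BY_ORGANISM

        byp = _BYPRODUCT_BY_ORGANISM[self.organism]
        pathways = [
            PathwayParams(
                "fermentation",
                atp_yield=self.true_gamma["glycolysis"],
                specific_activity=self.true_vmax["glycolysis"],
                byproduct_per_glucose=2.0,
                byproduct_name=byp,
            ),
            PathwayParams(
                "respiration",
                atp_yield=self.true_gamma["respiration"],
                specific_activity=self.true_vmax["respiration"],
                o2_per_glucose=6.0,
            ),
        ]
        if "pta_acka" in self.true_vmax:
            pathways.insert(
                1,
                PathwayParams(
                    "pta_acka",
                    atp_yield=self.true_gamma["pta_acka"],
                    specific_activity=self.true_vmax["pta_acka"],
                    o2_per_glucose=2.0,
                    byproduct_per_glucose=2.0,
                    byproduct_name="acetate",
                ),
            )
        return CellModel(tuple(pathways), phi_total_atp=sum(self.true_phi.values()))


# --- protein universe ------------------------------------------------------

_GLYCOLYSIS_ENZYMES = [
    ("HK", 100.0), ("PGI", 63.0), ("PFK", 85.0), ("ALDO", 39.0), ("TPI", 27.0),
    ("GAPDH", 36.0), ("PGK", 45.0), ("PGM", 29.0), ("ENO", 47.0), ("PK", 58.0),
    ("LDH", 37.0),
]
_TCA_ENZYMES = [
    ("CS", 52.0), ("ACO", 86.0), ("IDH", 47.0), ("OGDH", 116.0), ("SCS", 72.0),
    ("FH", 55.0), ("MDH", 36.0), ("PDH", 150.0),
]
# ETC complexes: subunit molecular weights (kDa) and copies per complex
_ETC_COMPLEXES = {
    "CI": [("CI_s1", 75.0, 1), ("CI_s2", 49.0, 1), ("CI_s3", 30.0, 1), ("CI_s4", 18.0, 2)],
    "CIII": [("CIII_s1", 48.0, 2), ("CIII_s2", 44.0, 2), ("CIII_s3", 28.0, 2)],
    "CIV": [("CIV_s1", 57.0, 1), ("CIV_s2", 26.0, 1), ("CIV_s3", 30.0, 2)],
    "CV": [("CV_a", 55.0, 3), ("CV_b", 52.0, 3), ("CV_c", 8.0, 10)],
}
_N_BACKGROUND = 60


def default_pathway_definitions(include_pta: bool = False) -> dict[str, PathwayDefinition]:
    """Pathway membership matching the synthetic protein universe."""
    glyc = PathwayDefinition(
        "glycolysis",
        tuple(EnzymeSlot(name, (name,)) for name, _ in _GLYCOLYSIS_ENZYMES),
    )
    resp_slots = [EnzymeSlot(name, (name,)) for name, _ in _TCA_ENZYMES]
    for cx, subunits in _ETC_COMPLEXES.items():
        resp_slots.append(
            EnzymeSlot(
                cx,
                isoform_ids=(),
                subunits=tuple((pid, float(copies)) for pid, _, copies in subunits),
            )
        )
    resp = PathwayDefinition("respiration", tuple(resp_slots))
    defs = {"glycolysis": glyc, "respiration": resp}
    if include_pta:
        # the respiro-fermentative route shares the glycolytic enzymes plus
        # acetate kinase/phosphotransacetylase and the ETC
        pta_slots = list(glyc.members) + [
            EnzymeSlot("PTA", ("PTA",)),
            EnzymeSlot("ACKA", ("ACKA",)),
        ]
        defs["pta_acka"] = PathwayDefinition("pta_acka", tuple(pta_slots))
    return defs


def _universe(include_pta: bool) -> list[tuple[str, float, frozenset, str | None, float, bool]]:
    """(protein_id, MW, tags, complex_id, stoichiometry, is_mito) rows."""
    rows = []
    for name, mw in _GLYCOLYSIS_ENZYMES:
        tags = {"glycolysis"} | ({"pta_acka"} if include_pta else set())
        rows.append((name, mw, frozenset(tags), None, 1.0, False))
    if include_pta:
        rows.append(("PTA", 77.0, frozenset({"pta_acka"}), None, 1.0, False))
        rows.append(("ACKA", 43.0, frozenset({"pta_acka"}), None, 1.0, False))
    for name, mw in _TCA_ENZYMES:
        rows.append((name, mw, frozenset({"respiration"}), None, 1.0, True))
    for cx, subunits in _ETC_COMPLEXES.items():
        for pid, mw, copies in subunits:
            rows.append((pid, mw, frozenset({"respiration"}), cx, float(copies), True))
    rng = np.random.default_rng(1234)  # fixed universe, independent of config seed
    for i in range(_N_BACKGROUND):
        mw = float(np.round(rng.uniform(15, 150), 1))
        rows.append((f"BG{i:03d}", mw, frozenset({"other"}), None, 1.0, False))
    return rows


def generate_proteomics(
    config: SyntheticConfig,
) -> tuple[list[ProteomicsSample], dict]:
    """Synthetic MS-signal samples whose expected pathway mass fractions
    equal ``config.true_phi``.

    Base signals are mass-proportional: within a pathway each protein's
    share follows its MW x stoichiometry; pathway totals are scaled to the
    true fractions and the background absorbs the remainder.  Lognormal
    noise (CV = noise_cv) is applied per protein per sample, and ETC
    subunit signals are set missing with probability ``missing_rate_etc``.
    Returns the samples and a truth record.
    """
    include_pta = "pta_acka" in config.true_phi
    rng = np.random.default_rng(config.seed)
    universe = _universe(include_pta)

    phi_other = 1.0 - sum(config.true_phi.values())
    target = dict(config.true_phi)
    target["other"] = phi_other

    # each protein belongs to exactly one mass group; enzymes shared between
    # glycolysis and the Pta-AckA route count under glycolysis, so the
    # "pta_acka" truth refers to the route's extra mass (Pta/AckA) only
    def _group(tags: frozenset) -> str:
        for g in ("glycolysis", "pta_acka", "respiration"):
            if g in tags:
                return g
        return "other"

    base_mass = {pid: mw * stoich for pid, mw, _, _, stoich, _ in universe}
    resolved_group = {pid: _group(tags) for pid, _, tags, _, _, _ in universe}
    group_totals: dict[str, float] = {}
    for pid in base_mass:
        g = resolved_group[pid]
        group_totals[g] = group_totals.get(g, 0.0) + base_mass[pid]
    scale = {
        g: (target.get(g, 0.0) / tot if tot > 0 else 0.0)
        for g, tot in group_totals.items()
    }

    cv = config.noise_cv
    sigma = math.sqrt(math.log(1 + cv**2)) if cv > 0 else 0.0
    mu = -0.5 * sigma**2  # unit-mean lognormal

    samples = []
    for i in range(config.n_proteomics_samples):
        entries = []
        for pid, mw, tags, cx, stoich, mito in universe:
            signal = base_mass[pid] * scale[resolved_group[pid]] * 1e6
            if sigma > 0:
                signal *= float(rng.lognormal(mu, sigma))
            missing = (
                cx is not None
                and config.missing_rate_etc > 0
                and rng.random() < config.missing_rate_etc
            )
            entries.append(
                ProteinEntry(
                    protein_id=pid,
                    ms_signal=None if missing else signal,
                    molecular_weight=mw,
                    pathway_tags=tags,
                    complex_id=cx,
                    subunit_stoichiometry=stoich,
                    is_mitochondrial=mito,
                )
            )
        samples.append(ProteomicsSample(f"sample{i:03d}", tuple(entries)))

    truth = {
        "true_phi": dict(config.true_phi),
        "phi_other": phi_other,
        "seed": config.seed,
    }
    return samples, truth


_INVERSE_FACTORS = {
    # canonical -> original unit multiplier, given metadata
    "umol/mgProtein/min": lambda meta: 1.0,
    "mmol/gCDW/h": lambda meta: meta["protein_per_gcdw"] * 60.0,
    "umol/1e6cells/h": lambda meta: meta["pg_protein_per_cell"] * 1e-3 * 60.0,
    "mM/OD600/h": lambda meta: meta["mg_protein_per_l_od"] * 60.0 / 1000.0,
}


def _default_metadata(organism: str, unit: str) -> dict[str, float]:
    if unit == "mmol/gCDW/h":
        return {"protein_per_gcdw": PROTEIN_PER_GCDW.get(organism, 0.5)}
    if unit == "umol/1e6cells/h":
        return {"pg_protein_per_cell": PG_PROTEIN_PER_CELL}
    if unit == "mM/OD600/h":
        return {"mg_protein_per_l_od": MG_PROTEIN_PER_L_PER_OD600}
    return {}


def generate_physiology(
    config: SyntheticConfig,
) -> tuple[list[PhysiologyMeasurement], dict]:
    """Synthetic maximal-rate measurements for both pathways.

    Glycolysis-maximizing records carry by-product rates with expectation
    2 * Vmax_glyc * phi_glyc; respiration-maximizing records carry OCRs
    with expectation 6 * Vmax_resp * phi_resp (for the mammalian condition
    vocabulary these come as FCCP / antimycin pairs, the difference being
    the maximal mitochondrial rate).  Values are reported in units drawn
    from ``unit_mix`` with correct conversion metadata attached.
    """
    rng = np.random.default_rng(config.seed + 1)
    cv = config.noise_cv
    sigma = math.sqrt(math.log(1 + cv**2)) if cv > 0 else 0.0
    mu = -0.5 * sigma**2

    organism = config.organism
    byp_kind = {"ecoli": "acetate", "yeast": "ethanol", "mammalian": "lactate"}[organism]
    glyc_pathway = "pta_acka" if "pta_acka" in config.true_vmax else "glycolysis"
    true_byp = 2.0 * config.true_vmax[glyc_pathway] * config.true_phi[glyc_pathway]
    true_ocr = 6.0 * config.true_vmax["respiration"] * config.true_phi["respiration"]

    units = list(config.unit_mix)
    probs = np.array([config.unit_mix[u] for u in units])

    def _noise() -> float:
        return float(rng.lognormal(mu, sigma)) if sigma > 0 else 1.0

    def _emit(kind, canonical_value, study, **cond) -> PhysiologyMeasurement:
        unit = units[int(rng.choice(len(units), p=probs))]
        meta = _default_metadata(organism, unit)
        value = canonical_value * _INVERSE_FACTORS[unit](meta)
        return PhysiologyMeasurement(
            organism=organism,
            study_id=study,
            kind=kind,
            value=value,
            unit=unit,
            metadata=meta,
            **cond,
        )

    measurements: list[PhysiologyMeasurement] = []
    for i in range(config.n_measurements_per_kind):
        rate = true_byp * _noise()
        if organism == "mammalian":
            measurements.append(
                _emit(byp_kind, rate, f"glyc{i:03d}", treatment="oligomycin",
                      culture="plate")
            )
        else:
            measurements.append(
                _emit(byp_kind, rate, f"glyc{i:03d}", substrate="glucose",
                      culture="batch")
            )
    for i in range(config.n_measurements_per_kind):
        rate = true_ocr * _noise()
        if organism == "mammalian":
            nonmito = 0.1 * true_ocr * _noise()
            measurements.append(
                _emit("OCR", rate + nonmito, f"resp{i:03d}", treatment="FCCP",
                      culture="plate")
            )
            measurements.append(
                _emit("OCR", nonmito, f"resp{i:03d}", treatment="antimycin",
                      culture="plate")
            )
        else:
            measurements.append(
                _emit("OCR", rate, f"resp{i:03d}", substrate="acetate",
                      culture="batch")
            )
    truth = {
        "true_max_byproduct": true_byp,
        "true_max_ocr": true_ocr,
        "true_vmax": dict(config.true_vmax),
        "seed": config.seed,
    }
    return measurements, truth


def generate_observations(
    model: CellModel,
    n: int,
    uptake_range: tuple[float, float],
    noise_cv: float = 0.0,
    decouple_growth: bool = False,
    seed: int = 0,
) -> list[ObservationRecord]:
    """Observation scatter generated from the model plus noise.

    Uptake values are sampled uniformly over ``uptake_range``, solved
    through the model, converted to observables and multiplied by lognormal
    noise.  A synthetic growth rate proportional to the ATP production rate
    is attached; with ``decouple_growth`` the growth rates are shuffled
    against uptake, emulating nitrogen/phosphorus-limited cultures where
    carbon uptake and growth diverge.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    lo, hi = uptake_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid uptake_range")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1 + noise_cv**2)) if noise_cv > 0 else 0.0
    mu = -0.5 * sigma**2

    def _solve(v):
        if len(model.pathways) == 2:
            return solve_two_pathway(model, v)
        return solve_three_pathway(model, v)

    uptakes = rng.uniform(lo, hi, size=n)
    atp_rates = []
    raw = []
    for v in uptakes:
        sol = _solve(float(v))
        obs = byproduct_rates(sol, model)
        byp = sum(rate for name, rate in obs.items() if name != "o2")
        raw.append((obs["o2"], byp))
        atp_rates.append(sol.atp_rate)
    growth = 0.05 * np.asarray(atp_rates) / max(max(atp_rates), 1e-12) if n else np.array([])
    if decouple_growth and n > 1:
        growth = rng.permutation(growth)

    records = []
    for i, ((o2, byp), g) in enumerate(zip(raw, growth)):
        noise_o2 = float(rng.lognormal(mu, sigma)) if sigma > 0 else 1.0
        noise_byp = float(rng.lognormal(mu, sigma)) if sigma > 0 else 1.0
        records.append(
            ObservationRecord(
                organism="synthetic",
                study_id=f"obs{i:03d}",
                o2_rate=o2 * noise_o2,
                byproduct_rate=byp * noise_byp,
                growth_rate=float(g),
            )
        )
    return records
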