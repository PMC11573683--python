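"""Estimation of the five model parameters from proteomics and physiology.

The model needs, per organism: the ATP yields gamma (taken from the
canonical stoichiometric constants in :mod:`atpmax.yields`), the pathway
specific activities Vmax, and the proteome budget phi_total_atp.  These are
estimated from two independent data classes:

* absolute proteomics (MS signal tables) give the proteome mass fraction of
  each pathway via the total-protein approach — a protein's share of total
  cellular protein mass is proportional to its share of total MS signal;
* physiology measurements taken under pathway-maximizing conditions
  (saturating fermentable substrate / ATP-synthase inhibition / anaerobiosis
  for glycolysis; non-fermentable substrate or uncoupler for respiration)
  give the maximal cellular rate of each pathway, which divided by the
  pathway's proteome fraction yields its specific activity.

Membrane-embedded ETC subunits extract poorly, so subunits missing in more
than 20% of samples are imputed from the mass- and stoichiometry-weighted
mean signal of the non-missing subunits of the same complex.

Heterogeneous source units are converted to the canonical
umol min^-1 (mg cellular protein)^-1 here and only here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import CellModel, PathwayParams
from .yields import CANONICAL_GAMMA

__all__ = [
    "ProteinEntry",
    "ProteomicsSample",
    "EnzymeSlot",
    "PathwayDefinition",
    "PhysiologyMeasurement",
    "ParamEstimate",
    "proteome_fraction",
    "impute_etc_subunits",
    "convert_to_canonical",
    "specific_activity",
    "pathway_molecular_weight",
    "select_correlated_mito",
    "estimate_all",
    "read_proteomics",
    "read_physiology",
    "FERMENTABLE_SUBSTRATES",
    "NONFERMENTABLE_SUBSTRATES",
    "PROTEIN_PER_GCDW",
    "MG_PROTEIN_PER_L_PER_OD600",
    "PG_PROTEIN_PER_CELL",
]

log = logging.getLogger(__name__)

# organism-level protein content of dry cell mass (g protein / g CDW)
PROTEIN_PER_GCDW = {"ecoli": 0.55, "yeast": 0.44}
# optical-density-to-protein conversion for E. coli cultures
MG_PROTEIN_PER_L_PER_OD600 = 192.5
# protein content assumed per mammalian cell
PG_PROTEIN_PER_CELL = 300.0

FERMENTABLE_SUBSTRATES = frozenset(
    {"glucose", "fructose", "sucrose", "maltose", "galactose", "mannose"}
)
NONFERMENTABLE_SUBSTRATES = frozenset(
    {"acetate", "pyruvate", "succinate", "glycerol", "fumarate", "ethanol", "lactate"}
)

BYPRODUCT_KINDS = frozenset({"acetate", "ethanol", "lactate"})


@dataclass(frozen=True)
class ProteinEntry:
    """One protein's row in an absolute-quantification proteomics sample."""

    protein_id: str
    ms_signal: float | None  # None = not detected (distinct from 0)
    molecular_weight: float  # kDa
    pathway_tags: frozenset[str] = frozenset()
    complex_id: str | None = None
    subunit_stoichiometry: float = 1.0
    is_mitochondrial: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathway_tags", frozenset(self.pathway_tags))
        if self.ms_signal is not None and self.ms_signal < 0:
            raise ValueError(f"ms_signal must be >= 0 or None, got {self.ms_signal}")
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")
        if self.subunit_stoichiometry < 1:
            raise ValueError("subunit_stoichiometry must be >= 1")


@dataclass(frozen=True)
class ProteomicsSample:
    sample_id: str
    entries: tuple[ProteinEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        ids = [e.protein_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate protein ids in sample {self.sample_id}")

    def entry(self, protein_id: str) -> ProteinEntry:
        for e in self.entries:
            if e.protein_id == protein_id:
                return e
        raise KeyError(protein_id)

    def total_signal(self) -> float:
        return sum(e.ms_signal for e in self.entries if e.ms_signal is not None)


@dataclass(frozen=True)
class EnzymeSlot:
    """One enzyme position in a pathway: either a set of interchangeable
    isoforms (averaged) or a multisubunit complex (stoichiometry-weighted
    subunit sum)."""

    name: str
    isoform_ids: tuple[str, ...]
    stoichiometry: float = 1.0
    subunits: tuple[tuple[str, float], ...] = ()  # (protein_id, copies per complex)

    def __post_init__(self) -> None:
        object.__setattr__(self, "isoform_ids", tuple(self.isoform_ids))
        object.__setattr__(self, "subunits", tuple(tuple(s) for s in self.subunits))
        if self.stoichiometry < 1:
            raise ValueError("slot stoichiometry must be >= 1")
        if not self.isoform_ids and not self.subunits:
            raise ValueError(f"slot {self.name} has neither isoforms nor subunits")

    def protein_ids(self) -> tuple[str, ...]:
        return self.isoform_ids + tuple(pid for pid, _ in self.subunits)


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    members: tuple[EnzymeSlot, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ValueError("pathway definition must have members")

    def protein_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for slot in self.members:
            out.extend(slot.protein_ids())
        return tuple(dict.fromkeys(out))

    def extended(self, extra_ids: Iterable[str]) -> "PathwayDefinition":
        """Return a copy with additional single-protein slots appended."""
        existing = set(self.protein_ids())
        new_slots = tuple(
            EnzymeSlot(name=pid, isoform_ids=(pid,))
            for pid in extra_ids
            if pid not in existing
        )
        return PathwayDefinition(self.name, self.members + new_slots)


@dataclass(frozen=True)
class PhysiologyMeasurement:
    """One literature or assay measurement of a maximal pathway rate."""

    organism: str
    study_id: str
    kind: str  # OCR | acetate | ethanol | lactate
    value: float
    unit: str  # umol/mgProtein/min | mmol/gCDW/h | umol/1e6cells/h | mM/OD600/h
    substrate: str = "glucose"
    limitation: str = "none"  # C | N | P | none
    culture: str = "batch"  # batch | chemostat | plate
    treatment: str = "none"  # none | oligomycin | FCCP | antimycin | anaerobic
    metadata: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "metadata", dict(self.metadata))
        if self.value < 0:
            raise ValueError(f"measurement value must be >= 0, got {self.value}")
        if self.unit not in _CONVERTERS:
            raise ValueError(f"unrecognized unit {self.unit!r}")


@dataclass(frozen=True)
class ParamEstimate:
    """A parameter point estimate with its per-source values retained for
    resampling.

    ``kind`` records how the point is derived from sources: ``"mean"`` (the
    unweighted mean of ``sources``) or ``"ratio"`` (mean of the ``rate``
    component over mean of the ``phi`` component, as for specific
    activities).  For ratio estimates ``sources`` holds rate_i / mean(phi),
    so the mean-of-sources invariant still holds.
    """

    name: str
    value: float
    unit: str
    sources: tuple[float, ...]
    kind: str = "mean"
    components: Mapping[str, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(float(s) for s in self.sources))
        if self.components is not None:
            object.__setattr__(
                self,
                "components",
                {k: tuple(float(x) for x in v) for k, v in self.components.items()},
            )
        if len(self.sources) < 1:
            raise ValueError("estimate needs >= 1 source value")
        if not np.isclose(self.value, float(np.mean(self.sources)), rtol=1e-9, atol=1e-12):
            raise ValueError(
                f"{self.name}: point {self.value} is not the mean of sources"
            )

    @property
    def n_sources(self) -> int:
        return len(self.sources)


# --- proteome fractions ----------------------------------------------------


def proteome_fraction(sample: ProteomicsSample, pathway: PathwayDefinition) -> float:
    """Pathway proteome mass fraction by the total-protein approach:
    sum of pathway-member MS signals over the total MS signal of the
    sample.  Missing signals count as absent (0)."""
    if not sample.entries:
        raise ValueError("empty proteomics sample")
    total = sample.total_signal()
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id} has no positive MS signal")
    members = set(pathway.protein_ids())
    pathway_signal = sum(
        e.ms_signal
        for e in sample.entries
        if e.protein_id in members and e.ms_signal is not None
    )
    return pathway_signal / total


def impute_etc_subunits(
    samples: Sequence[ProteomicsSample],
    complex_defs: Mapping[str, Mapping[str, float]] | None = None,
) -> list[ProteomicsSample]:
    """Impute poorly extracted ETC subunits from their complex partners.

    A subunit missing in more than 20% of samples (strict) is imputed, per
    sample, as the mean signal per unit of (molecular weight x subunit
    stoichiometry) of the non-missing subunits of the same complex, scaled
    by the target subunit's own MW x stoichiometry.  Subunits at or below
    the 20% threshold are left untouched; a complex with no measured subunit
    in a sample is skipped with a log warning.

    ``complex_defs`` (complex -> protein_id -> stoichiometry) defaults to
    the complex annotations carried on the entries themselves.
    """
    if not samples:
        return []

    # assemble complex membership from entry annotations if not supplied
    if complex_defs is None:
        cd: dict[str, dict[str, float]] = {}
        for s in samples:
            for e in s.entries:
                if e.complex_id is not None:
                    cd.setdefault(e.complex_id, {})[e.protein_id] = e.subunit_stoichiometry
        complex_defs = cd

    in_complex = {pid for members in complex_defs.values() for pid in members}
    missing_count: dict[str, int] = {pid: 0 for pid in in_complex}
    present_count: dict[str, int] = {pid: 0 for pid in in_complex}
    for s in samples:
        for e in s.entries:
            if e.protein_id in in_complex:
                if e.ms_signal is None:
                    missing_count[e.protein_id] += 1
                else:
                    present_count[e.protein_id] += 1
    n = len(samples)
    needs_imputation = {
        pid
        for pid in in_complex
        if (missing_count[pid] + (n - missing_count[pid] - present_count[pid])) / n > 0.20
    }
    # a subunit absent from a sample's table entirely counts as missing there

    out: list[ProteomicsSample] = []
    for s in samples:
        entries = {e.protein_id: e for e in s.entries}
        new_entries = dict(entries)
        for cx, members in complex_defs.items():
            observed = [
                (entries[pid], members[pid])
                for pid in members
                if pid in entries and entries[pid].ms_signal is not None
            ]
            targets = [
                pid
                for pid in members
                if pid in needs_imputation
                and pid in entries
                and entries[pid].ms_signal is None
            ]
            if not targets:
                continue
            if not observed:
                log.warning(
                    "complex %s has no measured subunit in sample %s; imputation skipped",
                    cx, s.sample_id,
                )
                continue
            per_mass = np.mean(
                [e.ms_signal / (e.molecular_weight * st) for e, st in observed]
            )
            for pid in targets:
                tgt = entries[pid]
                imputed = per_mass * tgt.molecular_weight * members[pid]
                new_entries[pid] = replace(tgt, ms_signal=float(imputed))
        out.append(ProteomicsSample(s.sample_id, tuple(new_entries[e.protein_id] for e in s.entries)))
    return out


# --- unit conversion -------------------------------------------------------


def _from_canonical(value: float, meta: Mapping[str, float]) -> float:
    return value


def _from_gcdw(value: float, meta: Mapping[str, float]) -> float:
    frac = meta["protein_per_gcdw"]
    if frac <= 0:
        raise ValueError("protein_per_gcdw must be > 0")
    # mmol g^-1 h^-1 == umol mg^-1 h^-1, so only the protein fraction and
    # the per-minute conversion apply
    return value / frac / 60.0


def _from_cells(value: float, meta: Mapping[str, float]) -> float:
    pg = meta["pg_protein_per_cell"]
    if pg <= 0:
        raise ValueError("pg_protein_per_cell must be > 0")
    mg_per_million = pg * 1e6 * 1e-9  # pg/cell * 1e6 cells -> mg
    return value / mg_per_million / 60.0


def _from_od(value: float, meta: Mapping[str, float]) -> float:
    mg_per_l = meta["mg_protein_per_l_od"]
    if mg_per_l <= 0:
        raise ValueError("mg_protein_per_l_od must be > 0")
    # mM h^-1 per OD600 -> umol (mg protein)^-1 min^-1
    return value * 1000.0 / mg_per_l / 60.0


_CONVERTERS = {
    "umol/mgProtein/min": (_from_canonical, ()),
    "mmol/gCDW/h": (_from_gcdw, ("protein_per_gcdw",)),
    "umol/1e6cells/h": (_from_cells, ("pg_protein_per_cell",)),
    "mM/OD600/h": (_from_od, ("mg_protein_per_l_od",)),
}


def convert_to_canonical(measurement: PhysiologyMeasurement) -> float:
    """Convert a measurement to umol min^-1 (mg cellular protein)^-1.

    Conversion factors come from the measurement's own metadata
    (``protein_per_gcdw``, ``pg_protein_per_cell`` or
    ``mg_protein_per_l_od``); organism-level defaults are filled in by
    :func:`read_physiology` / the synthetic generator, not assumed here.
    """
    converter, required = _CONVERTERS[measurement.unit]
    missing = [k for k in required if k not in measurement.metadata]
    if missing:
        raise ValueError(
            f"unit {measurement.unit!r} needs conversion metadata {missing}"
        )
    return converter(measurement.value, measurement.metadata)


def specific_activity(max_cellular_rate: float, phi_pathway: float) -> float:
    """Pathway specific activity Vmax = maximal cellular glucose-equivalent
    rate divided by the pathway's proteome fraction."""
    if phi_pathway <= 0:
        raise ValueError(f"phi_pathway must be > 0, got {phi_pathway}")
    if max_cellular_rate < 0:
        raise ValueError("rate must be >= 0")
    return max_cellular_rate / phi_pathway


def pathway_molecular_weight(
    pathway: PathwayDefinition, mw_table: Mapping[str, float]
) -> float:
    """Molecular weight of one pathway unit (kDa): over enzyme slots, the
    slot stoichiometry times the mean isoform MW, or for complexes the
    subunit-stoichiometry-weighted subunit sum."""
    unresolved = [pid for pid in pathway.protein_ids() if pid not in mw_table]
    if unresolved:
        raise KeyError(f"protein ids missing from MW table: {unresolved}")
    total = 0.0
    for slot in pathway.members:
        if slot.subunits:
            slot_mw = sum(mw_table[pid] * copies for pid, copies in slot.subunits)
        else:
            slot_mw = float(np.mean([mw_table[pid] for pid in slot.isoform_ids]))
        total += slot.stoichiometry * slot_mw
    return total


def select_correlated_mito(
    samples: Sequence[ProteomicsSample],
    core_respiration: PathwayDefinition,
    alpha: float = 0.05,
) -> PathwayDefinition:
    """Extend the core respiration definition with mitochondrial proteins
    whose abundance tracks it.

    For each mitochondrial protein outside the core set, the Spearman rank
    correlation of its per-sample signal against the per-sample sum of core
    respiration signals is computed; proteins with rho > 0 and
    Benjamini-Hochberg-adjusted two-tailed p < ``alpha`` are appended.
    """
    if len(samples) < 4:
        raise ValueError("select_correlated_mito needs >= 4 samples")
    core_ids = set(core_respiration.protein_ids())
    core_sums = np.array(
        [
            sum(
                e.ms_signal
                for e in s.entries
                if e.protein_id in core_ids and e.ms_signal is not None
            )
            for s in samples
        ]
    )
    candidates = sorted(
        {
            e.protein_id
            for s in samples
            for e in s.entries
            if e.is_mitochondrial and e.protein_id not in core_ids
        }
    )
    if not candidates:
        return core_respiration
    rhos, pvals = [], []
    for pid in candidates:
        signals = np.array(
            [
                next(
                    (e.ms_signal for e in s.entries if e.protein_id == pid),
                    None,
                )
                or 0.0
                for s in samples
            ]
        )
        rho, p = sps.spearmanr(signals, core_sums)
        if np.isnan(rho):  # constant vector
            rho, p = 0.0, 1.0
        rhos.append(rho)
        pvals.append(p)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    selected = [
        pid for pid, rho, rj in zip(candidates, rhos, reject) if rho > 0 and rj
    ]
    return core_respiration.extended(selected)


# --- condition filtering and orchestration ---------------------------------


def _is_glycolysis_maximizing(m: PhysiologyMeasurement) -> bool:
    if m.kind not in BYPRODUCT_KINDS:
        return False
    if m.treatment in ("oligomycin", "anaerobic"):
        return True
    return (
        m.treatment == "none"
        and m.substrate in FERMENTABLE_SUBSTRATES
        and m.culture in ("batch", "plate")
    )


def _is_respiration_maximizing(m: PhysiologyMeasurement) -> bool:
    if m.kind != "OCR":
        return False
    if m.treatment == "FCCP":
        return True
    return m.treatment == "none" and m.substrate in NONFERMENTABLE_SUBSTRATES


def _max_respiration_rates(measurements: Sequence[PhysiologyMeasurement]) -> list[float]:
    """Canonical maximal-respiration OCRs.

    FCCP-treated records are corrected for non-mitochondrial oxygen
    consumption by subtracting the same study's antimycin/rotenone OCR
    (clipped at 0); substrate-driven records pass through unchanged.
    """
    rates: list[float] = []
    antimycin_by_study: dict[str, float] = {}
    for m in measurements:
        if m.kind == "OCR" and m.treatment == "antimycin":
            antimycin_by_study[m.study_id] = convert_to_canonical(m)
    for m in measurements:
        if not _is_respiration_maximizing(m):
            continue
        rate = convert_to_canonical(m)
        if m.treatment == "FCCP":
            rate -= antimycin_by_study.get(m.study_id, 0.0)
        rates.append(max(rate, 0.0))
    return rates


_BYPRODUCT_BY_ORGANISM = {"ecoli": "acetate", "yeast": "ethanol", "mammalian": "lactate"}


def estimate_all(
    samples: Sequence[ProteomicsSample],
    measurements: Sequence[PhysiologyMeasurement],
    pathway_defs: Mapping[str, PathwayDefinition],
    organism: str,
    gammas: Mapping[str, float] | None = None,
) -> tuple[dict[str, ParamEstimate], CellModel]:
    """Estimate all model parameters and assemble a ready CellModel.

    ``pathway_defs`` must contain ``"glycolysis"`` and ``"respiration"``
    (plus ``"pta_acka"`` for E. coli).  Pathway proteome fractions are
    computed per sample after ETC imputation and averaged; maximal cellular
    rates come from the condition-filtered measurement subsets, converted to
    canonical units and to glucose equivalents (by-products / 2, OCR / 6);
    specific activities divide the mean rate by the mean fraction.  Yields
    are the canonical stoichiometric constants.  phi_total_atp is the
    per-sample sum of the pathway fractions, averaged.
    """
    if organism not in CANONICAL_GAMMA:
        raise ValueError(f"unknown organism {organism!r}")
    if gammas is None:
        gammas = CANONICAL_GAMMA[organism]
    if "glycolysis" not in pathway_defs or "respiration" not in pathway_defs:
        raise ValueError("pathway_defs must define glycolysis and respiration")
    if not samples:
        raise ValueError("no proteomics samples provided")

    samples = impute_etc_subunits(samples)

    with_pta = "pta_acka" in pathway_defs
    phi_sources: dict[str, list[float]] = {name: [] for name in pathway_defs}
    for s in samples:
        for name, pdef in pathway_defs.items():
            phi_sources[name].append(proteome_fraction(s, pdef))

    estimates: dict[str, ParamEstimate] = {}
    short = {"glycolysis": "glyc", "respiration": "resp", "pta_acka": "pta"}
    for name, values in phi_sources.items():
        estimates[f"phi_{short[name]}"] = ParamEstimate(
            name=f"phi_{short[name]}",
            value=float(np.mean(values)),
            unit="mg pathway protein / mg cellular protein",
            sources=tuple(values),
        )

    # phi_total_atp counts each protein once even where pathway definitions
    # overlap (in E. coli the Pta-AckA route shares the glycolytic enzymes)
    union_ids = sorted(
        {pid for pdef in pathway_defs.values() for pid in pdef.protein_ids()}
    )
    union_def = PathwayDefinition(
        "all_atp",
        tuple(EnzymeSlot(pid, (pid,)) for pid in union_ids),
    )
    phi_total_sources = [proteome_fraction(s, union_def) for s in samples]
    estimates["phi_total_atp"] = ParamEstimate(
        name="phi_total_atp",
        value=float(np.mean(phi_total_sources)),
        unit="mg ATP-pathway protein / mg cellular protein",
        sources=tuple(phi_total_sources),
    )

    glyc_rates = [
        convert_to_canonical(m) / 2.0
        for m in measurements
        if _is_glycolysis_maximizing(m)
    ]
    if not glyc_rates:
        raise ValueError(
            "no glycolysis-maximizing measurements (fermentable-substrate batch, "
            "oligomycin or anaerobic records required)"
        )
    resp_rates = [r / 6.0 for r in _max_respiration_rates(measurements)]
    if not resp_rates:
        raise ValueError(
            "no respiration-maximizing measurements (non-fermentable substrate "
            "or FCCP records required)"
        )

    def _vmax_estimate(pname: str, rates: list[float]) -> ParamEstimate:
        phi_est = estimates[f"phi_{short[pname]}"]
        point = float(np.mean(rates)) / phi_est.value
        return ParamEstimate(
            name=f"vmax_{short[pname]}",
            value=point,
            unit="umol glucose min^-1 (mg pathway protein)^-1",
            sources=tuple(r / phi_est.value for r in rates),
            kind="ratio",
            components={"rate": tuple(rates), "phi": phi_est.sources},
        )

    # in E. coli the acetate-secreting flux runs through Pta-AckA, whose
    # proteome share includes the ETC; fermentative glycolysis shares the
    # glycolytic enzyme set
    estimates["vmax_glyc"] = _vmax_estimate("glycolysis", glyc_rates)
    estimates["vmax_resp"] = _vmax_estimate("respiration", resp_rates)
    if with_pta:
        estimates["vmax_pta"] = _vmax_estimate("pta_acka", glyc_rates)

    for key, gname in (("gamma_glyc", "fermentation"), ("gamma_resp", "respiration")):
        estimates[key] = ParamEstimate(
            name=key,
            value=float(gammas[gname]),
            unit="mol ATP / mol glucose",
            sources=(float(gammas[gname]),),
        )
    if with_pta:
        estimates["gamma_pta"] = ParamEstimate(
            name="gamma_pta",
            value=float(gammas["pta_acka"]),
            unit="mol ATP / mol glucose",
            sources=(float(gammas["pta_acka"]),),
        )

    byproduct = _BYPRODUCT_BY_ORGANISM[organism]
    pathways = [
        PathwayParams(
            name="fermentation",
            atp_yield=estimates["gamma_glyc"].value,
            specific_activity=estimates["vmax_glyc"].value,
            o2_per_glucose=0.0,
            byproduct_per_glucose=2.0,
            byproduct_name=byproduct,
        ),
        PathwayParams(
            name="respiration",
            atp_yield=estimates["gamma_resp"].value,
            specific_activity=estimates["vmax_resp"].value,
            o2_per_glucose=6.0,
        ),
    ]
    if with_pta:
        pathways.insert(
            1,
            PathwayParams(
                name="pta_acka",
                atp_yield=estimates["gamma_pta"].value,
                specific_activity=estimates["vmax_pta"].value,
                o2_per_glucose=2.0,
                byproduct_per_glucose=2.0,
                byproduct_name="acetate",
            ),
        )
    model = CellModel(tuple(pathways), phi_total_atp=estimates["phi_total_atp"].value)
    return estimates, model


# --- file I/O --------------------------------------------------------------


def read_proteomics(signals_tsv, annotations_tsv) -> list[ProteomicsSample]:
    """Read a wide signal table (rows = proteins, columns = samples; empty
    cells = missing) plus an annotation table (protein_id, molecular_weight,
    pathway_tags ;-separated, complex_id, subunit_stoichiometry, is_mitochondrial)."""
    signals = pd.read_csv(signals_tsv, sep="\t", index_col="protein_id")
    annot = pd.read_csv(annotations_tsv, sep="\t", index_col="protein_id")
    samples = []
    for col in signals.columns:
        entries = []
        for pid, sig in signals[col].items():
            row = annot.loc[pid]
            tags = (
                frozenset(str(row["pathway_tags"]).split(";"))
                if pd.notna(row.get("pathway_tags"))
                else frozenset()
            )
            cx = row.get("complex_id")
            entries.append(
                ProteinEntry(
                    protein_id=str(pid),
                    ms_signal=None if pd.isna(sig) else float(sig),
                    molecular_weight=float(row["molecular_weight"]),
                    pathway_tags=tags,
                    complex_id=None if pd.isna(cx) else str(cx),
                    subunit_stoichiometry=float(row.get("subunit_stoichiometry", 1.0)),
                    is_mitochondrial=bool(row.get("is_mitochondrial", False)),
                )
            )
        samples.append(ProteomicsSample(sample_id=str(col), entries=tuple(entries)))
    return samples


_DEFAULT_METADATA = {
    "mmol/gCDW/h": lambda org: {"protein_per_gcdw": PROTEIN_PER_GCDW.get(org, 0.5)},
    "umol/1e6cells/h": lambda org: {"pg_protein_per_cell": PG_PROTEIN_PER_CELL},
    "mM/OD600/h": lambda org: {"mg_protein_per_l_od": MG_PROTEIN_PER_L_PER_OD600},
    "umol/mgProtein/min": lambda org: {},
}


def read_physiology(tsv) -> list[PhysiologyMeasurement]:
    """Read a long-format measurement table.  Conversion metadata columns
    (protein_per_gcdw, pg_protein_per_cell, mg_protein_per_l_od) are
    optional; organism defaults are filled in where absent."""
    df = pd.read_csv(tsv, sep="\t")
    out = []
    for _, row in df.iterrows():
        org = str(row["organism"])
        meta = dict(_DEFAULT_METADATA[str(row["unit"])](org))
        for key in ("protein_per_gcdw", "pg_protein_per_cell", "mg_protein_per_l_od"):
            if key in df.columns and pd.notna(row[key]):
                meta[key] = float(row[key])
        out.append(
            PhysiologyMeasurement(
                organism=org,
                study_id=str(row["study_id"]),
                kind=str(row["kind"]),
                value=float(row["value"]),
                unit=str(row["unit"]),
                substrate=str(row.get("substrate", "glucose")),
                limitation=str(row.get("limitation", "none")),
                culture=str(row.get("culture", "batch")),
                treatment=str(row.get("treatment", "none")),
                metadata=meta,
            )
        )
    return out
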