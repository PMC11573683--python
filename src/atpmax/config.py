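"""Organism configuration files: pathway parameters + ETC stoichiometry.

A config YAML has a ``pathways`` list ({name, gamma, vmax, o2_per_glucose,
byproduct_per_glucose, byproduct_name}), a scalar ``phi_total_atp``, and
optionally an ``etc_stoichiometry`` block mirroring
:class:`atpmax.yields.ETCStoichiometry`.  Three canonical organism configs
ship with the package (``ecoli`` three-pathway, ``yeast``, ``mammalian``);
their yields are the canonical stoichiometric constants and their specific
activities reproduce the published fold-differences between the ATP rates
of glycolysis and respiration (see docs/methods.md for the anchoring of
absolute scales).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .core import CellModel, PathwayParams
from .yields import ETCStoichiometry

__all__ = ["load_cell_model", "load_etc_stoichiometry", "available_organisms", "config_path"]

_BUILTIN = ("ecoli", "yeast", "mammalian")


def available_organisms() -> tuple[str, ...]:
    return _BUILTIN


def config_path(name_or_path: str | Path) -> Path:
    """Resolve a built-in organism name or a filesystem path to a YAML file."""
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") and p.exists():
        return p
    if str(name_or_path) in _BUILTIN:
        return Path(str(resources.files("atpmax").joinpath(f"configs/{name_or_path}.yaml")))
    raise FileNotFoundError(
        f"{name_or_path!r} is neither a built-in organism {_BUILTIN} nor a YAML file"
    )


def _load(name_or_path: str | Path) -> dict:
    with open(config_path(name_or_path)) as fh:
        return yaml.safe_load(fh)


def load_cell_model(name_or_path: str | Path) -> CellModel:
    doc = _load(name_or_path)
    pathways = tuple(
        PathwayParams(
            name=p["name"],
            atp_yield=float(p["gamma"]),
            specific_activity=float(p["vmax"]),
            o2_per_glucose=float(p.get("o2_per_glucose", 0.0)),
            byproduct_per_glucose=float(p.get("byproduct_per_glucose", 0.0)),
            byproduct_name=p.get("byproduct_name", "") or "",
        )
        for p in doc["pathways"]
    )
    return CellModel(pathways, phi_total_atp=float(doc["phi_total_atp"]))


def load_etc_stoichiometry(
    name_or_path: str | Path, pathway: str = "respiration"
) -> ETCStoichiometry:
    doc = _load(name_or_path)
    blocks = doc.get("etc_stoichiometry", {})
    if pathway not in blocks:
        raise KeyError(f"no etc_stoichiometry block for {pathway!r}")
    b = blocks[pathway]
    return ETCStoichiometry(
        h_per_electron={k: int(v) for k, v in b["h_per_electron"].items()},
        nadh_total=float(b["nadh_total"]),
        fadh2_total=float(b.get("fadh2_total", 0.0)),
        nadh_route=tuple(b["nadh_route"]),
        fadh2_route=tuple(b.get("fadh2_route", ())),
        nadh_shuttled=float(b.get("nadh_shuttled", 0.0)),
        shuttle_cost_h=float(b.get("shuttle_cost_h", 0.0)),
        leak_fraction=float(b.get("leak_fraction", 0.25)),
        h_per_atp_synthase=float(b["h_per_atp_synthase"]),
        h_per_atp_transport=float(b.get("h_per_atp_transport", 0.0)),
        substrate_level_atp=float(b.get("substrate_level_atp", 4.0)),
    )
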