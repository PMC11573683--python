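"""Proteome-constrained ATP-rate maximization.

The cell is modelled as allocating a fixed fraction ``phi_total_atp`` of its
proteome to 1-3 lumped ATP-producing pathways (glycolysis, respiration and,
in E. coli, the respiro-fermentative Pta-AckA route).  Each pathway *i* is
characterised by its ATP yield per glucose ``gamma_i`` and its specific
activity ``Vmax_i`` (umol glucose min^-1 per mg of pathway protein).  Given a
glucose uptake rate ``V_glucose`` the cell chooses pathway fluxes ``V_i``
(umol glucose min^-1 per mg of cellular protein) to maximize the total ATP
production rate

    V_ATP = sum_i gamma_i * V_i

subject to the proteome-occupancy budget

    sum_i V_i / Vmax_i <= phi_total_atp

and glucose availability ``sum_i V_i <= V_glucose``.

This linear program has a closed-form solution by KKT analysis, implemented
in :func:`solve_two_pathway` / :func:`solve_three_pathway`, and is also
solved numerically with HiGHS in :func:`solve_lp`; the two routes cross-check
each other.  When the high-yield pathway (respiration) is slower per mg of
protein than the low-yield one (glycolysis), the optimum switches from pure
respiration at low glucose to pure glycolysis at high glucose through a
mixed regime — the Warburg Effect.

All rates are in canonical units of umol min^-1 (mg cellular protein)^-1;
unit conversions live in :mod:`atpmax.estimation`, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "PathwayParams",
    "CellModel",
    "FluxSolution",
    "solve_two_pathway",
    "solve_lp",
    "solve_three_pathway",
    "solve_oxygen_constrained",
    "byproduct_rates",
    "glucose_uptake_from_rates",
    "FEASIBILITY_TOL",
    "LP_REL_TOL",
]

#: absolute tolerance for constraint satisfaction of returned solutions
FEASIBILITY_TOL = 1e-9
#: relative tolerance for analytic-vs-LP agreement
LP_REL_TOL = 1e-6

SUBSTRATE_LIMITED = "substrate_limited"
MIXED = "mixed"
PROTEOME_LIMITED = "proteome_limited"


@dataclass(frozen=True)
class PathwayParams:
    """One lumped ATP-producing pathway.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"glycolysis"``.
    atp_yield : float
        gamma, mol ATP per mol glucose (> 0).
    specific_activity : float
        Vmax, umol glucose min^-1 (mg pathway protein)^-1 (> 0).
    o2_per_glucose : float
        mol O2 consumed per mol glucose routed through this pathway (>= 0);
        6 for complete oxidation, 2 for Pta-AckA, 0 for fermentation.
    byproduct_per_glucose : float
        mol of secreted by-product per mol glucose (>= 0); 2 for
        lactate/ethanol/acetate-producing glycolysis, 0 for respiration.
    byproduct_name : str
        Label of the secreted by-product ("" if none).
    """

    name: str
    atp_yield: float
    specific_activity: float
    o2_per_glucose: float = 0.0
    byproduct_per_glucose: float = 0.0
    byproduct_name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("pathway name must be non-empty")
        if not self.atp_yield > 0:
            raise ValueError(f"atp_yield must be > 0, got {self.atp_yield}")
        if not self.specific_activity > 0:
            raise ValueError(
                f"specific_activity must be > 0, got {self.specific_activity}"
            )
        if self.o2_per_glucose < 0 or self.byproduct_per_glucose < 0:
            raise ValueError("stoichiometric coefficients must be >= 0")

    @property
    def atp_specific_activity(self) -> float:
        """Specific activity of ATP production, gamma * Vmax."""
        return self.atp_yield * self.specific_activity


@dataclass(frozen=True)
class CellModel:
    """A set of 1-3 pathways sharing the ATP proteome budget ``phi_total_atp``."""

    pathways: tuple[PathwayParams, ...]
    phi_total_atp: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathways", tuple(self.pathways))
        if not 1 <= len(self.pathways) <= 3:
            raise ValueError("CellModel supports 1-3 pathways")
        names = [p.name for p in self.pathways]
        if len(set(names)) != len(names):
            raise ValueError(f"pathway names must be unique, got {names}")
        if not 0 < self.phi_total_atp <= 1:
            raise ValueError(
                f"phi_total_atp must be in (0, 1], got {self.phi_total_atp}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.pathways)

    def __getitem__(self, name: str) -> PathwayParams:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(name)

    def capacity(self, name: str) -> float:
        """Maximal flux of one pathway if it filled the whole budget: phi * Vmax."""
        return self.phi_total_atp * self[name].specific_activity

    def replace_phi(self, phi_total_atp: float) -> "CellModel":
        return CellModel(self.pathways, phi_total_atp)


@dataclass(frozen=True)
class FluxSolution:
    """Optimizer output: glucose fluxes per pathway and the regime reached."""

    flux_per_pathway: Mapping[str, float]
    atp_rate: float
    proteome_used: float
    glucose_used: float
    regime: str

    def __getitem__(self, name: str) -> float:
        return self.flux_per_pathway[name]


def _make_solution(model: CellModel, fluxes: Mapping[str, float], regime: str) -> FluxSolution:
    atp = sum(model[n].atp_yield * v for n, v in fluxes.items())
    used = sum(v / model[n].specific_activity for n, v in fluxes.items())
    return FluxSolution(
        flux_per_pathway=dict(fluxes),
        atp_rate=atp,
        proteome_used=used,
        glucose_used=sum(fluxes.values()),
        regime=regime,
    )


def _check_v_glucose(v_glucose: float) -> None:
    if v_glucose < 0:
        raise ValueError(f"v_glucose must be >= 0, got {v_glucose}")


def solve_two_pathway(model: CellModel, v_glucose: float) -> FluxSolution:
    """Closed-form global maximum for a two-pathway model.

    If one pathway has both the larger ATP yield gamma and the larger
    specific activity of ATP production gamma*Vmax, it is used exclusively
    (up to its proteome cap).  When yield and rate split between the
    pathways — the Warburg parameter regime — the optimum passes through
    three regimes as ``v_glucose`` rises: pure high-yield flux while glucose
    is scarce, a mixed regime in which the faster pathway gradually displaces
    the high-yield one from the full proteome budget, and pure fast-pathway
    flux once even it cannot consume all available glucose.  Flux is
    continuous in ``v_glucose`` at both regime boundaries.
    """
    _check_v_glucose(v_glucose)
    if len(model.pathways) != 2:
        raise ValueError("solve_two_pathway requires exactly 2 pathways")
    a, b = model.pathways
    phi = model.phi_total_atp

    # high-yield pathway H and high-ATP-rate pathway E (gamma * Vmax)
    if a.atp_yield != b.atp_yield:
        high_yield = a if a.atp_yield > b.atp_yield else b
    else:
        high_yield = a if a.atp_specific_activity >= b.atp_specific_activity else b
    other = b if high_yield is a else a

    gv_h = high_yield.atp_specific_activity
    gv_e = other.atp_specific_activity

    if gv_h >= gv_e:
        # one pathway dominates (degenerate gamma*Vmax tie resolves to the
        # maximal-yield vertex): exclusive use up to its proteome cap
        dom = high_yield
        cap = phi * dom.specific_activity
        flux = min(v_glucose, cap)
        regime = SUBSTRATE_LIMITED if v_glucose < cap else PROTEOME_LIMITED
        return _make_solution(model, {dom.name: flux, other.name: 0.0}, regime)

    # Warburg regime: high_yield = slow, other = fast low-yield pathway
    slow, fast = high_yield, other
    cap_slow = phi * slow.specific_activity
    cap_fast = phi * fast.specific_activity

    if v_glucose <= cap_slow:
        fluxes = {slow.name: v_glucose, fast.name: 0.0}
        regime = SUBSTRATE_LIMITED
    elif v_glucose >= cap_fast:
        fluxes = {slow.name: 0.0, fast.name: cap_fast}
        regime = PROTEOME_LIMITED
    else:
        # both constraints active: proteome full, all glucose consumed
        v_fast = (
            (phi * fast.specific_activity * slow.specific_activity
             - v_glucose * fast.specific_activity)
            / (slow.specific_activity - fast.specific_activity)
        )
        fluxes = {fast.name: v_fast, slow.name: v_glucose - v_fast}
        regime = MIXED
    return _make_solution(model, fluxes, regime)


def solve_lp(
    model: CellModel,
    v_glucose: float,
    extra_constraints: Sequence[tuple[Mapping[str, float], float]] | None = None,
) -> FluxSolution:
    """Global maximum by linear programming (HiGHS).

    ``extra_constraints`` is a list of ``(coefficients, bound)`` pairs adding
    rows ``sum_i coeff[name_i] * V_i <= bound`` (bound >= 0) to the base
    proteome and glucose constraints; used e.g. for an oxygen-uptake cap.
    """
    _check_v_glucose(v_glucose)
    names = model.names
    n = len(names)
    gammas = np.array([p.atp_yield for p in model.pathways])
    vmaxes = np.array([p.specific_activity for p in model.pathways])

    rows = [1.0 / vmaxes, np.ones(n)]
    rhs = [model.phi_total_atp, v_glucose]
    for coeffs, bound in extra_constraints or []:
        if bound < 0:
            raise ValueError(f"constraint bound must be >= 0, got {bound}")
        rows.append(np.array([coeffs.get(nm, 0.0) for nm in names]))
        rhs.append(bound)
    a_ub = np.vstack(rows)
    b_ub = np.array(rhs)

    res = linprog(-gammas, A_ub=a_ub, b_ub=b_ub, bounds=[(0, None)] * n, method="highs")
    if not res.success:
        raise RuntimeError(f"LP solver failed (status {res.status}): {res.message}")
    fluxes = np.maximum(res.x, 0.0)
    objective = float(gammas @ fluxes)

    # degenerate optimum face (equal gamma*Vmax): re-solve lexicographically,
    # maximizing the flux of the maximal-yield pathway at fixed objective,
    # so the reported vertex is deterministic across solver versions
    gv = gammas * vmaxes
    if n >= 2:
        gv_sorted = np.sort(gv)[::-1]
        if np.isclose(gv_sorted[0], gv_sorted[1], rtol=1e-12, atol=0.0):
            i_yield = int(np.argmax(gammas))
            c2 = np.zeros(n)
            c2[i_yield] = -1.0
            a2 = np.vstack([a_ub, -gammas])
            b2 = np.append(b_ub, -(objective - 1e-12 * max(1.0, abs(objective))))
            res2 = linprog(c2, A_ub=a2, b_ub=b2, bounds=[(0, None)] * n, method="highs")
            if res2.success:
                fluxes = np.maximum(res2.x, 0.0)

    flux_map = dict(zip(names, (float(v) for v in fluxes)))
    proteome_used = float(np.sum(fluxes / vmaxes))
    glucose_used = float(np.sum(fluxes))
    tol = FEASIBILITY_TOL + 1e-7 * max(1.0, v_glucose)
    glucose_active = glucose_used >= v_glucose - tol
    proteome_active = proteome_used >= model.phi_total_atp - FEASIBILITY_TOL - 1e-7
    if glucose_active and proteome_active:
        regime = MIXED
    elif proteome_active:
        regime = PROTEOME_LIMITED
    else:
        regime = SUBSTRATE_LIMITED
    return FluxSolution(
        flux_per_pathway=flux_map,
        atp_rate=float(gammas @ fluxes),
        proteome_used=proteome_used,
        glucose_used=glucose_used,
        regime=regime,
    )


def _dominated(p: PathwayParams, q: PathwayParams) -> bool:
    """True if q is at least as good as p in both yield and ATP rate, and strictly
    better in one — p then carries zero flux in some global optimum."""
    ge_yield = q.atp_yield >= p.atp_yield
    ge_rate = q.atp_specific_activity >= p.atp_specific_activity
    strict = q.atp_yield > p.atp_yield or q.atp_specific_activity > p.atp_specific_activity
    return ge_yield and ge_rate and strict


def solve_three_pathway(model: CellModel, v_glucose: float) -> FluxSolution:
    """Global maximum for a three-pathway model (E. coli: fermentation,
    Pta-AckA, respiration).

    In the experimentally estimated E. coli regime — fermentation has both
    the lowest yield and a lower ATP rate than Pta-AckA — fermentation is
    dominated and carries zero flux at every glucose uptake rate; the
    optimum reduces to the two-pathway Pta-AckA/respiration trade-off.
    Outside that regime the LP route is used.
    """
    _check_v_glucose(v_glucose)
    if len(model.pathways) != 3:
        raise ValueError("solve_three_pathway requires exactly 3 pathways")

    # strip strictly dominated pathways; if exactly one remains dominated-free
    # pair, reuse the closed-form two-pathway solution
    remaining = list(model.pathways)
    dropped: list[PathwayParams] = []
    changed = True
    while changed and len(remaining) > 2:
        changed = False
        for p in list(remaining):
            if any(_dominated(p, q) for q in remaining if q is not p):
                remaining.remove(p)
                dropped.append(p)
                changed = True
                break

    if len(remaining) == 2:
        sub = CellModel(tuple(remaining), model.phi_total_atp)
        sol = solve_two_pathway(sub, v_glucose)
        fluxes = dict(sol.flux_per_pathway)
        for p in dropped:
            fluxes[p.name] = 0.0
        return _make_solution(model, fluxes, sol.regime)
    return solve_lp(model, v_glucose)


def solve_oxygen_constrained(
    model: CellModel, v_glucose: float, v_o2_max: float
) -> FluxSolution:
    """LP optimum with an additional oxygen-uptake cap
    ``sum_i o2_per_glucose_i * V_i <= v_o2_max``.

    As the cap grows the solution converges to the unconstrained optimum; at
    cap 0 all oxygen-consuming fluxes vanish (anaerobic glycolysis only).
    Sweeping the cap upward at fixed uptake makes glycolytic flux
    non-increasing — the Pasteur Effect.
    """
    if v_o2_max < 0:
        raise ValueError(f"v_o2_max must be >= 0, got {v_o2_max}")
    o2_row = {p.name: p.o2_per_glucose for p in model.pathways}
    return solve_lp(model, v_glucose, extra_constraints=[(o2_row, v_o2_max)])


def byproduct_rates(solution: FluxSolution, model: CellModel) -> dict[str, float]:
    """Observable rates implied by a flux solution.

    Returns a map with key ``"o2"`` (total O2 consumption) and one key per
    by-product name (production rate, summed over pathways secreting it),
    all in umol min^-1 (mg cellular protein)^-1.
    """
    if set(solution.flux_per_pathway) != set(model.names):
        raise ValueError(
            f"pathway names mismatch: solution {sorted(solution.flux_per_pathway)} "
            f"vs model {sorted(model.names)}"
        )
    out: dict[str, float] = {"o2": 0.0}
    for p in model.pathways:
        v = solution.flux_per_pathway[p.name]
        out["o2"] += p.o2_per_glucose * v
        if p.byproduct_name:
            out[p.byproduct_name] = out.get(p.byproduct_name, 0.0) + p.byproduct_per_glucose * v
    return out


def glucose_uptake_from_rates(o2_rate: float, byproduct_rate: float) -> float:
    """Glucose uptake directed to ATP production, reconstructed from
    observables: o2_rate / 6 + byproduct_rate / 2.

    Complete oxidation consumes 6 O2 per glucose and glycolytic routes
    secrete 2 by-product molecules per glucose, so this recovers the
    energy-directed glucose flux while excluding glucose diverted to
    biomass.
    """
    if o2_rate < 0 or byproduct_rate < 0:
        raise ValueError("rates must be >= 0")
    return o2_rate / 6.0 + byproduct_rate / 2.0
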