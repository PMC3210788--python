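"""Derived read-outs: steady-state flows, VEGF distribution, receptor
occupancy, net intercompartmental flows, and one-at-a-time parameter sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .geometry import myonuclear_variant_inputs
from .network import ReactionNetwork, SECONDS_PER_MINUTE
from .parameters import ParameterSet
from .simulation import (SimulationResult, free_vegf_picomolar, residual_norm,
                         solve_steady_state)


class AnalysisError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# steady-state flows
# ---------------------------------------------------------------------------

@dataclass
class FlowReport:
    """Whole-body VEGF flows (pmol/s) and their secretion-normalised shares.

    At steady state the elimination routes must balance secretion, so the
    normalised outflow shares sum to one.
    """

    flows: Dict[str, float]

    @property
    def normalized(self) -> Dict[str, float]:
        q = self.flows["secretion"]
        return {k: v / q for k, v in self.flows.items()}

    def to_frame(self) -> pd.DataFrame:
        norm = self.normalized
        return pd.DataFrame(
            {"flow_pmol_per_s": self.flows,
             "fraction_of_secretion": norm})


_OUTFLOW_KEYS = ("internalization_myocyte", "internalization_EC_tissue",
                 "internalization_EC_blood", "clearance_blood", "degradation")


def steady_state_flows(net: ReactionNetwork, y: np.ndarray,
                       require_steady: bool = True) -> FlowReport:
    """Evaluate every VEGF flow at a verified steady state.

    Tissue fluxes scale by tissue volume and blood fluxes by blood volume to
    give whole-body pmol/s.  ``permeability_net`` is positive for net
    tissue-to-blood (intravasation-dominated) flow of free VEGF.
    """
    if require_steady and residual_norm(net, y) > 1e-6:
        raise AnalysisError("flows are defined at a verified steady state "
                            f"(residual {residual_norm(net, y):.2e})")
    geo = net.geo
    tp = net.params.transport
    kint = net.params.kinetics.kint
    ix = net.index
    u_n, u_b = geo.tissue_volume, geo.blood_volume

    conv_myo = geo.conversions["myocyte_receptor"]
    secretion = (tp.q_v164 + tp.q_v120) * conv_myo * u_n

    myo = kint * y[ix["V164N1_myo"]] * u_n
    ec_tissue = kint * u_n * sum(
        y[ix[sp.name]] for sp in net.species
        if sp.location == "abluminal_EC" and sp.vegf)
    ec_blood = kint * u_b * sum(
        y[ix[sp.name]] for sp in net.species
        if sp.location == "luminal_EC" and sp.vegf)
    clearance = (tp.c_vegf / SECONDS_PER_MINUTE
                 * (y[ix["V164_B"]] + y[ix["V120_B"]]) * u_b)
    degradation = (tp.k_deg / SECONDS_PER_MINUTE
                   * (y[ix["V164_T"]] + y[ix["V120_T"]]) * u_n)

    trans = net.transport_fluxes(y)
    lymph = float(trans.loc[["V164", "V120"], "lymph"].sum())
    perm = float(trans.loc[["V164", "V120"], "permeability_net"].sum())

    return FlowReport(flows={
        "secretion": secretion,
        "internalization_myocyte": myo,
        "internalization_EC_tissue": ec_tissue,
        "internalization_EC_blood": ec_blood,
        "lymphatic": lymph,
        "permeability_net": perm,
        "clearance_blood": clearance,
        "degradation": degradation,
    })


# ---------------------------------------------------------------------------
# VEGF distribution
# ---------------------------------------------------------------------------

def _form_label(sp) -> str:
    """Human-readable bound-form grouping for a VEGF-carrying species."""
    if sp.category == "free_ligand":
        return "free"
    if sp.category == "trap_complex":
        return "trap_complex"
    if sp.category == "ligand_matrix_complex":
        return f"matrix_{sp.location}"
    if sp.location == "myocyte":
        return "myocyte_NRP1"
    if sp.category == "ternary_complex":
        return "ternary_" + "".join(sp.receptors)
    return "receptor_" + "".join(sp.receptors)


@dataclass
class DistributionReport:
    """Fractions of total VEGF by bound form, per compartment and isoform."""

    table: pd.DataFrame   # index (compartment, form), columns total/V164/V120

    def fraction(self, compartment: str, form: str,
                 isoform: str = "total") -> float:
        try:
            return float(self.table.loc[(compartment, form), isoform])
        except KeyError:
            return 0.0

    def unbound_isoform_ratio(self, compartment: str) -> tuple[float, float]:
        """(V164, V120) shares of the unbound pool, in percent."""
        v164 = self.fraction(compartment, "free", "V164_amount")
        v120 = self.fraction(compartment, "free", "V120_amount")
        tot = v164 + v120
        return 100.0 * v164 / tot, 100.0 * v120 / tot


def vegf_distribution(net: ReactionNetwork, y: np.ndarray) -> DistributionReport:
    """Group every VEGF-containing species by bound form.

    Fractions are per compartment (they sum to 1 within each compartment)
    and are reported for total VEGF and per isoform; raw amounts (pmol,
    whole-body) are carried alongside.
    """
    rows = []
    for i, sp in enumerate(net.species):
        if not sp.vegf:
            continue
        amount = y[i] * net.compartment_volume(sp.compartment) * sp.vegf
        rows.append({"compartment": sp.compartment,
                     "form": _form_label(sp),
                     "isoform": sp.isoform, "amount": amount})
    df = pd.DataFrame(rows)
    out = {}
    for comp, sub in df.groupby("compartment"):
        total = sub["amount"].sum()
        if total <= 0:
            raise AnalysisError(f"no VEGF present in {comp}")
        by_form = sub.pivot_table(index="form", columns="isoform",
                                  values="amount", aggfunc="sum",
                                  fill_value=0.0)
        tab = pd.DataFrame(index=by_form.index)
        tab["total"] = by_form.sum(axis=1) / total
        for iso in ("V164", "V120"):
            if iso in by_form:
                iso_total = by_form[iso].sum()
                tab[iso] = (by_form[iso] / iso_total if iso_total > 0
                            else 0.0)
                tab[f"{iso}_amount"] = by_form[iso]
            else:
                tab[iso] = 0.0
                tab[f"{iso}_amount"] = 0.0
        out[comp] = tab
    table = pd.concat(out, names=["compartment", "form"])
    return DistributionReport(table=table)


# ---------------------------------------------------------------------------
# receptor occupancy
# ---------------------------------------------------------------------------

@dataclass
class OccupancyReport:
    """Receptor-state fractions per receptor type and pooled totals.

    ``per_receptor`` fractions are of that receptor type's total within the
    compartment (each column sums to 1); ``pooled`` fractions are of all
    receptor molecules of every type in the compartment, the denominator
    used for statements like "unligated myocyte NRP-1 is 82.8% of total
    receptors".  A receptor inside a VEGF-free couple (VEGFR-1/NRP-1) counts
    as unligated.
    """

    per_receptor: pd.DataFrame   # index (compartment, receptor, state)
    pooled: pd.DataFrame         # index (compartment, location, receptor, state)

    def fraction(self, compartment: str, receptor: str, state: str) -> float:
        try:
            return float(self.per_receptor.loc[(compartment, receptor,
                                                state)])
        except KeyError:
            return 0.0

    def pooled_fraction(self, compartment: str, location: str,
                        receptor: str, state: str) -> float:
        sub = self.pooled
        try:
            return float(sub.loc[(compartment, location, receptor, state)])
        except KeyError:
            return 0.0


def _receptor_state(sp, receptor: str) -> str:
    """State label of ``receptor`` within species ``sp``."""
    if sp.category == "surface_receptor":
        if len(sp.receptors) == 1:
            return "unbound"
        return "coupled_unligated"     # VEGFR-1/NRP-1 couple
    if sp.category == "ternary_complex":
        return f"ternary_{sp.isoform}"
    return f"ligated_{sp.isoform}"


def receptor_occupancy(net: ReactionNetwork, y: np.ndarray) -> OccupancyReport:
    rows = []
    for i, sp in enumerate(net.species):
        for rec in sp.receptors:
            rows.append({"compartment": sp.compartment,
                         "location": sp.location,
                         "receptor": rec,
                         "state": _receptor_state(sp, rec),
                         "amount": y[i] * net.compartment_volume(
                             sp.compartment)})
    df = pd.DataFrame(rows)

    per = {}
    for (comp, rec), sub in df.groupby(["compartment", "receptor"]):
        total = sub["amount"].sum()
        per[(comp, rec)] = sub.groupby("state")["amount"].sum() / total
    per_receptor = pd.concat(per, names=["compartment", "receptor", "state"])

    pooled = {}
    for comp, sub in df.groupby("compartment"):
        total = sub["amount"].sum()
        pooled[comp] = (sub.groupby(["location", "receptor", "state"])
                        ["amount"].sum() / total)
    pooled_tab = pd.concat(pooled,
                           names=["compartment", "location", "receptor",
                                  "state"])
    return OccupancyReport(per_receptor=per_receptor, pooled=pooled_tab)


# ---------------------------------------------------------------------------
# net intercompartmental flows over time
# ---------------------------------------------------------------------------

def net_intercompartmental_flows(net: ReactionNetwork,
                                 result: SimulationResult) -> pd.DataFrame:
    """Signed net tissue-to-blood flow per free species over time (pmol/s).

    Net = intravasation + lymphatic drainage - extravasation; positive means
    movement from the tissue into the blood.
    """
    records = {"time_s": result.times}
    flows = {"VEGF": np.zeros_like(result.times),
             "trap": np.zeros_like(result.times),
             "complex": np.zeros_like(result.times)}
    group = {"V164": "VEGF", "V120": "VEGF", "A": "trap",
             "VA164": "complex", "VA120": "complex"}
    for k, t in enumerate(result.times):
        tf = net.transport_fluxes(result.trajectory[k])
        for species, g in group.items():
            flows[g][k] += tf.loc[species, "net"]
    records.update(flows)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# one-at-a-time parameter sweeps
# ---------------------------------------------------------------------------

#: sweepable parameters: dotted section.key names
SWEEPABLE = {
    "q_v164": ("transport", "q_v164"),
    "c_vegf": ("transport", "c_vegf"),
    "kp_vegf": ("transport", "kp_vegf"),
    "k_deg": ("transport", "k_deg"),
    "k_lymph": ("transport", "k_lymph"),
}


def parameter_sweep(base: ParameterSet, param: str,
                    grid: Sequence[float],
                    continuation: bool = True) -> pd.DataFrame:
    """Steady-state free VEGF (pM, blood & tissue) along a parameter grid.

    Each grid point rebuilds the network and re-equilibrates; with
    ``continuation`` the previous point's steady state seeds the next solve.
    """
    if param not in SWEEPABLE:
        raise AnalysisError(f"unknown sweep parameter {param!r}; "
                            f"choose from {sorted(SWEEPABLE)}")
    section, key = SWEEPABLE[param]
    rows = []
    seed = None
    for value in grid:
        ps = base.replace_section(section, **{key: float(value)})
        net = ReactionNetwork(ps)
        x0 = seed if (continuation and seed is not None) else None
        ss = solve_steady_state(net, x0=x0)
        seed = ss
        blood, tissue = free_vegf_picomolar(net, ss)
        rows.append({"param": param, "value": float(value),
                     "free_vegf_blood_pM": blood,
                     "free_vegf_tissue_pM": tissue})
    return pd.DataFrame(rows)


def permeability_equilibration_limit(base: ParameterSet | None = None,
                                     multipliers: Sequence[float] = (
                                         1e2, 1e3, 1e4, 1e5),
                                     rel_gap: float = 0.01) -> float:
    """Common free-VEGF level (pM) both compartments approach at high k_p.

    Sweeps the VEGF microvascular permeability upward from its default until
    the blood and (fluid-referenced) tissue concentrations agree within
    ``rel_gap``; returns their mean at convergence.
    """
    base = base or ParameterSet()
    kp0 = base.transport.kp_vegf
    grid = [kp0 * m for m in multipliers]
    sweep = parameter_sweep(base, "kp_vegf", grid)
    for _, row in sweep.iterrows():
        b, t = row["free_vegf_blood_pM"], row["free_vegf_tissue_pM"]
        if abs(b - t) / (0.5 * (b + t)) < rel_gap:
            return float(0.5 * (b + t))
    raise AnalysisError("blood and tissue free VEGF did not equilibrate "
                        "within the swept permeability range")


def myonuclear_variant_steady_state(base: ParameterSet | None = None,
                                    domain_length_um: float = 20.0
                                    ) -> tuple[float, float]:
    """Steady state of the long-myonuclear-domain geometry variant.

    Lengthening the domain reduces myocytes (hence myocyte NRP-1) per unit
    tissue; the per-domain secretion rate is scaled up in proportion so the
    secreted VEGF per cm^3 tissue is preserved.

    Returns (blood, tissue) free VEGF in pM.
    """
    base = base or ParameterSet()
    g = myonuclear_variant_inputs(base.muscle, domain_length_um)
    baseline_length = (base.muscle.myonuclear_domain_volume
                       / base.muscle.fiber_cross_section)
    scale = domain_length_um / baseline_length
    ps = replace(base, muscle=g).replace_section(
        "transport", q_v164=base.transport.q_v164 * scale)
    net = ReactionNetwork(ps)
    ss = solve_steady_state(net)
    return free_vegf_picomolar(net, ss)
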