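"""The 40-species, 94-reaction ligand–receptor–transport network.

Molecular interactions (both endothelial surfaces unless noted):

* VEGF120 binds VEGFR-1 and VEGFR-2, but not NRP-1.
* VEGF164 binds VEGFR-1, VEGFR-2, NRP-1 and matrix GAG chains
  (ECM/EBM/PBM, tissue only).
* NRP-1 couples unligated VEGFR-1 (and VEGF120-ligated VEGFR-1); VEGF120
  can still bind the VEGFR-1/NRP-1 couple, yielding the
  VEGF120/VEGFR-1/NRP-1 ternary complex.  VEGF164 bridges VEGFR-2 and
  NRP-1 through two coupling routes (VEGF164·R2 + N1 and VEGF164·N1 + R2).
* NRP-1 on myocytes (tissue only) binds VEGF164.
* The anti-VEGF agent (VEGF Trap) binds either free isoform in either
  compartment, forming an inert, non-internalised complex.
* All endothelial/myocyte surface receptors and complexes are internalised
  at a single rate constant and replaced by constant receptor insertion.
* Free VEGF, free trap and the complex are cleared from plasma; the free
  species are exchanged between compartments by microvascular permeability
  and drained from tissue by lymph (transport terms, not counted among the
  chemical reactions).

Species bookkeeping: 24 tissue species + 16 blood species; 28 reversible
binding steps (56 uni-directional reactions) + 24 internalisations +
7 insertions + 2 secretions + 5 clearances = 94 chemical reactions.
Concentrations are pmol per cm^3 of the owning compartment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .geometry import DerivedGeometry, derive_geometry
from .parameters import ParameterSet

EXPECTED_SPECIES = 40
EXPECTED_REACTIONS = 94
SECONDS_PER_MINUTE = 60.0


class NetworkConstructionError(RuntimeError):
    """Raised when the assembled topology drifts from the 40/94 layout."""


@dataclass(frozen=True)
class SpeciesDef:
    """One molecular species, with composition metadata for the analyses."""

    name: str
    compartment: str      # "tissue" | "blood"
    category: str
    location: str
    vegf: int = 0         # VEGF molecules carried
    isoform: str | None = None   # "V164" | "V120" for VEGF carriers
    trap: int = 0         # trap molecules carried
    receptors: tuple[str, ...] = ()   # receptor types contained


@dataclass(frozen=True)
class Reaction:
    """A single uni-directional chemical reaction with mass-action rate."""

    name: str
    kind: str             # binding|unbinding|internalization|insertion|secretion|clearance
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate_constant: float
    constant_name: str


def _surface_species(tag: str, compartment: str, location: str) -> List[SpeciesDef]:
    s = lambda name, **kw: SpeciesDef(name=f"{name}_{tag}",
                                      compartment=compartment,
                                      location=location, **kw)
    return [
        s("R1", category="surface_receptor", receptors=("R1",)),
        s("R2", category="surface_receptor", receptors=("R2",)),
        s("N1", category="surface_receptor", receptors=("N1",)),
        s("V120R1", category="ligand_receptor_complex", vegf=1,
          isoform="V120", receptors=("R1",)),
        s("V120R2", category="ligand_receptor_complex", vegf=1,
          isoform="V120", receptors=("R2",)),
        s("V164R1", category="ligand_receptor_complex", vegf=1,
          isoform="V164", receptors=("R1",)),
        s("V164R2", category="ligand_receptor_complex", vegf=1,
          isoform="V164", receptors=("R2",)),
        s("V164N1", category="ligand_receptor_complex", vegf=1,
          isoform="V164", receptors=("N1",)),
        s("R1N1", category="surface_receptor", receptors=("R1", "N1")),
        s("V120R1N1", category="ternary_complex", vegf=1, isoform="V120",
          receptors=("R1", "N1")),
        s("V164R2N1", category="ternary_complex", vegf=1, isoform="V164",
          receptors=("R2", "N1")),
    ]


def build_species() -> List[SpeciesDef]:
    tissue_free = [
        SpeciesDef("V164_T", "tissue", "free_ligand", "interstitial_fluid",
                   vegf=1, isoform="V164"),
        SpeciesDef("V120_T", "tissue", "free_ligand", "interstitial_fluid",
                   vegf=1, isoform="V120"),
        SpeciesDef("A_T", "tissue", "trap", "interstitial_fluid", trap=1),
        SpeciesDef("VA164_T", "tissue", "trap_complex", "interstitial_fluid",
                   vegf=1, isoform="V164", trap=1),
        SpeciesDef("VA120_T", "tissue", "trap_complex", "interstitial_fluid",
                   vegf=1, isoform="V120", trap=1),
    ]
    matrix = []
    for region in ("ECM", "EBM", "PBM"):
        matrix.append(SpeciesDef(f"GAG_{region}", "tissue", "matrix_site",
                                 region))
        matrix.append(SpeciesDef(f"V164GAG_{region}", "tissue",
                                 "ligand_matrix_complex", region, vegf=1,
                                 isoform="V164"))
    myocyte = [
        SpeciesDef("N1_myo", "tissue", "surface_receptor", "myocyte",
                   receptors=("N1",)),
        SpeciesDef("V164N1_myo", "tissue", "ligand_receptor_complex",
                   "myocyte", vegf=1, isoform="V164", receptors=("N1",)),
    ]
    blood_free = [
        SpeciesDef("V164_B", "blood", "free_ligand", "plasma", vegf=1,
                   isoform="V164"),
        SpeciesDef("V120_B", "blood", "free_ligand", "plasma", vegf=1,
                   isoform="V120"),
        SpeciesDef("A_B", "blood", "trap", "plasma", trap=1),
        SpeciesDef("VA164_B", "blood", "trap_complex", "plasma", vegf=1,
                   isoform="V164", trap=1),
        SpeciesDef("VA120_B", "blood", "trap_complex", "plasma", vegf=1,
                   isoform="V120", trap=1),
    ]
    species = (tissue_free + matrix
               + _surface_species("abl", "tissue", "abluminal_EC")
               + myocyte + blood_free
               + _surface_species("lum", "blood", "luminal_EC"))
    names = [sp.name for sp in species]
    if len(set(names)) != len(names):
        raise NetworkConstructionError("duplicate species names")
    return species


class ReactionNetwork:
    """Compiled network: species registry, reactions, transport, rate terms.

    The right-hand side decomposes as

        dy/dt = S2 @ r2(y)  +  L @ y  +  c0  +  q_A(t) e_A,B

    with ``r2`` the bimolecular mass-action fluxes, ``L`` the constant
    matrix collecting every first-order process (unbinding, internalisation,
    clearance, degradation, permeability, lymph) and ``c0`` the constant
    sources (secretion, receptor insertion).
    """

    def __init__(self, params: ParameterSet | None = None,
                 geometry: DerivedGeometry | None = None):
        self.params = params or ParameterSet()
        self.geo = geometry or derive_geometry(
            self.params.whole_body, self.params.muscle, self.params.matrix)
        self.species = build_species()
        self.index: Dict[str, int] = {sp.name: i
                                      for i, sp in enumerate(self.species)}
        self.n_species = len(self.species)
        self.reactions: List[Reaction] = []
        self._initial_receptor_state = self._compute_initial_state()
        self._build_reactions()
        self._check_counts()
        self._compile()

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    def _compute_initial_state(self) -> np.ndarray:
        """Receptors/matrix sites at resting density, no ligand, no trap."""
        rc = self.params.receptors
        conv = self.geo.conversions
        y0 = np.zeros(self.n_species)
        ix = self.index
        lum = rc.luminal_fraction
        for rec, total in (("R1", rc.vegfr1_per_ec),
                           ("R2", rc.vegfr2_per_ec),
                           ("N1", rc.nrp1_per_ec)):
            y0[ix[f"{rec}_lum"]] = total * lum * conv["luminal_receptor"]
            y0[ix[f"{rec}_abl"]] = (total * (1.0 - lum)
                                    * conv["abluminal_receptor"])
        y0[ix["N1_myo"]] = rc.nrp1_per_myocyte * conv["myocyte_receptor"]
        y0[ix["GAG_ECM"]] = rc.ecm_sites_molar * conv["ecm_molar"]
        y0[ix["GAG_EBM"]] = rc.ebm_sites_molar * conv["ebm_molar"]
        y0[ix["GAG_PBM"]] = rc.pbm_sites_molar * conv["pbm_molar"]
        return y0

    def _add_pair(self, a: str, b: str, c: str, kon: float, koff: float,
                  kon_name: str, koff_name: str) -> None:
        ix = self.index
        self.reactions.append(Reaction(
            name=f"{a}+{b}->{c}", kind="binding",
            reactants=(ix[a], ix[b]), products=(ix[c],),
            rate_constant=kon, constant_name=kon_name))
        self.reactions.append(Reaction(
            name=f"{c}->{a}+{b}", kind="unbinding",
            reactants=(ix[c],), products=(ix[a], ix[b]),
            rate_constant=koff, constant_name=koff_name))

    def _build_reactions(self) -> None:
        kin = self.params.kinetics
        tp = self.params.transport
        conv = self.geo.conversions
        ix = self.index

        for tag, free_tag, molar, coupling in (
                ("abl", "T", conv["tissue_molar"],
                 conv["tissue_surface_coupling"]),
                ("lum", "B", conv["blood_molar"],
                 conv["blood_surface_coupling"])):
            pair = lambda a, b, c, kon, koff, kn, xn: self._add_pair(
                a, b, c, kon, koff, kn, xn)
            pair(f"V120_{free_tag}", f"R1_{tag}", f"V120R1_{tag}",
                 kin.kon_r1 / molar, kin.koff_r1, "kon_r1", "koff_r1")
            pair(f"V164_{free_tag}", f"R1_{tag}", f"V164R1_{tag}",
                 kin.kon_r1 / molar, kin.koff_r1, "kon_r1", "koff_r1")
            pair(f"V120_{free_tag}", f"R2_{tag}", f"V120R2_{tag}",
                 kin.kon_r2 / molar, kin.koff_r2, "kon_r2", "koff_r2")
            pair(f"V164_{free_tag}", f"R2_{tag}", f"V164R2_{tag}",
                 kin.kon_r2 / molar, kin.koff_r2, "kon_r2", "koff_r2")
            pair(f"V164_{free_tag}", f"N1_{tag}", f"V164N1_{tag}",
                 kin.kon_n1 / molar, kin.koff_n1, "kon_n1", "koff_n1")
            pair(f"R1_{tag}", f"N1_{tag}", f"R1N1_{tag}",
                 kin.kc_r1_n1 / coupling, kin.kdissoc_r1n1,
                 "kc_r1_n1", "kdissoc_r1n1")
            pair(f"V120R1_{tag}", f"N1_{tag}", f"V120R1N1_{tag}",
                 kin.kc_r1_n1 / coupling, kin.kdissoc_r1n1,
                 "kc_r1_n1", "kdissoc_r1n1")
            pair(f"V120_{free_tag}", f"R1N1_{tag}", f"V120R1N1_{tag}",
                 kin.kon_r1 / molar, kin.koff_r1, "kon_r1", "koff_r1")
            pair(f"V164R2_{tag}", f"N1_{tag}", f"V164R2N1_{tag}",
                 kin.kc_v164r2_n1 / coupling, kin.koff_v164r2_n1,
                 "kc_v164r2_n1", "koff_v164r2_n1")
            pair(f"V164N1_{tag}", f"R2_{tag}", f"V164R2N1_{tag}",
                 kin.kc_v164n1_r2 / coupling, kin.koff_v164n1_r2,
                 "kc_v164n1_r2", "koff_v164n1_r2")

        self._add_pair("V164_T", "N1_myo", "V164N1_myo",
                       kin.kon_n1 / conv["tissue_molar"], kin.koff_n1,
                       "kon_n1", "koff_n1")
        for region in ("ECM", "EBM", "PBM"):
            self._add_pair("V164_T", f"GAG_{region}", f"V164GAG_{region}",
                           kin.kon_gag / conv["tissue_molar"], kin.koff_gag,
                           "kon_gag", "koff_gag")
        for iso in ("V164", "V120"):
            self._add_pair(f"{iso}_T", "A_T", f"VA{iso[1:]}_T",
                           kin.kon_trap / conv["tissue_molar"],
                           kin.koff_trap, "kon_trap", "koff_trap")
            self._add_pair(f"{iso}_B", "A_B", f"VA{iso[1:]}_B",
                           kin.kon_trap / conv["blood_molar"],
                           kin.koff_trap, "kon_trap", "koff_trap")

        # internalisation of every endothelial/myocyte surface species
        for sp in self.species:
            if sp.location in ("abluminal_EC", "luminal_EC", "myocyte"):
                self.reactions.append(Reaction(
                    name=f"int:{sp.name}", kind="internalization",
                    reactants=(ix[sp.name],), products=(),
                    rate_constant=kin.kint, constant_name="kint"))

        # receptor insertion balances internalisation of the resting pool
        for name in ("R1_abl", "R2_abl", "N1_abl",
                     "R1_lum", "R2_lum", "N1_lum", "N1_myo"):
            self.reactions.append(Reaction(
                name=f"ins:{name}", kind="insertion", reactants=(),
                products=(ix[name],),
                rate_constant=kin.kint * self._initial_receptor_state[ix[name]],
                constant_name="s"))

        # secretion of the two isoforms by myocytes, pmol/cm^3 tissue/s
        conv_myo = conv["myocyte_receptor"]  # pmol/cm^3 per molecules/cell
        for iso, q in (("V164", tp.q_v164), ("V120", tp.q_v120)):
            self.reactions.append(Reaction(
                name=f"sec:{iso}", kind="secretion", reactants=(),
                products=(ix[f"{iso}_T"],), rate_constant=q * conv_myo,
                constant_name=f"q_{iso.lower()}"))

        # plasma clearance of free VEGF, free trap, and complex
        for name, c in (("V164_B", tp.c_vegf), ("V120_B", tp.c_vegf),
                        ("A_B", tp.c_trap),
                        ("VA164_B", tp.c_complex), ("VA120_B", tp.c_complex)):
            self.reactions.append(Reaction(
                name=f"clr:{name}", kind="clearance",
                reactants=(ix[name],), products=(),
                rate_constant=c / SECONDS_PER_MINUTE, constant_name="c"))

    def _check_counts(self) -> None:
        n_t = sum(sp.compartment == "tissue" for sp in self.species)
        n_b = sum(sp.compartment == "blood" for sp in self.species)
        if (n_t, n_b) != (24, 16):
            raise NetworkConstructionError(
                f"species split {n_t}/{n_b}, expected 24 tissue/16 blood")
        if len(self.reactions) != EXPECTED_REACTIONS:
            raise NetworkConstructionError(
                f"{len(self.reactions)} reactions, expected "
                f"{EXPECTED_REACTIONS}")

    # ------------------------------------------------------------------
    # compilation into array form
    # ------------------------------------------------------------------
    def _compile(self) -> None:
        n = self.n_species
        tp = self.params.transport
        geo = self.geo

        bi = [r for r in self.reactions if len(r.reactants) == 2]
        uni = [r for r in self.reactions if len(r.reactants) == 1]
        zero = [r for r in self.reactions if len(r.reactants) == 0]

        self._bi_i = np.array([r.reactants[0] for r in bi], dtype=np.intp)
        self._bi_j = np.array([r.reactants[1] for r in bi], dtype=np.intp)
        self._bi_k = np.array([r.rate_constant for r in bi])
        s2 = np.zeros((n, len(bi)))
        for col, r in enumerate(bi):
            for i in r.reactants:
                s2[i, col] -= 1.0
            for i in r.products:
                s2[i, col] += 1.0
        self._s2 = s2

        lmat = np.zeros((n, n))
        for r in uni:
            i = r.reactants[0]
            lmat[i, i] -= r.rate_constant
            for j in r.products:
                lmat[j, i] += r.rate_constant

        c0 = np.zeros(n)
        for r in zero:
            for j in r.products:
                c0[j] += r.rate_constant
        self._c0 = c0

        # ---- transport terms (permeability + lymph), linear in y --------
        ix = self.index
        k_av = geo.k_av
        f_p = geo.plasma_fraction
        u_n = geo.tissue_volume
        u_b = geo.blood_volume
        s_nb = geo.total_capillary_surface
        k_l = tp.k_lymph
        self._transport = []  # (tissue idx, blood idx, kp) for reporting
        for t_name, b_name, kp in (
                ("V164_T", "V164_B", tp.kp_vegf),
                ("V120_T", "V120_B", tp.kp_vegf),
                ("A_T", "A_B", tp.kp_trap),
                ("VA164_T", "VA164_B", tp.kp_trap),
                ("VA120_T", "VA120_B", tp.kp_trap)):
            it, ib = ix[t_name], ix[b_name]
            self._transport.append((it, ib, kp))
            # permeability: J = kp*S_NB*(C_B/f_p - C_T/K_AV), blood -> tissue
            lmat[it, ib] += kp * s_nb / (f_p * u_n)
            lmat[it, it] -= kp * s_nb / (k_av * u_n)
            lmat[ib, ib] -= kp * s_nb / (f_p * u_b)
            lmat[ib, it] += kp * s_nb / (k_av * u_b)
            # lymphatic drainage, tissue -> blood
            lmat[it, it] -= k_l / (k_av * u_n)
            lmat[ib, it] += k_l / (k_av * u_b)

        # tissue VEGF degradation (free isoforms only)
        kdeg = tp.k_deg / SECONDS_PER_MINUTE
        if kdeg:
            for name in ("V164_T", "V120_T"):
                lmat[ix[name], ix[name]] -= kdeg
        self._lmat = lmat
        self._i_trap_blood = ix["A_B"]
        self._dr2_buf = np.zeros((len(bi), n))

    # ------------------------------------------------------------------
    # evaluation
    # ------------------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray, q_a: float = 0.0) -> np.ndarray:
        """Time derivative of the concentration vector (pmol/cm^3/s)."""
        r2 = self._bi_k * y[self._bi_i] * y[self._bi_j]
        dy = self._s2 @ r2
        dy += self._lmat @ y
        dy += self._c0
        if q_a:
            dy[self._i_trap_blood] += q_a
        return dy

    def jacobian(self, t: float, y: np.ndarray,
                 q_a: float = 0.0) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs` with respect to ``y``."""
        d = self._dr2_buf
        d[:] = 0.0
        rows = np.arange(d.shape[0])
        d[rows, self._bi_i] = self._bi_k * y[self._bi_j]
        d[rows, self._bi_j] += self._bi_k * y[self._bi_i]
        return self._lmat + self._s2 @ d

    # ------------------------------------------------------------------
    # helpers
    # ------------------------------------------------------------------
    def initial_state(self) -> np.ndarray:
        """Resting state: receptors & matrix sites populated, no ligand."""
        return self._initial_receptor_state.copy()

    def species_names(self) -> List[str]:
        return [sp.name for sp in self.species]

    def compartment_volume(self, compartment: str) -> float:
        return (self.geo.tissue_volume if compartment == "tissue"
                else self.geo.blood_volume)

    def amount_weights(self, count_attr: str = "vegf") -> np.ndarray:
        """Per-species weights converting concentration to whole-body pmol.

        ``count_attr`` selects what is counted ("vegf" or "trap" molecules).
        """
        return np.array([getattr(sp, count_attr)
                         * self.compartment_volume(sp.compartment)
                         for sp in self.species])

    def reaction_fluxes(self, y: np.ndarray) -> np.ndarray:
        """Instantaneous rate of every chemical reaction at state ``y``."""
        rates = np.empty(len(self.reactions))
        for k, r in enumerate(self.reactions):
            rate = r.rate_constant
            for i in r.reactants:
                rate *= y[i]
            rates[k] = rate
        return rates

    def transport_fluxes(self, y: np.ndarray) -> pd.DataFrame:
        """Permeability / lymph flows per free species, pmol/s, whole body.

        Positive permeability flux means net tissue-to-blood movement
        (intravasation); lymph is always tissue-to-blood.
        """
        geo = self.geo
        rows = []
        for it, ib, kp in self._transport:
            c_t_fluid = y[it] / geo.k_av
            c_b_plasma = y[ib] / geo.plasma_fraction
            perm = kp * geo.total_capillary_surface * (c_t_fluid - c_b_plasma)
            lymph = self.params.transport.k_lymph * c_t_fluid
            rows.append({"species": self.species[it].name.rsplit("_", 1)[0],
                         "permeability_net": perm, "lymph": lymph,
                         "net": perm + lymph})
        return pd.DataFrame(rows).set_index("species")

    def stoichiometry(self) -> np.ndarray:
        """Dense species x reaction stoichiometry matrix (40 x 94)."""
        s = np.zeros((self.n_species, len(self.reactions)))
        for col, r in enumerate(self.reactions):
            for i in r.reactants:
                s[i, col] -= 1.0
            for i in r.products:
                s[i, col] += 1.0
        return s

    def reaction_table(self) -> pd.DataFrame:
        names = self.species_names()
        rows = []
        for k, r in enumerate(self.reactions):
            rows.append({
                "id": f"r{k + 1:02d}", "kind": r.kind,
                "reactants": " + ".join(names[i] for i in r.reactants),
                "products": " + ".join(names[i] for i in r.products),
                "rate_constant": r.constant_name,
                "value": r.rate_constant,
                "units": _rate_units(len(r.reactants)),
            })
        return pd.DataFrame(rows)


def _rate_units(order: int) -> str:
    return {0: "pmol/cm^3/s",
            1: "1/s",
            2: "(pmol/cm^3)^-1 s^-1"}[order]


def total_vegf(net: ReactionNetwork, y: np.ndarray,
               compartment: str | None = None) -> float:
    """Total VEGF amount (pmol) across all carrier species."""
    w = net.amount_weights("vegf")
    if compartment is not None:
        mask = np.array([sp.compartment == compartment
                         for sp in net.species], dtype=float)
        w = w * mask
    return float(w @ y)
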