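"""Reaction network: topology guards, kinetics, conservation properties."""

import numpy as np
import pytest

from vegfmouse.network import (NetworkConstructionError, ReactionNetwork,
                               total_vegf)
from vegfmouse.parameters import ParameterSet
from conftest import sigfig_tol


def closed_system_params() -> ParameterSet:
    """No secretion, transport, clearance or internalisation: pure binding."""
    ps = ParameterSet()
    ps = ps.replace_section("transport", q_v164=1e-30, k_lymph=0.0,
                            kp_vegf=0.0, kp_trap=0.0, c_vegf=0.0,
                            c_trap=0.0, c_complex=0.0)
    return ps.replace_section("kinetics", kint=0.0)


class TestTopology:
    def test_species_and_reaction_counts(self, net):
        assert net.n_species == 40
        assert len(net.reactions) == 94
        comp = [sp.compartment for sp in net.species]
        assert comp.count("tissue") == 24
        assert comp.count("blood") == 16

    def test_reaction_kind_census(self, net):
        kinds = [r.kind for r in net.reactions]
        assert kinds.count("binding") == 28
        assert kinds.count("unbinding") == 28
        assert kinds.count("internalization") == 24
        assert kinds.count("insertion") == 7
        assert kinds.count("secretion") == 2
        assert kinds.count("clearance") == 5

    def test_count_guard_trips_on_drift(self, net):
        import copy

        broken = copy.copy(net)
        broken.reactions = net.reactions[:-1]
        with pytest.raises(NetworkConstructionError):
            broken._check_counts()

    def test_ternary_complexes_in_both_compartments(self, net):
        names = set(net.species_names())
        for tag in ("abl", "lum"):
            assert f"V164R2N1_{tag}" in names
            assert f"V120R1N1_{tag}" in names

    def test_isoform_selectivity(self, net):
        """VEGF120 never binds NRP-1 directly nor matrix GAG chains."""
        names = net.species_names()
        for r in self.binding_reactions(net):
            reactants = {names[i] for i in r.reactants}
            if any(n.startswith("V120_") for n in reactants):
                partners = {n for n in reactants
                            if not n.startswith("V120_")}
                assert not any(p.startswith(("N1_", "GAG_"))
                               for p in partners)

    @staticmethod
    def binding_reactions(net):
        return [r for r in net.reactions if r.kind == "binding"]


class TestKineticConsistency:
    @pytest.mark.parametrize("kd_attr, printed_molar", [
        ("kd_r1", 33e-12), ("kd_r2", 100e-12), ("kd_n1", 312e-12),
        ("kd_gag", 24e-9), ("kd_trap", 0.37e-12),
    ])
    def test_kd_equals_koff_over_kon(self, default_params, kd_attr,
                                     printed_molar):
        kd = getattr(default_params.kinetics, kd_attr)
        assert kd == pytest.approx(printed_molar,
                                   abs=sigfig_tol(printed_molar, 2))

    @pytest.mark.parametrize("reactant_pair, printed_tissue", [
        (("V164_T", "R1_abl"), 2.65e-1),
        (("V164_T", "R2_abl"), 8.84e-2),
        (("V164_T", "N1_abl"), 2.77e-2),
        (("V164_T", "GAG_ECM"), 3.72e-3),
        (("V164_T", "A_T"), 1.00),
        (("V164R2_abl", "N1_abl"), 1.99e-1),
        (("V164N1_abl", "R2_abl"), 6.41e-1),
        (("R1_abl", "N1_abl"), 6.41e-1),
    ])
    def test_converted_tissue_rate_constants(self, net, reactant_pair,
                                             printed_tissue):
        """Converted on-rates match the published per-tissue-volume values."""
        names = net.species_names()
        match = [r for r in net.reactions if r.kind == "binding" and
                 {names[i] for i in r.reactants} == set(reactant_pair)]
        assert len(match) == 1
        assert match[0].rate_constant == pytest.approx(printed_tissue,
                                                       rel=5e-3)

    @pytest.mark.parametrize("reactant_pair, printed_blood", [
        (("V164_B", "R1_lum"), 6.15e-2),
        (("V164_B", "N1_lum"), 6.41e-3),
        (("V164_B", "A_B"), 2.32e-1),
        (("V164R2_lum", "N1_lum"), 1.59e-2),
    ])
    def test_converted_blood_rate_constants(self, net, reactant_pair,
                                            printed_blood):
        names = net.species_names()
        match = [r for r in net.reactions if r.kind == "binding" and
                 {names[i] for i in r.reactants} == set(reactant_pair)]
        assert len(match) == 1
        assert match[0].rate_constant == pytest.approx(printed_blood,
                                                       rel=5e-3)


class TestInitialState:
    @pytest.mark.parametrize("name, printed", [
        ("R1_lum", 1.70e-1), ("R1_abl", 1.36e-2),
        ("R2_lum", 1.13e-1), ("R2_abl", 9.07e-3),
        ("N1_lum", 5.67), ("N1_abl", 4.53e-1), ("N1_myo", 2.26),
        ("GAG_EBM", 9.02), ("GAG_PBM", 40.95), ("GAG_ECM", 82.50),
    ])
    def test_published_receptor_densities(self, net, name, printed):
        """Table of resting densities in pmol/cm^3 of the compartment.

        Matched to 1%: the published numbers chain intermediate-rounded
        conversion factors.
        """
        y0 = net.initial_state()
        assert y0[net.index[name]] == pytest.approx(printed, rel=1e-2)

    def test_ligands_absent_initially(self, net):
        y0 = net.initial_state()
        for sp, v in zip(net.species, y0):
            if sp.vegf or sp.trap:
                assert v == 0.0


class TestRhsAndJacobian:
    def test_zero_state_zero_sources_is_equilibrium(self):
        """With no secretion and no insertion, the empty state is fixed."""
        ps = closed_system_params()
        net = ReactionNetwork(ps)
        dy = net.rhs(0.0, np.zeros(net.n_species))
        assert np.allclose(dy, 0.0, atol=1e-25)

    def test_insertion_balances_internalization(self, net):
        """Resting receptor state is stationary without ligand."""
        dy = net.rhs(0.0, net.initial_state())
        ix = net.index
        for name in ("R2_lum", "R2_abl"):  # no coupling partner involved
            assert dy[ix[name]] == pytest.approx(0.0, abs=1e-18)

    def test_rhs_equals_stoichiometry_times_flux(self, net):
        """Compiled right-hand side agrees with the declarative reaction
        list (stoichiometry x flux) plus the explicit transport terms."""
        rng = np.random.default_rng(42)
        s = net.stoichiometry()
        geo = net.geo
        for _ in range(10):
            y = rng.uniform(0, 1.0, net.n_species)
            expected = s @ net.reaction_fluxes(y)
            tf = net.transport_fluxes(y)
            for it, ib, kp in net._transport:
                perm = tf.iloc[[i for i, (jt, _, _) in
                                enumerate(net._transport) if jt == it][0]]
                net_flux = perm["net"]
                expected[it] -= net_flux / geo.tissue_volume
                expected[ib] += net_flux / geo.blood_volume
            assert np.allclose(net.rhs(0.0, y), expected, rtol=1e-10,
                               atol=1e-14)

    def test_jacobian_matches_finite_differences(self, net):
        rng = np.random.default_rng(7)
        y = np.abs(rng.normal(0.1, 0.2, net.n_species))
        jac = net.jacobian(0.0, y)
        eps = 1e-7
        f0 = net.rhs(0.0, y)
        for j in range(net.n_species):
            yp = y.copy()
            yp[j] += eps
            col = (net.rhs(0.0, yp) - f0) / eps
            assert np.allclose(jac[:, j], col, rtol=5e-4, atol=1e-8)


class TestConservation:
    def test_ligand_conservation_closed_system(self):
        """With transport, secretion, clearance, internalisation and
        insertion all disabled, total VEGF is constant along trajectories."""
        from scipy.integrate import solve_ivp

        net = ReactionNetwork(closed_system_params())
        rng = np.random.default_rng(3)
        y0 = net.initial_state()
        ix = net.index
        for name in ("V164_T", "V120_T", "V164_B", "V120_B", "A_T", "A_B"):
            y0[ix[name]] = rng.uniform(0.001, 0.1)
        sol = solve_ivp(net.rhs, (0, 1e6), y0, method="BDF",
                        jac=net.jacobian, rtol=1e-10, atol=1e-18)
        v0 = total_vegf(net, y0)
        vT = total_vegf(net, sol.y[:, -1])
        assert vT == pytest.approx(v0, rel=1e-8)
        w_trap = net.amount_weights("trap")
        assert w_trap @ sol.y[:, -1] == pytest.approx(w_trap @ y0, rel=1e-8)

    def test_receptor_pools_relax_to_initial_density(self, net):
        """Without ligand each receptor's total pool stays at its resting
        density (insertion balances internalisation), even though the
        VEGFR-1/NRP-1 couple redistributes the pool internally."""
        from scipy.integrate import solve_ivp

        ps = ParameterSet().replace_section("transport", q_v164=1e-30)
        qnet = ReactionNetwork(ps)
        sol = solve_ivp(qnet.rhs, (0, 2e6), qnet.initial_state(),
                        method="BDF", jac=qnet.jacobian, rtol=1e-10,
                        atol=1e-20)
        y = sol.y[:, -1]
        y0 = qnet.initial_state()
        for rec in ("R1", "R2", "N1"):
            for comp in ("tissue", "blood"):
                pool = sum(
                    y[i] * sp.receptors.count(rec)
                    for i, sp in enumerate(qnet.species)
                    if sp.compartment == comp and rec in sp.receptors)
                pool0 = sum(
                    y0[i] * sp.receptors.count(rec)
                    for i, sp in enumerate(qnet.species)
                    if sp.compartment == comp and rec in sp.receptors)
                assert pool == pytest.approx(pool0, rel=1e-6)

    def test_detailed_balance_single_pair(self):
        """An isolated binding pair equilibrates to bound/free = R/Kd."""
        from scipy.integrate import solve_ivp

        net = ReactionNetwork(closed_system_params())
        ix = net.index
        y0 = np.zeros(net.n_species)
        y0[ix["V164_T"]] = 0.01
        y0[ix["N1_myo"]] = 2.0
        sol = solve_ivp(net.rhs, (0, 1e6), y0, method="BDF",
                        jac=net.jacobian, rtol=1e-12, atol=1e-22)
        y = sol.y[:, -1]
        kon = [r for r in net.reactions
               if r.kind == "binding"
               and set(r.reactants) == {ix["V164_T"], ix["N1_myo"]}][0]
        kd = net.params.kinetics.koff_n1 / kon.rate_constant
        ratio = y[ix["V164N1_myo"]] / (y[ix["V164_T"]] * y[ix["N1_myo"]])
        assert ratio == pytest.approx(1.0 / kd, rel=1e-3)

    def test_trap_with_zero_affinity_forms_no_complex(self):
        ps = closed_system_params().replace_section("kinetics", kon_trap=0.0)
        net = ReactionNetwork(ps)
        ix = net.index
        y0 = np.zeros(net.n_species)
        y0[ix["V164_T"]] = 0.01
        y0[ix["A_T"]] = 10.0
        dy = net.rhs(0.0, y0)
        assert dy[ix["VA164_T"]] == 0.0
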