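"""Network construction, mass-action right-hand side, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sacsim import (ConfigurationError, ParameterSet, build_full_network,
                    build_reduced_network, conservation_totals, ode_rhs,
                    reference_parameters)
from sacsim.network import FULL_SPECIES, Reaction, ReactionNetwork, Species

SPEC_SPECIES = {
    "Kin_U", "Kin_A", "APC/C", "Cdc20", "APC/C:Cdc20", "Securin", "CyclinB",
    "O-Mad2", "C-Mad2", "C-Mad2:Cdc20", "BubR1:Bub3", "MCC", "BCC",
    "APC/C:MCC", "APC/C:Cdc20:C-Mad2", "APC/C:BCC", "APC/C:Cdc20:MCC",
}


def brute_force_rhs(net, state):
    """Independent oracle: accumulate +-propensity reaction by reaction,
    straight from the declarative reaction list (no stoichiometry matrix)."""
    dy = {n: 0.0 for n in net.species_names}
    conc = dict(zip(net.species_names, state))
    for r in net.reactions:
        directions = [(r.rate_symbol, r.educts, r.products, r.modifiers)]
        if r.reversible:
            directions.append((r.reverse_rate_symbol, r.products, r.educts,
                               ()))
        for sym, educts, products, mods in directions:
            prop = getattr(net.params, sym)
            for e in educts:
                prop *= conc[e]
            for m in mods:
                prop *= conc[m]
            for e in educts:
                dy[e] -= prop
            for p in products:
                dy[p] += prop
    return np.array([dy[n] for n in net.species_names])


class TestFullNetwork:
    def test_seventeen_schemes_and_species(self, full_net):
        assert full_net.n_schemes == 17
        assert set(full_net.species_names) == SPEC_SPECIES

    def test_kin_a_is_absorbing(self, full_net):
        for r in full_net.reactions:
            assert "Kin_A" not in r.educts

    def test_missing_rate_symbol_is_named(self, ref_params):
        sp = [Species("A", "neutral", 1.0)]
        rx = [Reaction("X", ("A",), (), "k99")]
        with pytest.raises(ConfigurationError, match="k99"):
            ReactionNetwork("broken", sp, rx, ref_params)

    def test_modifier_must_not_be_consumed(self):
        with pytest.raises(ConfigurationError, match="modifier"):
            Reaction("X", ("A",), ("B",), "k1", modifiers=("A",))


class TestReducedNetwork:
    def test_five_schemes(self, ref_params):
        net = build_reduced_network(ref_params)
        assert net.n_schemes == 5

    def test_feedback_propensity_carries_apc(self, ref_params):
        net = build_reduced_network(ref_params,
                                    include_kina_in_feedback=False)
        state = net.initial_state()
        state[net.index["APC/C"]] = 0.05
        state[net.index["APC/C:MCC"]] = 0.02
        props = net.propensities(state)
        j = [i for i, s in enumerate(net._step_schemes) if s == "M4"][0]
        assert props[j] == pytest.approx(ref_params.kM3 * 0.05 * 0.02)
        # with no free APC/C the autocatalytic feedback is silent
        state[net.index["APC/C"]] = 0.0
        assert net.propensities(state)[j] == 0.0

    def test_feedback_kina_variant(self, ref_params):
        net = build_reduced_network(ref_params,
                                    include_kina_in_feedback=True)
        state = net.initial_state()
        state[net.index["APC/C"]] = 0.05
        state[net.index["APC/C:MCC"]] = 0.02
        state[net.index["Kin_A"]] = 46.0
        j = [i for i, s in enumerate(net._step_schemes) if s == "M4"][0]
        assert net.propensities(state)[j] == pytest.approx(
            ref_params.kM3 * 0.05 * 0.02 * 46.0)


class TestOdeRhs:
    def test_empty_state_has_zero_derivative(self, full_net):
        state = np.zeros(len(full_net.species))
        assert np.allclose(ode_rhs(full_net, state), 0.0)

    def test_securin_derivative_is_degradation_only(self, full_net,
                                                    ref_params):
        state = full_net.initial_state()
        state[full_net.index["APC/C:Cdc20"]] = 0.03
        dy = ode_rhs(full_net, state)
        i = full_net.index["Securin"]
        assert dy[i] == pytest.approx(
            -ref_params.kD * 0.03 * ref_params.Securin)

    def test_negative_state_rejected(self, full_net):
        state = full_net.initial_state()
        state[3] = -0.01
        with pytest.raises(ValueError, match="negative"):
            ode_rhs(full_net, state)

    def test_wrong_length_rejected(self, full_net):
        with pytest.raises(ValueError, match="length"):
            ode_rhs(full_net, np.ones(3))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        """Compiled RHS equals the per-reaction accumulation oracle."""
        p = reference_parameters()
        for net in (build_full_network(p), build_reduced_network(p)):
            rng = np.random.default_rng(seed)
            state = rng.uniform(0, 0.5, size=len(net.species))
            for kin in ("Kin_U", "Kin_A"):
                state[net.index[kin]] = rng.integers(0, 93)
            np.testing.assert_allclose(
                ode_rhs(net, state), brute_force_rhs(net, state),
                rtol=1e-12, atol=1e-15)


class TestConservation:
    def test_full_model_composition(self, full_net):
        state = full_net.initial_state()
        rng = np.random.default_rng(7)
        state[:] = rng.uniform(0, 0.2, len(state))
        state[full_net.index["Kin_U"]] = 60
        state[full_net.index["Kin_A"]] = 32
        t = conservation_totals(full_net, state)
        g = lambda n: state[full_net.index[n]]
        assert t["kinetochores"] == 92
        assert t["APC/C"] == pytest.approx(
            g("APC/C") + g("APC/C:Cdc20") + g("APC/C:MCC")
            + g("APC/C:Cdc20:C-Mad2") + g("APC/C:BCC")
            + g("APC/C:Cdc20:MCC"))
        # the double-Cdc20 complex counts twice in the Cdc20 total
        assert t["Cdc20"] == pytest.approx(
            g("Cdc20") + g("APC/C:Cdc20") + g("C-Mad2:Cdc20") + g("MCC")
            + g("BCC") + g("APC/C:MCC") + g("APC/C:Cdc20:C-Mad2")
            + g("APC/C:BCC") + 2 * g("APC/C:Cdc20:MCC"))

    def test_reduced_model_mcct(self, ref_params):
        net = build_reduced_network(ref_params)
        state = net.initial_state()
        state[net.index["MCC"]] = 0.04
        state[net.index["APC/C:MCC"]] = 0.03
        t = conservation_totals(net, state)
        assert t["MCC"] == pytest.approx(0.07)
        assert t["APC/C"] == pytest.approx(state[net.index["APC/C"]] + 0.03)
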