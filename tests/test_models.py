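"""Transporter fixtures: topology, parameters, presets, invariants."""

import numpy as np
import pytest

import monokin as mk
from monokin.energetics import loop_charge, loop_profile
from monokin.scheme import independent_cycles

from conftest import collapsed_conditions


class TestSubstrateKinetics:
    @pytest.mark.parametrize(
        "builder, k_on, k_off",
        [
            (mk.build_dat_model, 9e5, 30.0),
            (mk.build_net_model, 3e5, 1.0),
            (mk.build_sert_model, 1e5, 1.0),
        ],
    )
    def test_fluorescent_substrate_binding_parameters(self, builder, k_on, k_off):
        model = builder()
        assert model.params["k_on_S_active"] == k_on
        assert model.params["k_off_S_active"] == k_off
        tr = model.scheme.find_transition("ToClNa", "ToClNaS")
        assert tr.k0_fwd == k_on
        assert tr.k0_rev == k_off

    def test_dat_substrate_dissociation_constant(self, dat_model):
        assert dat_model.substrate_kd == pytest.approx(33.3e-6, rel=1e-2)


class TestDatNetSharing:
    def test_differ_only_in_substrate_and_conducting_state(self):
        dat = mk.build_dat_model(with_conducting_state=False)
        net = mk.build_net_model()
        assert [s.name for s in dat.scheme.states] == [s.name for s in net.scheme.states]
        substrate_edges = {
            frozenset(("ToClNa", "ToClNaS")),  # binding
            frozenset(("TiClS", "TiCl")),  # intracellular release
        }
        for td, tn in zip(dat.scheme.transitions, net.scheme.transitions):
            assert td.pair == tn.pair
            assert td.zQ == tn.zQ
            if td.pair in substrate_edges:
                continue
            # the return step closes the loop thermodynamically; its reverse
            # rate is substrate-independent because binding terms cancel
            assert td.k0_fwd == pytest.approx(tn.k0_fwd, rel=1e-12)
            assert td.k0_rev == pytest.approx(tn.k0_rev, rel=1e-12)

    def test_net_lacks_conducting_state_by_default(self, net_model, dat_model):
        assert net_model.conducting_state is None
        assert dat_model.conducting_state == "Tcond"
        assert "Tcond" not in net_model.scheme.state_names


class TestLoopCharges:
    def test_sert_antiport_loops_electroneutral(self, sert_model):
        k_loop = ["ToCl", "ToClNa", "ToClNaS", "ToccClNaS", "TiClNaS",
                  "TiClS", "TiCl", "TiClK", "ToccClK", "ToClK", "ToCl"]
        h_loop = ["ToCl", "ToClNa", "ToClNaS", "ToccClNaS", "TiClNaS",
                  "TiClS", "TiCl", "TiClH", "ToccClH", "ToClH", "ToCl"]
        assert loop_charge(sert_model.scheme, k_loop) == pytest.approx(0.0, abs=1e-12)
        assert loop_charge(sert_model.scheme, h_loop) == pytest.approx(0.0, abs=1e-12)

    def test_dat_transport_loop_electrogenic(self, dat_model):
        assert loop_charge(dat_model.scheme, mk.DAT_OUTER_LOOP) > 0

    def test_dat_transient_k_loop_electroneutral(self, dat_model):
        small = ["TiCl", "TiClK", "ToccClK", "ToccCl", "TiCl"]
        assert loop_charge(dat_model.scheme, small) == pytest.approx(0.0, abs=1e-12)


class TestThermodynamicConsistency:
    @pytest.mark.parametrize("builder", [
        mk.build_dat_model, mk.build_net_model, mk.build_sert_model,
    ])
    def test_every_cycle_balanced_at_collapsed_gradients(self, builder):
        """Wegscheider conditions: each fundamental cycle has zero total
        free energy when all gradients are collapsed at 0 mV."""
        model = builder()
        cond = collapsed_conditions(0.05)
        for cycle in independent_cycles(model.scheme):
            profile = loop_profile(model.scheme, cond, 0.0, cycle)
            assert abs(profile.total) < 1e-9


class TestConductingState:
    def test_conducting_state_is_a_small_perturbation(self, physiological):
        with_cond = mk.build_dat_model()
        without = mk.build_dat_model(with_conducting_state=False)
        p_with = mk.steady_state(with_cond.scheme, physiological, -0.06)
        p_without = mk.steady_state(without.scheme, physiological, -0.06)
        names = without.scheme.state_names
        p_cond = p_with[with_cond.scheme.state_index("Tcond")]
        for name in names:
            delta = abs(p_with[with_cond.scheme.state_index(name)]
                        - p_without[without.scheme.state_index(name)])
            assert delta <= p_cond + 1e-12


class TestVariantFlags:
    def test_unknown_variant_flag_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            mk.build_dat_model(with_wormhole=True)

    def test_sert_li_deadend_variant(self):
        model = mk.build_sert_model(with_li_deadend=True)
        assert "TiClLi" in model.scheme.state_names
        tr = model.scheme.find_transition("TiCl", "TiClLi")
        assert tr.ligand_fwd == ("Li", "in")

    def test_build_model_dispatch(self):
        assert mk.build_model("sert").transporter_id == "SERT"
        with pytest.raises(ValueError):
            mk.build_model("VMAT2")


class TestConditionPresets:
    def test_physiological_composition(self, physiological):
        assert physiological.get("K", "in") == pytest.approx(0.163)
        assert physiological.get("Na", "in") == pytest.approx(0.006)
        assert physiological.get("Na", "out") == pytest.approx(0.163)

    def test_nmdg_replaces_internal_cations(self):
        cond = mk.get_condition_preset("NMDG_in")
        assert cond.get("Na", "in") == 0.0
        assert cond.get("K", "in") == 0.0
        assert cond.get("Li", "in") == 0.0
        assert cond.get("Na", "out") == pytest.approx(0.163)

    def test_high_li_preset(self):
        assert mk.get_condition_preset("high_Li_in").get("Li", "in") == pytest.approx(0.163)

    def test_all_presets_share_external_sodium(self):
        for name in mk.CONDITION_PRESETS:
            assert mk.get_condition_preset(name).get("Na", "out") == pytest.approx(0.163)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            mk.get_condition_preset("martian")

    def test_acidic_preset_pH(self):
        cond = mk.get_condition_preset("pH5.6_in")
        assert cond.get("H", "in") == pytest.approx(10 ** -5.6)
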