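"""Packaged models and protocols behave as documented."""

import numpy as np
import pytest
import sympy as sp

from qssareduce import fixtures, integrate, oscillation_metrics
from qssareduce.model_core import make_symbol

S = make_symbol


class TestModelZoo:
    def test_sm_dimension_and_inputs(self, sm):
        assert sm.dim == 10
        assert sm.inputs == ["k24"]

    def test_every_zoo_entry_loads(self):
        for label, entry in fixtures.MODEL_ZOO.items():
            system = entry.load()
            assert system.dim in (4, 6, 10), label

    def test_minimal_continuous_dimensions(self):
        derived = fixtures.build_minimal_continuous()
        printed = fixtures.build_minimal_continuous(as_printed=True)
        assert derived.variables == ["q", "r", "u", "x"]
        assert printed.variables == ["q", "r", "u", "x"]
        assert derived.label == "z0p0y0v0s0w1"

    def test_minimal_pulsed_dimensions_and_wbar(self):
        system = fixtures.build_minimal_pulsed()
        assert system.variables == ["q", "r", "s", "u", "v", "x"]
        wbar = system.defs[S("wbar")]
        assert sp.simplify(wbar - S("k24") * S("k22") * S("v") / S("k23")) == 0

    def test_pulsed_typo_variants_differ_only_in_the_s_equation(self):
        fixed = fixtures.build_minimal_pulsed(fix_typo=True)
        printed = fixtures.build_minimal_pulsed(fix_typo=False)
        assert sp.simplify(fixed.flattened_rhs("q")
                           - printed.flattened_rhs("q")) == 0
        assert sp.simplify(fixed.flattened_rhs("s")
                           - printed.flattened_rhs("s")) != 0

    def test_active_ikk_decays_when_stimulus_is_off(self, sm):
        """With k24 = 0 the w equation is pure first-order decay."""
        rhs_off = sm.rhs["w"].subs(S("k24"), 0)
        assert sp.simplify(rhs_off - (-S("k23") * S("w"))) == 0

    def test_printed_minimal_sbar_matches_derivation(self):
        printed = fixtures.build_minimal_continuous(as_printed=True)
        sbar = printed.defs[S("sbar")]
        expected = S("k1") * S("k13") * S("q") / (
            S("k4") * S("r") + S("k1") * S("k14") + S("k8"))
        assert sp.simplify(sbar - expected) == 0


class TestProtocols:
    def test_continuous_is_a_saturating_constant(self):
        proto = fixtures.continuous_protocol()
        assert proto.value(0.0) == proto.value(1e5) == 1.0
        assert proto.edges(1e6) == []

    def test_pulse_train_duty_cycle(self):
        proto = fixtures.pulsed_protocol(n_pulses=3)
        assert proto.value(0.0) == 1.0
        assert proto.value(5 * 60.0) == 0.0
        assert proto.value(100 * 60.0) == 1.0
        on = sum(b - a for a, b, v in proto.segments if v == 1.0)
        assert on / (3 * 100 * 60.0) == pytest.approx(0.05)

    def test_pulse_edges_land_on_the_reporting_grid(self):
        proto = fixtures.pulsed_protocol(n_pulses=3)
        for e in proto.edges(300 * 60.0):
            assert e % 10.0 == 0.0


class TestDerivedBehaviour:
    def test_free_nfkb_reconstruction_stays_in_range(self, sm, sm_traj):
        """The complexed NF-kB implied by the conservation total,
        d = k3 - p - z - r/k1, stays within [0, k3] along the stimulated
        solution."""
        k1, k3 = sm.param_value("k1"), sm.param_value("k3")
        d = (k3 - sm_traj.series("p") - sm_traj.series("z")
             - sm_traj.series("r") / k1)
        assert d.min() >= -1e-9
        assert d.max() <= k3 + 1e-9

    def test_derived_minimal_model_oscillates_at_saturating_dose(self):
        system = fixtures.build_minimal_continuous()
        proto = fixtures.continuous_protocol()
        traj = integrate(system, system.initial_conditions, proto, 3000 * 60.0)
        met = oscillation_metrics(traj, "r", 1000 * 60.0)
        assert met.oscillatory

    def test_toy_tikhonov_reduces_to_plain_decay(self):
        from qssareduce import reduce_once

        toy = fixtures.build_toy_tikhonov(0.05)
        red = reduce_once(toy, "z", 0)
        assert sp.simplify(red.flattened_rhs("x") - (-S("x"))) == 0
        red1 = reduce_once(toy, "z", 1)
        expected = -(1 + S("eps")) * S("x")
        assert sp.simplify(red1.flattened_rhs("x") - expected) == 0
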