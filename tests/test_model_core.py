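"""Parsing, serialization, conservation elimination, decoupled variables."""

import numpy as np
import pytest
import sympy as sp

from qssareduce import (
    ModelParseError,
    ModelError,
    StimulusProtocol,
    drop_decoupled,
    eliminate_by_conservation,
    integrate,
    parse_model,
    serialize_model,
)
from qssareduce.model_core import make_symbol


def _toy(text):
    return parse_model(text)


class TestParsing:
    def test_sm_fixture_has_ten_variables(self, sm):
        assert sm.dim == 10
        assert sm.variables == list("pqrsuvwxyz")
        assert sm.inputs == ["k24"]
        assert sm.parameters["k23"].value == pytest.approx(0.003)

    def test_empty_model_rejected(self):
        with pytest.raises(ModelParseError, match="no variables"):
            parse_model("[variables]\n")

    def test_unknown_symbol_reported_by_name_and_line(self):
        text = "[variables]\nx\n\n[equations]\nx' = -x + foo\n"
        with pytest.raises(ModelParseError, match="foo") as err:
            parse_model(text)
        assert "line 5" in str(err.value)

    def test_duplicate_variable_rejected(self):
        with pytest.raises(ModelParseError, match="duplicate"):
            parse_model("[variables]\nx\nx\n\n[equations]\nx' = -x\n")

    def test_unparseable_expression_rejected(self):
        with pytest.raises(ModelParseError):
            parse_model("[variables]\nx\n\n[equations]\nx' = -x + (\n")

    @pytest.mark.parametrize("name", ["sm.model", "minimal_continuous_printed.model",
                                      "minimal_pulsed.model",
                                      "minimal_pulsed_printed.model"])
    def test_fixture_files_round_trip(self, name):
        from qssareduce.fixtures import load_fixture_text

        system = parse_model(load_fixture_text(name))
        again = parse_model(serialize_model(system))
        assert again.variables == system.variables
        for v in system.variables:
            diff = sp.simplify(system.flattened_rhs(v) - again.flattened_rhs(v))
            assert diff == 0, f"rhs of {v} changed in round trip"

    def test_reduced_model_round_trips(self, sm):
        from qssareduce import reduce_once

        z0 = reduce_once(sm, "z", 0)
        again = parse_model(serialize_model(z0))
        for v in z0.variables:
            assert sp.simplify(z0.flattened_rhs(v) - again.flattened_rhs(v)) == 0


class TestConservation:
    def test_non_conserved_total_rejected(self):
        toy = _toy("[variables]\nx\ny\n\n[equations]\nx' = y\ny' = -x\n")
        with pytest.raises(ModelError, match="not conserved"):
            eliminate_by_conservation(toy, "x + y", "y", constant=1.0)

    def test_symmetric_exchange_reduces_to_one_variable(self):
        toy = _toy("[variables]\nx\ny\n\n[parameters]\nkk = 1.0\nC = 2.0\n"
                   "\n[equations]\nx' = -kk*x + kk*y\ny' = kk*x - kk*y\n")
        red = eliminate_by_conservation(toy, "x + y", "y", constant="C")
        assert red.variables == ["x"]
        kk, C, x = map(make_symbol, ["kk", "C", "x"])
        assert sp.simplify(red.flattened_rhs("x") - (-kk*x + kk*(C - x))) == 0

    def test_victim_absent_from_total_rejected(self):
        toy = _toy("[variables]\nx\ny\n\n[equations]\nx' = -x + y\ny' = x - y\n")
        with pytest.raises(ModelError, match="does not appear"):
            eliminate_by_conservation(toy, "x", "y", constant=1.0)

    def test_ikk_subsystem_matches_published_structure(self):
        """Conserving v+w+a and removing a reproduces the printed neutral-IKK
        equation up to the pruned -k20*phi*w term."""
        text = """
[variables]
v = 0.08
w = 0.0
a = 0.0

[parameters]
k2 = 0.08
k20 = 0.0006
k21 = 0.0018
k22 = 0.004
k23 = 0.003
k24 = 1.0
y = 7.19e-4

[equations]
v' = k20*k21/(k21 + k24*y)*a - k24*k22*v
w' = k24*k22*v - k23*w
a' = k23*w - k20*k21/(k21 + k24*y)*a
"""
        sys3 = parse_model(text)
        red = eliminate_by_conservation(sys3, "v + w + a", "a", constant="k2")
        assert red.variables == ["v", "w"]
        k2, k20, k21, k22, k23, k24, y, v, w = map(
            make_symbol, ["k2", "k20", "k21", "k22", "k23", "k24", "y", "v", "w"])
        phi = k20 * k21 / (k21 + k24 * y)
        printed_fv = phi * (k2 - v) - k24 * k22 * v   # as published
        derived = red.flattened_rhs("v")
        # derived = printed minus the w term the publication pruned
        assert sp.simplify(derived - (printed_fv - phi * w)) == 0
        assert sp.simplify(derived - printed_fv) != 0

    def test_conservation_preserves_retained_trajectories(self):
        toy = _toy("[variables]\nx = 1.5\ny = 0.5\n\n[parameters]\nkk = 0.7\n"
                   "\n[equations]\nx' = -kk*x + kk*y\ny' = kk*x - kk*y\n")
        red = eliminate_by_conservation(toy, "x + y", "y")
        t_end = 20.0
        full = integrate(toy, toy.initial_conditions, None, t_end, step=0.5)
        part = integrate(red, {"x": 1.5}, None, t_end, step=0.5)
        assert np.max(np.abs(full.series("x") - part.series("x"))) < 1e-8


class TestDropDecoupled:
    def test_sink_variable_dropped(self):
        toy = _toy("[variables]\nx\nb\n\n[equations]\nx' = -x\nb' = x - b\n")
        red, dropped = drop_decoupled(toy)
        assert dropped == ["b"]
        assert red.variables == ["x"]

    def test_no_decoupled_variables_is_identity(self):
        toy = _toy("[variables]\nx\ny\n\n[equations]\nx' = -y\ny' = x\n")
        red, dropped = drop_decoupled(toy)
        assert dropped == []
        assert red.variables == ["x", "y"]

    def test_chain_dropped_to_fixpoint(self):
        toy = _toy("[variables]\nx\nb1\nb2\n\n[equations]\n"
                   "x' = -x\nb1' = x - b1\nb2' = b1 - b2\n")
        red, dropped = drop_decoupled(toy)
        assert dropped == ["b2", "b1"]
        assert red.variables == ["x"]

    def test_retained_solution_unchanged(self):
        toy = _toy("[variables]\nx = 2.0\nb = 0.0\n\n[equations]\n"
                   "x' = -0.3*x\nb' = x - b\n")
        red, _ = drop_decoupled(toy)
        full = integrate(toy, toy.initial_conditions, None, 10.0, step=0.5,
                         rtol=1e-11, atol=1e-14)
        part = integrate(red, {"x": 2.0}, None, 10.0, step=0.5,
                         rtol=1e-11, atol=1e-14)
        assert np.max(np.abs(full.series("x") - part.series("x"))) < 1e-9


class TestProtocol:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ModelError, match="overlap"):
            StimulusProtocol("k24", 0.0, [(0, 10, 1.0), (5, 15, 1.0)])

    def test_value_is_start_inclusive_end_exclusive(self):
        p = StimulusProtocol("k24", 0.0, [(60.0, 360.0, 1.0)])
        assert p.value(59.9) == 0.0
        assert p.value(60.0) == 1.0
        assert p.value(359.9) == 1.0
        assert p.value(360.0) == 0.0

    def test_period_hint_for_regular_trains(self):
        from qssareduce.fixtures import pulsed_protocol

        assert pulsed_protocol(5).period_hint() == pytest.approx(6000.0)
        assert StimulusProtocol("k24", 1.0).period_hint() is None
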