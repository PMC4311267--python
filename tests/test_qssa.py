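"""Affine decomposition, QSSA substitutions and the reduction loop."""

import numpy as np
import pytest
import sympy as sp

from qssareduce import (
    affine_decompose,
    compare_models,
    parse_model,
    qssa_expression,
    reduce_iteratively,
    reduce_once,
    total_time_derivative,
)
from qssareduce.model_core import ModelError, make_symbol
from qssareduce.qssa import compare_trajectories
from helpers import loglog_slope, tikhonov_reduction_error

S = make_symbol


class TestAffineDecompose:
    def test_quadratic_rhs_rejected(self):
        toy = parse_model("[variables]\nx\n\n[equations]\nx' = x**2\n")
        with pytest.raises(ModelError, match="not affine"):
            affine_decompose(toy, "x")

    def test_vanishing_decay_coefficient_rejected(self):
        toy = parse_model("[variables]\nx\n\n[parameters]\nkk = 1.0\n"
                          "\n[equations]\nx' = kk\n")
        with pytest.raises(ModelError, match="identically zero"):
            affine_decompose(toy, "x")

    def test_nuclear_ikba_decomposition(self, sm):
        """s' = k13*k1*q - (k4*r + k8 + k14*k1)*s in the full model."""
        pair = affine_decompose(sm, "s")
        assert sp.simplify(pair.alpha - S("k13") * S("k1") * S("q")) == 0
        beta_expected = S("k4") * S("r") + S("k8") + S("k14") * S("k1")
        assert sp.simplify(pair.beta - beta_expected) == 0

    def test_nuclear_complex_decomposition(self, sm):
        """z' = k18*w*(k3 - p - r/k1) - k19*z."""
        pair = affine_decompose(sm, "z")
        alpha_expected = S("k18") * S("w") * (S("k3") - S("p") - S("r") / S("k1"))
        assert sp.simplify(pair.alpha - alpha_expected) == 0
        assert sp.simplify(pair.beta - S("k19")) == 0


class TestTotalTimeDerivative:
    def test_constant_has_zero_derivative(self, sm):
        assert total_time_derivative(sp.Integer(3), sm) == 0
        assert total_time_derivative(S("k5"), sm) == 0

    def test_derivative_of_a_variable_is_its_rhs(self, sm):
        d = total_time_derivative(S("x"), sm)
        assert sp.simplify(d - sm.rhs["x"]) == 0

    def test_chain_rule_through_nonlinear_function(self):
        toy = parse_model("[variables]\nx\n\n[equations]\nx' = -x\n")
        d = total_time_derivative(S("x") ** 2, toy)
        assert sp.simplify(d - (-2 * S("x") ** 2)) == 0

    def test_unresolved_symbol_rejected(self, sm):
        with pytest.raises(ModelError, match="unresolved"):
            total_time_derivative(S("nonexistent"), sm)


class TestQSSAExpressions:
    def test_constant_coefficients_make_the_correction_vanish(self):
        toy = parse_model("[variables]\nx\ny\n\n[parameters]\naa = 2.0\n"
                          "bb = 3.0\n\n[equations]\nx' = -x + y\n"
                          "y' = aa - bb*y\n")
        pair = affine_decompose(toy, "y")
        sub0 = qssa_expression(pair, 0, toy)
        sub1 = qssa_expression(pair, 1, toy)
        assert sp.simplify(sub0.expression - S("aa") / S("bb")) == 0
        assert sp.simplify(sub1.expression - sub0.expression) == 0

    def test_nuclear_ikba_substitution_matches_published_form(self, sm):
        """sbar(q, r) = k1*k13*q / (k4*r + k1*k14 + k8) in the 6-variable
        continuous-lineage model."""
        system = sm
        for var in ("z", "p", "y", "v"):
            system = reduce_once(system, var, 0)
        sbar = reduce_once(system, "s", 0).substitution_expression("s")
        expected = S("k1") * S("k13") * S("q") / (
            S("k4") * S("r") + S("k1") * S("k14") + S("k8"))
        assert sp.simplify(sbar - expected) == 0

    def test_cytoplasmic_nfkb_substitution_matches_published_form(self, sm):
        """pbar = (k16*r + k18*w*(k3 - r/k1)) / (k4*q + k15 + k18*w) after
        removing z (w still dynamic at that stage; the published final form
        has its own substitution in place of w)."""
        z0 = reduce_once(sm, "z", 0)
        pbar = reduce_once(z0, "p", 0).substitution_expression("p")
        w, q, r = S("w"), S("q"), S("r")
        expected = (S("k16") * r + S("k18") * w * (S("k3") - r / S("k1"))) / (
            S("k4") * q + S("k15") + S("k18") * w)
        assert sp.simplify(pbar - expected) == 0


class TestReduceOnce:
    def test_dimension_drops_by_one(self, sm):
        assert reduce_once(sm, "z", 0).dim == sm.dim - 1

    def test_unknown_variable_rejected(self, sm):
        with pytest.raises(ModelError, match="not a dynamic variable"):
            reduce_once(sm, "nope", 0)

    def test_lineage_labels_follow_the_subscript_convention(self, sm):
        z0 = reduce_once(sm, "z", 0)
        assert z0.label == "z0"
        assert reduce_once(z0, "p", 1).label == "z0p1"

    def test_first_elimination_is_visually_indistinguishable(
            self, lineage_continuous):
        """Removing the fast nuclear complex at zeroth order leaves the
        solution essentially unchanged."""
        step = lineage_continuous.steps[0]
        assert step.variable == "z"
        assert step.vs_parent.period_fold == pytest.approx(1.0, abs=0.01)
        assert step.vs_parent.max_pointwise_dev < 2e-3
        assert step.vs_parent.shape_mse < 1e-6


class TestCompare:
    def test_model_against_itself_is_a_fixed_point(self, sm_traj):
        rec = compare_trajectories(sm_traj, sm_traj)
        assert rec.period_fold == pytest.approx(1.0)
        assert rec.amplitude_fold == pytest.approx(1.0)
        assert rec.shape_mse == 0.0
        assert rec.max_pointwise_dev == 0.0

    def test_variables_must_nest(self, sm):
        z0 = reduce_once(sm, "z", 0)
        with pytest.raises(ModelError, match="absent"):
            compare_models(z0, sm)


class TestReduceIteratively:
    def test_zero_steps_returns_root_only(self, sm, continuous):
        lineage = reduce_iteratively(sm, continuous, n_steps=0)
        assert lineage.steps == []
        assert lineage.final is sm
        assert lineage.root_metrics.oscillatory

    def test_too_many_steps_rejected(self, sm, continuous):
        with pytest.raises(ModelError, match="cannot remove"):
            reduce_iteratively(sm, continuous, n_steps=10)

    def test_metrics_table_lists_every_model(self, lineage_continuous):
        csv = lineage_continuous.metrics_csv()
        lines = csv.strip().splitlines()
        assert len(lines) == 2 + len(lineage_continuous.steps)
        assert lines[1].startswith("SM,")


class TestTikhonovScaling:
    """Convergence of the QSSA on the linear fast-slow toy.

    The reduction error of the slow variable scales like eps at zeroth
    order and like eps^2 at first order (log-log slopes 1 and 2).
    """

    epsilons = [1e-1, 1e-2, 1e-3]

    def test_zeroth_order_error_scales_linearly(self):
        errs = [tikhonov_reduction_error(e, 0) for e in self.epsilons]
        assert abs(loglog_slope(self.epsilons, errs) - 1.0) < 0.2

    def test_first_order_error_scales_quadratically(self):
        errs = [tikhonov_reduction_error(e, 1) for e in self.epsilons]
        assert abs(loglog_slope(self.epsilons, errs) - 2.0) < 0.2

    def test_first_order_beats_zeroth_order(self):
        for e in self.epsilons:
            assert tikhonov_reduction_error(e, 1) < tikhonov_reduction_error(e, 0)
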