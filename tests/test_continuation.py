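"""Equilibrium solving, stability, branch continuation and bifurcations."""

import numpy as np
import pytest

from lhigp import (classify_equilibrium, continue_branch, find_attractor,
                   invasion_fitness_R0, invasion_growth, jacobian_eigenvalues,
                   solve_equilibrium, two_parameter_map)
from lhigp.continuation import EquilibriumError, InconsistentStageError
from lhigp.scenarios import default_parameters

from conftest import CR_C, CR_R


class TestSolveEquilibrium:
    def test_resource_only(self, params):
        eq = solve_equilibrium([1.0, 0, 0, 0], params(a_jr=4.0),
                               absent={"C", "Pj", "Pa"})
        assert eq.R == pytest.approx(3.0, abs=1e-12)
        assert eq.label == "R"

    def test_cr_closed_form(self, params):
        eq = solve_equilibrium([0.5, 0.5, 0, 0], params(a_jr=4.0),
                               absent={"Pj", "Pa"})
        assert eq.R == pytest.approx(CR_R, abs=1e-10)
        assert eq.C == pytest.approx(CR_C, abs=1e-10)
        assert eq.residual_norm < 1e-10

    def test_pcr_all_positive(self, pcr_equilibrium):
        eq = pcr_equilibrium
        assert eq.label == "PCR"
        assert np.all(eq.state > 0)
        assert eq.residual_norm < 1e-10
        assert eq.stable

    def test_negative_density_rejected(self, params):
        # below the consumer persistence threshold (R_max < R*_C) the
        # consumer-resource algebra only balances at negative C
        with pytest.raises(EquilibriumError, match="negative"):
            solve_equilibrium([0.3, 0.5, 0, 0], params(a_jr=4.0, R_max=0.2),
                              absent={"Pj", "Pa"})

    def test_r_equilibrium_consumer_invasion_eigenvalue(self, params):
        """The resource-only state is always consumer-invadable at R_max=3."""
        eq = solve_equilibrium([3.0, 0, 0, 0], params(a_jr=4.0),
                               absent={"C", "Pj", "Pa"})
        ev = jacobian_eigenvalues(eq)
        # nu_c(R_max) - mu_c = 0.5*(10*3/4) - 1 - 0.1 = +2.65
        assert ev[0].real == pytest.approx(2.65, abs=1e-6)
        assert not eq.stable

    def test_cr_stable_at_low_trait(self, params):
        eq = solve_equilibrium([0.3, 1.2, 0, 0], params(a_jr=3.0),
                               absent={"Pj", "Pa"})
        assert eq.stable
        assert np.max(eq.eigenvalues.real) < 0


class TestClassification:
    @pytest.mark.parametrize("state, label", [
        ([3.0, 0, 0, 0], "R"),
        ([CR_R, CR_C, 0, 0], "CR"),
        ([0.3, 0, 0.5, 0.5], "PR"),
        ([0.5, 0.5, 0.2, 0.4], "PCR"),
    ])
    def test_labels(self, state, label):
        assert classify_equilibrium(state) == label

    def test_single_stage_is_inconsistent(self):
        with pytest.raises(InconsistentStageError):
            classify_equilibrium([1.0, 0.5, 0.4, 0.0])


@pytest.fixture(scope="module")
def cr_branch():
    p = default_parameters(a_jr=0.0, a_ar=0.0, beta=0.0)
    eq = solve_equilibrium([0.3, 1.2, 0, 0], p, absent={"Pj", "Pa"})
    return continue_branch(eq, "a_jr", 0.0, 6.0, ds0=0.02, ds_max=0.1)


@pytest.fixture(scope="module")
def pcr_branch():
    p = default_parameters(a_jr=4.5, a_ar=0.0, beta=0.0)
    rep = find_attractor(np.array([1.5, 0.5, 0.3, 0.3]), p)
    return continue_branch(rep.equilibrium, "a_jr", 0.0, 6.0,
                           ds0=0.01, ds_max=0.05, direction=-1)


class TestBranches:
    def test_cr_branch_matches_closed_form_everywhere(self, cr_branch):
        """The consumer-resource state is independent of the predator trait."""
        df = cr_branch.to_frame()
        np.testing.assert_allclose(df["R"], CR_R, atol=1e-8)
        np.testing.assert_allclose(df["C"], CR_C, atol=1e-8)
        assert df["param"].iloc[-1] == pytest.approx(6.0)

    def test_cr_branch_invasion_boundaries(self, cr_branch):
        """Predator invasion opens and closes a window of CR instability."""
        bps = [b for b in cr_branch.bifurcations if b.kind == "invasion_boundary"]
        assert len(bps) == 2
        lo, hi = sorted(b.value for b in bps)
        assert 3.5 < lo < 4.0 and 5.0 < hi < 5.5
        df = cr_branch.to_frame()
        below = df[df["param"] < lo - 0.05]
        inside = df[(df["param"] > lo + 0.05) & (df["param"] < hi - 0.05)]
        above = df[df["param"] > hi + 0.05]
        assert below["stable"].all() and above["stable"].all()
        assert not inside["stable"].any()

    def test_pcr_branch_residuals(self, pcr_branch):
        assert max(eq.residual_norm for eq in pcr_branch.points) < 1e-8

    def test_pcr_branch_turns_at_fold(self, pcr_branch):
        """The coexistence branch has a fold marking minimum predator trait."""
        folds = [b for b in pcr_branch.bifurcations if b.kind == "fold"]
        assert len(folds) == 1
        fold = folds[0]
        assert 0.0 < fold.value < 3.55
        assert fold.value == pytest.approx(min(pcr_branch.param_values), abs=1e-3)
        # defining property: one Jacobian eigenvalue crosses zero at the fold
        ev = fold.equilibrium.eigenvalues
        assert np.min(np.abs(ev.real)) < 1e-6

    def test_pcr_branch_ends_on_cr_at_transcritical(self, cr_branch, pcr_branch):
        """The coexistence branch terminates where the predator density
        vanishes, exactly at the CR invasion boundary."""
        assert pcr_branch.termination == "component_extinct"
        end = pcr_branch.points[-1]
        cr_lo = min(b.value for b in cr_branch.bifurcations
                    if b.kind == "invasion_boundary")
        assert end.params.a_jr == pytest.approx(cr_lo, abs=1e-4)
        assert end.R == pytest.approx(CR_R, abs=1e-5)

    def test_transcritical_matches_R0_root(self, cr_branch):
        """The eigenvalue-based invasion boundary equals the root of the
        mutant lifetime reproductive success R0 = 1 (algebraic identity)."""
        from scipy.optimize import brentq
        p = default_parameters(a_jr=4.0, a_ar=0.0, beta=0.0)
        eq_cr = solve_equilibrium([0.3, 1.2, 0, 0], p, absent={"Pj", "Pa"})
        root = brentq(lambda y: invasion_fitness_R0(y, eq_cr) - 1.0, 3.6, 4.0,
                      xtol=1e-10)
        boundary = min(b.value for b in cr_branch.bifurcations
                       if b.kind == "invasion_boundary")
        assert root == pytest.approx(boundary, abs=1e-4)

    def test_invasion_growth_sign_agrees_with_stability(self, cr_branch):
        for eq in cr_branch.points[:: max(1, len(cr_branch.points) // 10)]:
            g = invasion_growth(eq, "P")
            assert (g < 0) == eq.stable or abs(g) < 1e-7


class TestTwoParameterMap:
    def test_diet_shift_rows(self):
        """Bistable CR+PCR band without cannibalism; with cannibalism the
        predator only persists at high juvenile specialization."""
        p = default_parameters(a_jr=4.0, a_ar=0.0, beta=0.0)
        table = two_parameter_map(p, "a_jr", "beta", [3.0, 4.5], [0.0, 1.0],
                                  seed=3)
        cell = lambda x, b: table[(table.a_jr == x) & (table.beta == b)].iloc[0]
        assert cell(3.0, 0.0)["classes"] == "CR+PCR"       # bistability
        assert cell(4.5, 0.0)["classes"] == "PCR"
        assert "PCR:-" in cell(4.5, 0.0)["gradient_sign"]  # selection downward
        assert cell(3.0, 1.0)["classes"] == "CR"           # cannibalism removes
        assert "+" in cell(4.5, 1.0)["gradient_sign"]      # selection upward
        assert not table["undecided"].any()

    def test_superior_predator_cell(self):
        """With a_ar=4 the fully juvenile-specialized predator holds a
        stable PR state and no CR alternative exists."""
        p = default_parameters(a_jr=4.0, a_ar=4.0, beta=0.0)
        table = two_parameter_map(p, "a_jr", "beta", [6.0], [0.0],
                                  seed=3, gradient_signs=False)
        assert table.iloc[0]["classes"] == "PR"
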