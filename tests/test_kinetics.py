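import math

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import KB, KF_EXPR
from ecsrd.kinetics import (
    RateTerm,
    Reaction,
    ReactionSystem,
    Species,
    numerical_jacobian,
    parse_rate_expression,
)

NAMES = ["k", "A", "AK"]

conc_floats = st.floats(0.0, 50.0, allow_nan=False)


class TestParseRateExpression:
    def test_sigmoidal_uptake_at_threshold(self):
        kf = parse_rate_expression(KF_EXPR, NAMES)
        # at [K] = threshold the sigmoid is exactly 1/2
        assert kf({"k": 15.0, "A": 0.0, "AK": 0.0}) == pytest.approx(
            0.0004, abs=1e-15
        )

    def test_sigmoidal_uptake_saturates_at_kb(self):
        kf = parse_rate_expression(KF_EXPR, NAMES)
        assert kf({"k": 1000.0, "A": 0.0, "AK": 0.0}) == pytest.approx(
            KB, abs=1e-12
        )

    def test_constant_leaf(self):
        expr = parse_rate_expression("3.5", NAMES)
        assert expr({"k": 1.0, "A": 2.0, "AK": 3.0}) == 3.5

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            parse_rate_expression("k * glutamate", NAMES)

    def test_malformed_syntax_rejected(self):
        with pytest.raises(ValueError):
            parse_rate_expression("k ++* 2)", NAMES)

    @settings(max_examples=100, derandomize=True)
    @given(conc_floats, conc_floats, conc_floats)
    def test_matches_independent_math_evaluation(self, k, a, ak):
        """Compiled evaluation agrees with scalar math-library evaluation
        of the same tree to near machine precision."""
        kf = parse_rate_expression(KF_EXPR, NAMES)
        ours = float(kf({"k": k, "A": a, "AK": ak}))
        ref = KB / (1.0 + math.exp(-(k - 15.0) / 1.15))
        assert ours == pytest.approx(ref, rel=1e-14, abs=1e-300)

    def test_vectorized_over_voxels(self):
        kf = parse_rate_expression(KF_EXPR, NAMES)
        conc = np.zeros((3, 4, 5))
        conc[0] = 15.0
        out = kf(conc)
        assert out.shape == (4, 5)
        assert np.allclose(out, 0.0004)


class TestReactionRate:
    @pytest.fixture
    def system(self, buffer_reaction):
        return ReactionSystem(NAMES, [buffer_reaction])

    def test_zero_concentration_annihilates_forward(self, system):
        assert system.reaction_rate(0, np.array([0.0, 0.0, 0.0])) == 0.0
        assert system.reaction_rate(0, np.array([0.0, 5.0, 0.0])) == 0.0

    def test_printed_constants_forward_rate(self, system):
        """kf(3.5)*3.5*10 with the published sigmoid constants."""
        rate = system.reaction_rate(0, np.array([3.5, 10.0, 0.0]))
        kf = KB / (1.0 + math.exp((15.0 - 3.5) / 1.15))
        assert rate == pytest.approx(kf * 3.5 * 10.0, rel=1e-12)
        assert rate == pytest.approx(1.27e-6, rel=0.01)

    def test_reverse_only_releases(self, system):
        rate = system.reaction_rate(0, np.array([0.0, 0.0, 1.0]))
        assert rate == pytest.approx(-KB, abs=1e-18)

    def test_non_mass_action_is_rate_difference(self):
        rx = Reaction("k", "AK", "0.01", "0.004", mass_action=False)
        system = ReactionSystem(NAMES, [rx])
        # rates are taken as full rates regardless of concentrations
        assert system.reaction_rate(0, np.array([7.0, 1.0, 9.0])) == \
            pytest.approx(0.006)

    @settings(max_examples=50, derandomize=True)
    @given(conc_floats, conc_floats, st.floats(0.1, 4.0))
    def test_mass_action_multilinear_in_lhs(self, k, a, scale):
        """With units-1 stoichiometry the forward product is linear in each
        reactant separately."""
        system = ReactionSystem(NAMES, [Reaction("k + A", "AK", 0.002, 0.0)])
        base = system.reaction_rate(0, np.array([k, a, 0.0]))
        scaled = system.reaction_rate(0, np.array([k * scale, a, 0.0]))
        assert scaled == pytest.approx(scale * base, rel=1e-12, abs=1e-300)

    def test_stoichiometric_power(self):
        system = ReactionSystem(NAMES, [Reaction({"k": 2}, {"AK": 1}, 1.0, 0.0)])
        assert system.reaction_rate(0, np.array([3.0, 0.0, 0.0])) == 9.0

    def test_rejects_non_integer_stoichiometry(self):
        with pytest.raises(ValueError, match="positive integer"):
            Reaction({"k": 0.5}, "AK", 1.0, 0.0)


class TestReactionRhs:
    def test_no_reactions_zero(self):
        system = ReactionSystem(NAMES)
        assert np.all(system.rhs(np.array([1.0, 2.0, 3.0])) == 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(conc_floats, conc_floats, conc_floats)
    def test_sign_pattern_of_buffer_system(self, k, a, ak):
        """d[k]/dt = d[A]/dt = -rate and d[AK]/dt = +rate, exactly."""
        system = ReactionSystem(NAMES, [Reaction("k + A", "AK", KF_EXPR, KB)])
        conc = np.array([k, a, ak])
        rate = system.reaction_rate(0, conc)
        rhs = system.rhs(conc)
        assert rhs[0] == -rate and rhs[1] == -rate and rhs[2] == rate

    @settings(max_examples=50, derandomize=True)
    @given(conc_floats, conc_floats, conc_floats)
    def test_linear_invariants_conserved_pointwise(self, k, a, ak):
        """d([K]+[AK])/dt = 0 and d([A]+[AK])/dt = 0 at every state, with
        exact floating-point cancellation."""
        system = ReactionSystem(NAMES, [Reaction("k + A", "AK", KF_EXPR, KB)])
        rhs = system.rhs(np.array([k, a, ak]))
        assert rhs[0] + rhs[2] == 0.0
        assert rhs[1] + rhs[2] == 0.0

    def test_duplicate_reaction_doubles(self):
        rx = Reaction("k + A", "AK", KF_EXPR, KB)
        one = ReactionSystem(NAMES, [rx]).rhs(np.array([20.0, 5.0, 1.0]))
        two = ReactionSystem(NAMES, [rx, rx]).rhs(np.array([20.0, 5.0, 1.0]))
        assert np.allclose(two, 2 * one, rtol=1e-15)

    def test_rate_terms_add(self):
        system = ReactionSystem(NAMES, rate_terms=[RateTerm("k", "-0.1*k")])
        rhs = system.rhs(np.array([2.0, 0.0, 0.0]))
        assert rhs[0] == pytest.approx(-0.2) and rhs[1] == 0.0

    def test_participating_species_tracked(self):
        system = ReactionSystem(
            ["na"] + NAMES, [Reaction("k + A", "AK", KF_EXPR, KB)]
        )
        assert system.participating == NAMES


class TestNumericalJacobian:
    def test_no_reactions_zero_matrix(self):
        system = ReactionSystem(NAMES)
        J = system.jacobian(np.array([1.0, 1.0, 1.0]))
        assert np.all(J == 0.0)

    def test_linear_decay_matches_analytic(self):
        system = ReactionSystem(["s"], rate_terms=[RateTerm("s", "-0.1*s")])
        J = system.jacobian(np.array([1.0]))
        assert J[0, 0] == pytest.approx(-0.1, abs=1e-6)

    def test_buffer_release_partial(self):
        """d(d[AK]/dt)/d[AK] = -kb for the sigmoidal buffer system."""
        system = ReactionSystem(NAMES, [Reaction("k + A", "AK", KF_EXPR, KB)])
        J = system.jacobian(np.array([10.0, 4.0, 2.0]))
        assert J[2, 2] == pytest.approx(-KB, rel=1e-5)

    def test_matches_symbolic_jacobian(self):
        """Finite differences track the sympy-differentiated Jacobian on the
        full 3x3 system."""
        system = ReactionSystem(NAMES, [Reaction("k + A", "AK", KF_EXPR, KB)])
        conc = np.array([12.0, 6.0, 3.0])
        J = system.jacobian(conc)
        k, a, ak = sp.symbols("k A AK")
        kf = KB / (1 + sp.exp(-(k - 15.0) / 1.15))
        rate = kf * k * a - KB * ak
        rhs_sym = [-rate, -rate, rate]
        for i in range(3):
            for j, s in enumerate((k, a, ak)):
                exact = float(sp.diff(rhs_sym[i], s).subs(
                    {k: conc[0], a: conc[1], ak: conc[2]}
                ))
                assert J[i, j] == pytest.approx(exact, rel=1e-4, abs=1e-9)

    def test_nonfinite_state_rejected(self):
        system = ReactionSystem(["s"], rate_terms=[RateTerm("s", "1/s")])
        with pytest.raises(FloatingPointError):
            numerical_jacobian(system.rhs, np.array([0.0]))


class TestSpecies:
    def test_rejects_negative_diffusion(self):
        with pytest.raises(ValueError):
            Species("k", d=-1.0)

    def test_rejects_bad_boundary_string(self):
        with pytest.raises(ValueError):
            Species("k", boundary="periodic")

    def test_dirichlet_boundary_coerced_to_float(self):
        assert Species("k", boundary=3).boundary == 3.0

    def test_anisotropic_tuple(self):
        assert Species("k", d=(1, 2, 3)).d_tuple == (1.0, 2.0, 3.0)

    def test_rejects_invalid_identifier(self):
        with pytest.raises(ValueError):
            Species("2k")
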