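"""Unit and closed-form tests for the individual measures."""

import numpy as np
import pytest

from iintegrate import (ARSystem, Partition, avg_abs_correlation, build_model,
                        causal_density, cd_measure, effective_info_phi,
                        effective_info_phi_star, effective_info_phi_tilde,
                        effective_info_psi, i_tilde_beta, multi_information,
                        phi_g, phi_g_measure, phi_star, phi_tilde, phi_wms,
                        psi, tdmi, transfer_entropy, two_node,
                        union_information_mmi)
from iintegrate.networks import random_stable_system

P2 = Partition([(0,), (1,)])


def decoupled_pairs_model(a_within=0.4, rho_noise=0.0):
    """Two internally coupled pairs with no interaction between pairs."""
    a = np.array([[0.2, a_within], [a_within, 0.2]])
    A = np.block([[a, np.zeros((2, 2))], [np.zeros((2, 2)), a]])
    eps = np.eye(4)
    eps[0, 1] = eps[1, 0] = rho_noise
    eps[2, 3] = eps[3, 2] = rho_noise
    return build_model(ARSystem(A, eps))


SEPARATING = Partition([(0, 1), (2, 3)])


class TestTDMI:
    def test_white_noise_carries_no_information(self):
        model = build_model(ARSystem(np.zeros((2, 2)), np.eye(2)))
        assert tdmi(model) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_closed_form(self):
        # 1-D, a = 0.5, unit noise: Σ = 4/3, TDMI = ½ log(Σ/Σ(ε))
        model = build_model(ARSystem([[0.5]], [[1.0]]))
        assert tdmi(model) == pytest.approx(0.5 * np.log(4.0 / 3.0))

    def test_invariant_to_noise_correlation(self):
        vals = [tdmi(build_model(two_node(0.4, c)))
                for c in (0.0, 0.3, 0.6, 0.9)]
        assert np.ptp(vals) < 1e-9


class TestAvgAbsCorrelation:
    def test_diagonal_covariance_gives_zero(self):
        model = build_model(ARSystem(np.zeros((2, 2)), np.diag([1.0, 3.0])))
        assert avg_abs_correlation(model) == 0.0

    def test_two_node_is_the_single_correlation(self):
        model = build_model(two_node(0.4, 0.5))
        expected = model.sigma_x[0, 1] / model.sigma_x[0, 0]
        assert avg_abs_correlation(model) == pytest.approx(abs(expected))

    def test_increases_with_noise_correlation(self):
        vals = [avg_abs_correlation(build_model(two_node(0.4, c)))
                for c in np.arange(0.0, 1.0, 0.1)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestPhi:
    def test_decoupled_parts_give_zero(self):
        assert effective_info_phi(decoupled_pairs_model(), SEPARATING) == \
            pytest.approx(0.0, abs=1e-10)

    def test_negative_under_strong_noise_correlation(self):
        model = build_model(two_node(0.4, 0.9))
        assert phi_wms(model).value < 0

    def test_bounded_by_tdmi(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            model = build_model(random_stable_system(4, rng))
            assert phi_wms(model).value <= tdmi(model) + 1e-9


class TestPhiTilde:
    def test_decoupled_independent_parts_give_zero(self):
        assert effective_info_phi_tilde(decoupled_pairs_model(), SEPARATING) \
            == pytest.approx(0.0, abs=1e-10)

    def test_decomposes_into_phi_plus_multi_information(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            model = build_model(random_stable_system(4, rng))
            for p in (SEPARATING, Partition([(0, 2), (1, 3)])):
                lhs = effective_info_phi_tilde(model, p)
                rhs = (effective_info_phi(model, p)
                       + multi_information(model, p))
                assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_growth_with_noise_correlation(self):
        # φ̃(c) at a=0.4 has a shallow interior minimum near c ≈ 0.1, then
        # increases steeply and diverges as c → 1
        grid = np.arange(0.15, 1.0, 0.05)
        vals = [phi_tilde(build_model(two_node(0.4, c))).value for c in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        v0 = phi_tilde(build_model(two_node(0.4, 0.0))).value
        v99 = phi_tilde(build_model(two_node(0.4, 0.99))).value
        assert v99 > 5 * v0


class TestPhiTildeRescaling:
    def test_unnormalised_scheme_is_exactly_rescaling_invariant(self):
        # per partition, the log|det D| contributions of whole and parts
        # cancel, so φ̃ under the unnormalised scan cannot change
        rng = np.random.default_rng(31)
        for _ in range(10):
            sys = random_stable_system(4, rng)
            d = rng.uniform(0.5, 2.0, size=4)
            D, Dinv = np.diag(d), np.diag(1.0 / d)
            rescaled = ARSystem(D @ sys.A @ Dinv, D @ sys.sigma_eps @ D)
            v = phi_tilde(build_model(sys)).value
            vr = phi_tilde(build_model(rescaled)).value
            assert vr == pytest.approx(v, abs=1e-9)


class TestPhiGTimeSymmetry:
    def test_projection_depends_on_time_direction(self):
        # the severed-links constraint conditions future on past; the
        # projection of the time-reversed model can genuinely differ
        rng = np.random.default_rng(20260)
        devs = []
        for _ in range(30):
            sys = random_stable_system(4, rng)
            model = build_model(sys)
            devs.append(abs(phi_g_measure(model).value
                            - phi_g_measure(model.time_reversed()).value))
        assert max(devs) > 1e-4


class TestMultiInformation:
    def test_independent_parts_give_zero(self):
        assert multi_information(decoupled_pairs_model(), SEPARATING) == \
            pytest.approx(0.0, abs=1e-10)

    def test_bivariate_closed_form(self):
        model = build_model(two_node(0.4, 0.5))
        rho = model.sigma_x[0, 1] / model.sigma_x[0, 0]
        assert multi_information(model, P2) == \
            pytest.approx(-0.5 * np.log(1 - rho**2))

    def test_nonnegative_on_random_systems(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            model = build_model(random_stable_system(4, rng))
            assert multi_information(model, SEPARATING) > -1e-10


class TestPsi:
    def test_fully_informative_part_gives_zero(self):
        # part 1 drives everything; part 2 is exogenous white noise
        A = np.array([[0.5, 0.0], [0.4, 0.0]])
        model = build_model(ARSystem(A, np.eye(2)))
        # the union information from part {0}'s past reaches full TDMI
        # only if node 0's past determines the whole prediction; here the
        # present of both nodes depends on node 0's past alone
        assert effective_info_psi(model, P2) == pytest.approx(0.0, abs=1e-10)

    def test_bounds(self):
        rng = np.random.default_rng(24)
        for _ in range(20):
            model = build_model(random_stable_system(4, rng))
            val = psi(model).value
            assert -1e-9 <= val <= tdmi(model) + 1e-9

    def test_union_information_is_max_over_parts(self):
        model = build_model(two_node(0.4, 0.3))
        from iintegrate import gaussian_mi, partial_covariance
        parts = []
        for idx in ([0], [1]):
            s = model.sigma_x[np.ix_(idx, idx)]
            cross = model.sigma_lag[idx, :]
            parts.append(gaussian_mi(
                s, partial_covariance(s, cross, model.sigma_x)))
        assert union_information_mmi(model, P2) == pytest.approx(max(parts))

    def test_vanishes_as_noise_correlation_saturates(self):
        vals = [psi(build_model(two_node(0.4, c))).value
                for c in (0.0, 0.5, 0.9, 0.99)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.01


class TestMismatchedDecoding:
    def test_beta_zero_gives_zero_information(self):
        model = build_model(two_node(0.4, 0.5))
        assert i_tilde_beta(model, P2, 0.0).i_tilde == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_matched_decoder_attains_tdmi(self):
        model = decoupled_pairs_model(rho_noise=0.3)
        state = i_tilde_beta(model, SEPARATING, 1.0)
        assert state.i_tilde == pytest.approx(tdmi(model), abs=1e-10)

    def test_bounded_by_tdmi(self):
        model = build_model(two_node(0.4, 0.5))
        full = tdmi(model)
        for beta in (0.0, 0.5, 1.0, 1.5, 2.0):
            assert i_tilde_beta(model, P2, beta).i_tilde <= full + 1e-10

    def test_concave_unimodal_on_grid(self):
        rng = np.random.default_rng(25)
        betas = np.linspace(0.0, 2.0, 41)
        for _ in range(20):
            model = build_model(random_stable_system(2, rng))
            vals = np.array([i_tilde_beta(model, P2, b).i_tilde
                             for b in betas])
            second_diff = np.diff(vals, 2)
            assert (second_diff <= 1e-9).all()


class TestPhiStar:
    def test_decoupling_partition_gives_zero(self):
        model = decoupled_pairs_model(rho_noise=0.2)
        assert effective_info_phi_star(model, SEPARATING) == \
            pytest.approx(0.0, abs=1e-9)

    def test_decreases_toward_zero_with_noise_correlation(self):
        vals = [phi_star(build_model(two_node(0.4, c))).value
                for c in (0.0, 0.3, 0.6, 0.9)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.01

    def test_reports_beta_star_near_one_for_weak_mismatch(self):
        res = phi_star(build_model(two_node(0.4, 0.1)))
        assert 0.0 < res.diagnostics["beta_star"] < 2.0


class TestPhiG:
    def test_block_diagonal_coupling_gives_zero(self):
        model = decoupled_pairs_model(rho_noise=0.3)
        state = phi_g(model, SEPARATING)
        assert state.objective == pytest.approx(0.0, abs=1e-9)
        assert state.constraint_residual < 1e-6

    def test_invariant_to_noise_correlation(self):
        v0 = phi_g_measure(build_model(two_node(0.4, 0.0))).value
        v5 = phi_g_measure(build_model(two_node(0.4, 0.5))).value
        assert v5 == pytest.approx(v0, abs=1e-6)

    def test_solution_beats_naive_feasible_initialisation(self):
        rng = np.random.default_rng(26)
        for _ in range(10):
            model = build_model(random_stable_system(2, rng))
            state = phi_g(model, P2)
            # feasible upper bound: A' = block-diagonal restriction of A
            a_eff = model.effective_coupling()
            a0 = np.diag(np.diag(a_eff))
            delta = a_eff - a0
            sp = model.sigma_present_given_past() + \
                delta @ model.sigma_x @ delta.T
            naive = 0.5 * (np.linalg.slogdet(sp)[1] - np.linalg.slogdet(
                model.sigma_present_given_past())[1])
            assert state.objective <= naive + 1e-10

    def test_bounds(self):
        rng = np.random.default_rng(27)
        for _ in range(10):
            model = build_model(random_stable_system(4, rng))
            val = phi_g_measure(model).value
            assert -1e-9 <= val <= tdmi(model) + 1e-9


class TestTransferEntropyAndCD:
    def test_no_coupling_means_no_transfer(self):
        model = build_model(ARSystem(np.zeros((2, 2)), np.eye(2)))
        assert cd_measure(model).value == pytest.approx(0.0, abs=1e-12)

    def test_unidirectional_coupling_has_one_way_transfer(self):
        A = np.array([[0.5, 0.0], [0.4, 0.3]])  # node 0 → node 1 only
        model = build_model(ARSystem(A, np.eye(2)))
        assert transfer_entropy(model, [1], [0]) == pytest.approx(0.0,
                                                                  abs=1e-10)
        assert transfer_entropy(model, [0], [1]) > 0.01

    def test_atomic_partition_conditions_on_the_rest(self):
        rng = np.random.default_rng(28)
        model = build_model(random_stable_system(4, rng))
        from iintegrate import atomic_partition
        val = causal_density(model, atomic_partition(4))
        assert np.isfinite(val) and val >= -1e-10

    def test_decreases_toward_zero_with_noise_correlation(self):
        vals = [cd_measure(build_model(two_node(0.4, c))).value
                for c in (0.0, 0.3, 0.6, 0.9)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.02

    def test_bounded_by_tdmi(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            model = build_model(random_stable_system(4, rng))
            assert -1e-9 <= cd_measure(model).value <= tdmi(model) + 1e-9
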