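"""Tests of the exact linear-model engine against closed forms, quadrature
oracles, sampling oracles, and the model's structural invariants."""

import numpy as np
import pytest
from scipy.linalg import expm, solve_continuous_lyapunov

from infotherm import (
    BLRMParams,
    ContractError,
    causal_influence,
    information_flow,
    irreversibility,
    irreversibility_ratio,
    lagged_gaussian,
    psi_density,
    sample_transitions,
    stationary_cov,
)
from infotherm.blrm import drift_matrix, suggested_dps
from infotherm.gaussian import gaussian_logpdf


class TestStationaryCov:
    def test_ou_variance_closed_form(self):
        S = stationary_cov(BLRMParams(trel=10.0, D=1.0, alpha=1.0, beta=0.2))
        assert S[0, 0] == pytest.approx(5.0, rel=1e-12)

    def test_decoupled_response_limit(self):
        S = stationary_cov(BLRMParams(trel=10.0, D=1.0, alpha=1e-12, beta=0.2))
        assert S[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert S[0, 0] == pytest.approx(5.0, rel=1e-12)

    def test_lyapunov_oracle(self):
        """The closed form solves A S + S A' + diag(D^2, 0) = 0 (scipy route)."""
        p = BLRMParams(trel=7.0, D=1.3, alpha=-0.8, beta=0.45)
        A = drift_matrix(p)
        S_ref = solve_continuous_lyapunov(A, -np.diag([p.D**2, 0.0]))
        assert stationary_cov(p) == pytest.approx(S_ref, rel=1e-9)


class TestLaggedGaussian:
    def test_x_autocovariance_closed_form(self):
        p = BLRMParams(trel=10.0, D=1.0, alpha=1.0, beta=0.2)
        ljg = lagged_gaussian(p, tau=10.0)
        assert ljg.sigma4[2, 0] == pytest.approx(5.0 * np.exp(-1.0), rel=1e-10)

    def test_stationary_blocks_equal(self):
        ljg = lagged_gaussian(BLRMParams(trel=3.0, beta=0.7), tau=2.0)
        assert np.allclose(ljg.sigma4[:2, :2], ljg.sigma4[2:, 2:], atol=1e-9)

    def test_large_tau_decorrelates(self):
        p = BLRMParams(trel=10.0, beta=0.2)
        ljg = lagged_gaussian(p, tau=100 * max(p.trel, 1 / p.beta))
        assert np.abs(ljg.cross).max() < 1e-12

    def test_spd_at_moderate_tau(self):
        ljg = lagged_gaussian(BLRMParams(trel=10.0, beta=0.2), tau=0.5)
        assert np.linalg.eigvalsh(ljg.sigma4).min() > 0

    def test_tau_nonpositive_rejected(self):
        with pytest.raises(ContractError):
            lagged_gaussian(BLRMParams(trel=10.0, beta=0.2), tau=0.0)

    def test_sampling_oracle_covariance(self):
        """Exact draws reproduce the analytic 4x4 covariance within 3 SE."""
        p = BLRMParams(trel=10.0, D=1.0, alpha=1.0, beta=0.2)
        ljg = lagged_gaussian(p, tau=5.0)
        ens = sample_transitions(ljg, 10**6, seed=17)
        emp = np.cov(ens.samples, rowvar=False)
        n = ens.n
        for i in range(4):
            for j in range(4):
                se = np.sqrt(
                    (ljg.sigma4[i, i] * ljg.sigma4[j, j] + ljg.sigma4[i, j] ** 2) / n
                )
                assert emp[i, j] == pytest.approx(ljg.sigma4[i, j], abs=3 * se)


class TestIrreversibility:
    def test_signal_marginal_reversible(self):
        """The OU signal is time-symmetric: phi_x = 0 for any parameters."""
        for p, tau in [
            (BLRMParams(trel=10.0, beta=0.2), 5.0),
            (BLRMParams(trel=1.0, D=2.0, alpha=-3.0, beta=4.0), 0.3),
            (BLRMParams(trel=50.0, D=0.1, alpha=0.5, beta=0.02), 40.0),
        ]:
            assert irreversibility(p, tau).phi_x <= 1e-10

    def test_large_tau_ratio_two(self):
        p = BLRMParams(trel=10.0, beta=0.2)
        r = irreversibility(p, 50.0)
        assert r.phi_xy / r.bte == pytest.approx(2.0, rel=0.05)

    def test_ratio_two_any_parameters_high_precision(self):
        """The limit of 2 holds for every beta*trel, evaluated at tau = 50/beta."""
        for beta in (0.05, 0.2, 1.0):
            p = BLRMParams(trel=10.0, beta=beta)
            assert irreversibility_ratio(p, 50.0 / beta) == pytest.approx(2.0, rel=0.05)

    def test_high_precision_agrees_with_float_path(self):
        p = BLRMParams(trel=10.0, beta=0.2)
        a = irreversibility(p, 5.0)
        b = irreversibility(p, 5.0, dps=50)
        assert a.phi_xy == pytest.approx(b.phi_xy, rel=1e-9)
        assert a.bte == pytest.approx(b.bte, rel=1e-9)
        assert a.causal_influence == pytest.approx(b.causal_influence, rel=1e-8)

    def test_sampling_oracle_phi(self):
        """phi_xy equals the sampled mean of the log-density ratio within 3 SE."""
        p = BLRMParams(trel=10.0, beta=0.2)
        ljg = lagged_gaussian(p, 5.0)
        ens = sample_transitions(ljg, 10**6, seed=23)
        phi_samples = gaussian_logpdf(ljg.sigma4, ens.samples) - gaussian_logpdf(
            ljg.swapped(), ens.samples
        )
        se = phi_samples.std(ddof=1) / np.sqrt(ens.n)
        assert irreversibility(p, 5.0).phi_xy == pytest.approx(
            phi_samples.mean(), abs=3 * se
        )

    def test_small_tau_singularity_message(self):
        p = BLRMParams(trel=10.0, beta=0.2)
        with pytest.raises(Exception, match="larger tau"):
            irreversibility(p, 1e-9)


class TestCausalInfluence:
    def test_coupling_scale_free(self):
        """With zero response noise every information measure is independent
        of the coupling scale alpha (y is a noiseless linear functional of
        the x history, and mutual information ignores linear rescalings)."""
        c_ref, r_ref = causal_influence(BLRMParams(trel=10.0, alpha=1.0, beta=0.2), 1.0)
        for alpha in (1e-9, 1e-3, -7.0):
            c, r = causal_influence(BLRMParams(trel=10.0, alpha=alpha, beta=0.2), 1.0)
            assert c == pytest.approx(c_ref, abs=1e-9)
            assert r == pytest.approx(r_ref, abs=1e-9)

    def test_large_tau_eighth_of_phi(self):
        p = BLRMParams(trel=10.0, beta=0.2)
        r = irreversibility(p, 50.0)
        assert r.phi_xy / r.causal_influence == pytest.approx(8.0, rel=0.10)

    def test_small_tau_converges_to_bte(self):
        p = BLRMParams(trel=10.0, beta=0.2)
        r = irreversibility(p, 0.01)
        assert r.causal_influence == pytest.approx(r.bte, rel=0.05)

    def test_redundancy_vanishes_at_large_tau(self):
        p = BLRMParams(trel=10.0, beta=0.2)
        _, r_small = causal_influence(p, 1.0)
        _, r_large = causal_influence(p, 200.0)
        assert r_large < 1e-6 < r_small


class TestInformationFlow:
    def test_flow_is_coupling_independent(self):
        """With zero response noise, y tracks the x history deterministically
        at any coupling scale, so the flow equals the response bandwidth beta
        for every alpha != 0 (it jumps to 0 only at exactly alpha = 0)."""
        for alpha in (1e-6, 1.0, -4.0):
            p = BLRMParams(trel=10.0, alpha=alpha, beta=0.2)
            assert information_flow(p) == pytest.approx(p.beta, rel=1e-12)

    def test_quadrature_oracle(self):
        """Grid quadrature of the current-times-score integral, 800x800, +-6 SD."""
        p = BLRMParams(trel=10.0, D=1.0, alpha=1.0, beta=0.2)
        S = stationary_cov(p)
        sx, sy = np.sqrt(S[0, 0]), np.sqrt(S[1, 1])
        x = np.linspace(-6 * sx, 6 * sx, 800)
        y = np.linspace(-6 * sy, 6 * sy, 800)
        X, Y = np.meshgrid(x, y, indexing="ij")
        det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
        pdf = np.exp(
            -0.5 * (S[1, 1] * X**2 - 2 * S[0, 1] * X * Y + S[0, 0] * Y**2) / det
        ) / (2 * np.pi * np.sqrt(det))
        # d ln p(x|y) / dy for the stationary Gaussian
        k = S[0, 1] / S[1, 1]
        var_c = S[0, 0] - S[0, 1] ** 2 / S[1, 1]
        score = (X - k * Y) * k / var_c
        integrand = pdf * (p.alpha * X - p.beta * Y) * score
        quad = np.trapezoid(np.trapezoid(integrand, y, axis=1), x)
        assert information_flow(p) == pytest.approx(quad, rel=1e-3)

    def test_small_tau_causal_rate_oracle(self):
        """The causal-influence rate extrapolated to tau -> 0 equals the flow."""
        p = BLRMParams(trel=10.0, D=1.0, alpha=1.0, beta=0.2)
        c1, _ = causal_influence(p, 1e-3)
        c2, _ = causal_influence(p, 2e-3)
        rate = (c2 - c1) / 1e-3
        assert information_flow(p) == pytest.approx(rate, rel=0.02)


class TestPsiDensity:
    def test_quadrature_recovers_phi(self):
        p = BLRMParams(trel=10.0, beta=0.2)
        gd = psi_density(p, 0.5, grid_sd=6.0, grid_n=400)
        phi = irreversibility(p, 0.5).phi_xy
        assert gd.quadrature() == pytest.approx(phi, rel=0.01)

    def test_point_symmetry_and_positivity(self):
        gd = psi_density(BLRMParams(trel=10.0, beta=0.2), 0.5, grid_n=151)
        assert np.all(gd.psi >= 0)
        assert np.abs(gd.psi - gd.psi[::-1, ::-1]).max() <= 1e-9 * gd.psi.max()

    def test_two_off_diagonal_spots_at_small_tau(self):
        """For tau below both timescales the density peaks off the axes,
        in two spots exchanged by the point reflection (x, y) -> (-x, -y)."""
        gd = psi_density(BLRMParams(trel=10.0, beta=0.2), 0.5, grid_n=151)
        i, j = np.unravel_index(np.argmax(gd.psi), gd.psi.shape)
        assert abs(gd.x_axis[i]) > 0.1 and abs(gd.y_axis[j]) > 0.05
        mirrored = gd.psi[gd.psi.shape[0] - 1 - i, gd.psi.shape[1] - 1 - j]
        assert mirrored == pytest.approx(gd.psi[i, j], rel=1e-9)


class TestStructuralInvariants:
    TAUS = (0.1, 1.0, 10.0, 100.0)
    BETA_TRELS = (0.1, 0.5, 1.0, 2.0, 10.0)

    @pytest.mark.parametrize("beta_trel", BETA_TRELS)
    def test_second_law_chain(self, beta_trel):
        """phi_xy >= phi_cond >= bte >= 0, strict in the interior."""
        p = BLRMParams(trel=1.0, beta=beta_trel)
        for tau in self.TAUS:
            need = suggested_dps(p, tau)
            r = irreversibility(p, tau, dps=need if need > 55 else None)
            assert r.phi_xy >= r.phi_cond >= r.bte >= 0
            if tau <= 10.0:
                assert r.phi_cond > r.bte > 0

    def test_no_feedback_means_no_forward_transfer(self):
        for beta_trel in self.BETA_TRELS:
            for tau in self.TAUS:
                r = irreversibility(BLRMParams(trel=1.0, beta=beta_trel), tau)
                assert r.fte <= 1e-10

    def test_scale_invariance_in_noise_amplitude(self):
        p1 = BLRMParams(trel=10.0, D=1.0, alpha=1.0, beta=0.2)
        p2 = BLRMParams(trel=10.0, D=2.0, alpha=1.0, beta=0.2)
        r1, r2 = irreversibility(p1, 5.0), irreversibility(p2, 5.0)
        for key in ("phi_xy", "phi_x", "bte", "fte", "causal_influence", "redundancy"):
            assert getattr(r1, key) == pytest.approx(getattr(r2, key), abs=1e-9)

    def test_beta_trel_sufficiency(self):
        """Equal beta*trel and tau/trel give identical measures."""
        r1 = irreversibility(BLRMParams(trel=10.0, D=1.0, alpha=1.0, beta=0.2), 5.0)
        r2 = irreversibility(BLRMParams(trel=2.0, D=0.7, alpha=3.0, beta=1.0), 1.0)
        for key in ("phi_xy", "phi_x", "bte", "fte", "causal_influence", "redundancy"):
            assert getattr(r1, key) == pytest.approx(getattr(r2, key), abs=1e-9)

    def test_measures_decay_at_large_tau(self):
        p = BLRMParams(trel=10.0, beta=0.2)
        taus = [10.0 * 2**k for k in range(5)]
        phis = [irreversibility(p, t, dps=60).phi_xy for t in taus]
        btes = [irreversibility(p, t, dps=60).bte for t in taus]
        assert all(a > b for a, b in zip(phis, phis[1:]))
        assert all(a > b for a, b in zip(btes, btes[1:]))
        assert phis[-1] < 1e-6

    def test_phi_diverges_at_small_tau(self):
        p = BLRMParams(trel=10.0, beta=0.2)
        assert irreversibility(p, 1e-3).phi_xy > irreversibility(p, 1e-2).phi_xy


def test_expm_matches_closed_form_cross_block():
    """The matrix-exponential cross block agrees with the scalar OU factor."""
    p = BLRMParams(trel=4.0, D=1.0, alpha=2.0, beta=0.5)
    E = expm(drift_matrix(p) * 3.0)
    assert E[0, 0] == pytest.approx(np.exp(-3.0 / 4.0), rel=1e-12)
    assert E[0, 1] == 0.0
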