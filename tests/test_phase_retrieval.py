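"""The RED phase-retrieval solver, probing, and the closed calibration loop."""

import numpy as np
import pytest

from prfocus._utils import align_phase
from prfocus.metrics import corr
from prfocus.phase_retrieval import (
    AdaptiveCalibration,
    SolverConfig,
    SonicationOracle,
    TransferMatrixCalibration,
    align_global_phase,
    amplitude_loss,
    amplitude_subgradient,
    bernoulli_probes,
    calibration_loop,
    fasta_solve,
    make_init_with_corr,
    measure,
    red_penalty,
)

PLAIN = SolverConfig(lam=0.0, denoiser="identity", n_restarts=1)


def random_row(rng, n=16):
    return rng.standard_normal(n) + 1j * rng.standard_normal(n)


class TestProbes:
    def test_entries_are_plus_minus_one(self):
        E = bernoulli_probes(100, 32, seed=0).matrix
        assert set(np.unique(E)) == {-1.0, 1.0}

    def test_column_means_concentrate(self):
        E = bernoulli_probes(10_000, 16, seed=1).matrix
        assert np.max(np.abs(E.mean(axis=0))) < 0.05

    def test_seeded_determinism(self):
        a = bernoulli_probes(50, 8, seed=9).matrix
        b = bernoulli_probes(50, 8, seed=9).matrix
        np.testing.assert_array_equal(a, b)


class TestMeasure:
    def test_zero_row_gives_zero_magnitudes(self):
        P = measure(np.zeros(8, complex), bernoulli_probes(20, 8, 0)).values
        assert np.all(P == 0)

    def test_hand_computed_single_probe(self):
        P = measure(np.array([1.0, 1j]), np.array([[1.0, 1.0]])).values
        assert P[0] == pytest.approx(np.sqrt(2.0))

    def test_noiseless_is_reproducible(self, rng):
        h = random_row(rng)
        probes = bernoulli_probes(32, 16, 3)
        a = measure(h, probes, 0.0).values
        b = measure(h, probes, 0.0).values
        np.testing.assert_array_equal(a, b)

    def test_negative_noise_rejected(self, rng):
        with pytest.raises(ValueError):
            measure(random_row(rng), bernoulli_probes(4, 16, 0), noise_std=-0.1)


class TestObjectivePieces:
    def test_loss_zero_at_truth(self, rng):
        h = random_row(rng)
        probes = bernoulli_probes(32, 16, 2)
        P = measure(h, probes).values
        assert amplitude_loss(h, probes, P) == pytest.approx(0.0, abs=1e-20)

    def test_loss_scalar_case(self):
        # P = 2, |Eh| = 1  ->  1/2 (2-1)^2
        assert amplitude_loss(np.array([1.0 + 0j]), np.array([[1.0]]), [2.0]) == 0.5

    def test_loss_global_phase_invariant(self, rng):
        h = random_row(rng)
        probes = bernoulli_probes(32, 16, 4)
        P = measure(h, probes, 0.3, seed=0).values
        base = amplitude_loss(h, probes, P)
        for theta in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            assert amplitude_loss(np.exp(1j * theta) * h, probes, P) == pytest.approx(base)

    def test_subgradient_zero_at_exact_fit(self):
        z = np.array([1.0, 2.0, 3.0], dtype=complex)
        np.testing.assert_allclose(amplitude_subgradient(z, np.abs(z)), 0.0, atol=1e-15)

    def test_subgradient_at_zero_magnitude_target(self):
        z = np.array([1.0 + 2j, -3.0 + 0j])
        np.testing.assert_array_equal(amplitude_subgradient(z, np.zeros(2)), z)

    @pytest.mark.parametrize("theta", [0.0, 0.7, 2.1, -1.3])
    def test_subgradient_scalar_phase(self, theta):
        z = np.array([2.0 * np.exp(1j * theta)])
        out = amplitude_subgradient(z, np.array([1.0]))
        assert out[0] == pytest.approx((2.0 - 1.0) * np.exp(1j * theta))

    def test_subgradient_defined_at_z_zero(self):
        out = amplitude_subgradient(np.zeros(2, complex), np.array([1.0, 2.0]))
        np.testing.assert_array_equal(out, 0.0)

    def test_red_penalty_identity_denoiser_is_zero(self, rng):
        h = random_row(rng)
        assert red_penalty(h, "identity", lam=2.0) == 0.0
        assert red_penalty(h, "median", lam=0.0) == 0.0

    def test_red_penalty_scalar_hand_computed(self):
        def d(h, layout, strength):
            return np.array([1.0 + 0j])

        assert red_penalty(np.array([2.0 + 0j]), d, lam=1.0, layout=(1, 1)) == pytest.approx(1.0)


class TestSolver:
    def test_truth_init_noiseless_returns_immediately(self, rng):
        h = random_row(rng)
        probes = bernoulli_probes(64, 16, 5)
        P = measure(h, probes)
        est = fasta_solve(h, probes, P, PLAIN)
        assert est.iterations_used == 0
        assert est.final_objective == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_array_equal(est.h, h)

    def test_objective_trace_monotone_over_seeds(self):
        cfg = SolverConfig(max_inner_iterations=200, n_restarts=1, polish=False)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            h = random_row(rng)
            probes = bernoulli_probes(32, 16, seed)
            P = measure(h, probes, noise_std=0.2, seed=seed)
            model = TransferMatrixCalibration(probes, P, cfg)
            res = model.fit(random_row(rng))
            assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_noiseless_exact_recovery_at_4n(self):
        """m >= 4N noiseless: phase-aligned relative error <= 1e-3.

        Real probes cannot distinguish a row from its conjugate, so the
        error is taken to the closer of the two branches.
        """
        cfg = SolverConfig(n_restarts=16, max_inner_iterations=2000)
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            h = random_row(rng)
            probes = bernoulli_probes(64, 16, seed)
            P = measure(h, probes)
            init = make_init_with_corr(h, 0.3, seed=seed).h
            est = fasta_solve(init, probes, P, cfg)
            err = min(
                np.linalg.norm(align_phase(est.h, ref) - ref) for ref in (h, np.conj(h))
            ) / np.linalg.norm(h)
            assert err <= 1e-3

    def test_brute_force_oracle_equivalence_at_n2(self, rng):
        """At N=2 an exhaustive magnitude x phase grid cannot beat the solver."""
        h = np.array([1.1 * np.exp(0.4j), 0.8 * np.exp(-1.9j)])
        probes = bernoulli_probes(8, 2, 0)
        P = measure(h, probes).values
        E = probes.matrix
        mags = np.linspace(0.05, 2.0, 24)
        phases = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        m1, p1, m2, p2 = np.meshgrid(mags, phases, mags, phases, indexing="ij")
        cand = np.stack(
            [(m1 * np.exp(1j * p1)).ravel(), (m2 * np.exp(1j * p2)).ravel()], axis=1
        )
        objs = 0.5 * np.sum((P[None, :] - np.abs(cand @ E.T)) ** 2, axis=1)
        est = fasta_solve(random_row(rng, 2), probes, P,
                          SolverConfig(lam=0.0, denoiser="identity", n_restarts=6))
        model = TransferMatrixCalibration(probes, P, PLAIN)
        assert model.objective(est.h) <= objs.min() + 1e-9

    def test_results_summary_and_predict(self, rng):
        h = random_row(rng)
        probes = bernoulli_probes(64, 16, 6)
        P = measure(h, probes)
        res = TransferMatrixCalibration(probes, P, PLAIN).fit(h)
        text = res.summary()
        assert "m/N" in text and "final objective" in text
        np.testing.assert_allclose(res.predict(), P.values, atol=1e-9)
        assert res.mse() == pytest.approx(0.0, abs=1e-18)

    def test_probe_measurement_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="counts differ"):
            TransferMatrixCalibration(bernoulli_probes(8, 4, 0), np.ones(7))


class TestAlignment:
    def test_pure_rotation_recovered_exactly(self, rng):
        h = random_row(rng)
        np.testing.assert_allclose(align_global_phase(1j * h, h), h, atol=1e-12)

    def test_identity_when_already_aligned(self, rng):
        h = random_row(rng)
        np.testing.assert_allclose(align_global_phase(h, h), h, atol=1e-12)

    def test_zero_reference_unchanged(self, rng):
        h = random_row(rng)
        np.testing.assert_array_equal(align_global_phase(h, np.zeros_like(h)), h)

    def test_aligned_residual_beats_grid_search(self, rng):
        for _ in range(10):
            a, b = random_row(rng), random_row(rng)
            aligned = np.linalg.norm(align_global_phase(a, b) - b)
            grid = min(
                np.linalg.norm(np.exp(1j * t) * a - b)
                for t in np.linspace(0, 2 * np.pi, 720)
            )
            assert aligned <= grid + 1e-9


class TestInitWithCorr:
    def test_rho_one_returns_truth(self, rng):
        h = random_row(rng, 64)
        np.testing.assert_array_equal(make_init_with_corr(h, 1.0, 0).h, h)

    def test_rho_zero_has_small_overlap(self, rng):
        h = random_row(rng, 64)
        for seed in range(50):
            init = make_init_with_corr(h, 0.0, seed).h
            assert abs(corr(init, h)) < 0.1

    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.95])
    def test_calibrated_correlation(self, rho, rng):
        h = random_row(rng, 64)
        for seed in range(5):
            init = make_init_with_corr(h, rho, seed).h
            assert corr(init, h) == pytest.approx(rho, abs=0.02)

    def test_invalid_rho_rejected(self, rng):
        with pytest.raises(ValueError):
            make_init_with_corr(random_row(rng), 1.5, 0)


class TestOracleAndLoop:
    def test_conjugate_branch_resolved_by_extra_sonication(self, rng):
        h = random_row(rng, 32)
        oracle = SonicationOracle(h)
        assert oracle.recovery_pct(np.conj(h)) == pytest.approx(100.0)
        assert oracle.recovery_pct(h) == pytest.approx(100.0)
        assert oracle.recovery_pct(1j * h) == pytest.approx(100.0)

    def test_zero_probe_budget_returns_init(self, rng):
        h = random_row(rng)
        oracle = SonicationOracle(h)
        init = make_init_with_corr(h, 0.6, 0).h
        est, trace = calibration_loop(init, oracle, PLAIN, max_probes=0)
        np.testing.assert_array_equal(est.h, init)
        assert len(trace) == 1 and trace["m"].iloc[0] == 0

    def test_trace_shape_and_bounds(self, rng):
        h = random_row(rng)
        oracle = SonicationOracle(h)
        init = make_init_with_corr(h, 0.6, 1).h
        est, trace = calibration_loop(init, oracle, PLAIN, max_probes=8, seed=3)
        assert len(trace) == 9  # step 0 plus one row per probe
        assert list(trace.columns) == [
            "m", "m_over_n", "r_ns_pct", "r_ns_step_pct", "corr", "mse", "objective",
        ]
        assert trace["r_ns_pct"].between(0, 100 + 1e-9).all()
        # the protocol retains the best measured drive, so this is monotone
        assert (trace["r_ns_pct"].diff().dropna() >= -1e-9).all()
        assert np.isnan(trace["mse"].iloc[0]) and trace["mse"].iloc[1:].notna().all()

    def test_stop_ratio_halts_early(self, rng):
        h = random_row(rng)
        oracle = SonicationOracle(h)
        init = make_init_with_corr(h, 0.95, 2).h
        proto = AdaptiveCalibration(oracle, init, PLAIN, max_probes=64, stop_ratio=99.0)
        res = proto.run(seed=4)
        assert res.final_recovery_pct >= 99.0
        assert res.trace["m"].iloc[-1] < 64
        assert "retained recovery" in res.summary()

    def test_recovery_invariant_to_estimate_phase(self, rng):
        h = random_row(rng, 32)
        oracle = SonicationOracle(h)
        g = make_init_with_corr(h, 0.7, 3).h
        base = oracle.recovery_pct(g)
        for theta in (0.5, 1.7, 3.0):
            assert oracle.recovery_pct(np.exp(1j * theta) * g) == pytest.approx(base)

    def test_anchored_loop_improves_from_warm_start(self, rng):
        h = random_row(rng, 32)
        oracle = SonicationOracle(h)
        init = make_init_with_corr(h, 0.6, 5).h
        cfg = SolverConfig(lam=0.5, denoiser="identity", max_inner_iterations=400)
        est, trace = calibration_loop(init, oracle, cfg, max_probes=32, seed=6)
        assert trace["r_ns_pct"].iloc[-1] > trace["r_ns_pct"].iloc[0]


def test_estimate_hdf5_roundtrip(tmp_path, rng):
    from prfocus.phase_retrieval import TMEstimate

    est = TMEstimate(random_row(rng), 12, 0.5, "estimate", True)
    path = tmp_path / "est.h5"
    est.to_hdf5(path)
    back = TMEstimate.from_hdf5(path)
    np.testing.assert_array_equal(back.h, est.h)
    assert back.iterations_used == 12 and back.provenance == "estimate"
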