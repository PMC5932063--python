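"""Square-well DMD, ENM surrogate, covariance, and mode analysis."""

import math

import numpy as np
import pytest

from allokit import dynamics as dyn
from allokit.structure import CaTrace
from conftest import linear_ca_trace


class TestSquareWellModel:
    def test_bonded_pair_well_bounds(self):
        model = dyn.build_square_well_model(linear_ca_trace(2))
        (pair,) = model.pairs
        assert pair.bonded
        assert pair.d_min == pytest.approx(0.95 * 3.8)
        assert pair.d_max == pytest.approx(1.05 * 3.8)

    def test_linear_chain_pair_classes(self):
        model = dyn.build_square_well_model(linear_ca_trace(5))
        kinds = {(p.i, p.j): p.bonded for p in model.pairs}
        assert kinds[(0, 1)] is True
        assert kinds[(0, 2)] is False          # 7.6 A < 8 A cutoff
        assert (0, 3) not in kinds             # 11.4 A, no interaction

    def test_distant_nonconsecutive_beads_free(self):
        pos = np.array([[0.0, 0, 0], [9.0, 0, 0]])
        trace = CaTrace(positions=pos,
                        residue_index_map=[("A", 1, ""), ("B", 1, "")])
        model = dyn.build_square_well_model(trace, chain_breaks=[1])
        assert model.pairs == []


class TestRunDMD:
    def test_hard_wall_energy_momentum_invariants(self):
        model = dyn.build_square_well_model(linear_ca_trace(8))
        traj = dyn.run_dmd(model, n_events=5000, sample_every=25, seed=0)
        assert dyn.well_violation(model, traj.frames) <= 1e-9
        ke0 = traj.meta["kinetic_energy_initial"]
        ke1 = traj.meta["kinetic_energy_final"]
        assert abs(ke1 - ke0) / ke0 < 1e-8
        assert traj.meta["momentum_drift"] < 1e-8

    def test_queue_matches_brute_force_minimum_time(self):
        """Every popped event is the exhaustive minimum over pair events."""
        pos = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0.5, 0]])
        trace = CaTrace(positions=pos,
                        residue_index_map=[("A", i + 1, "")
                                           for i in range(3)])
        model = dyn.build_square_well_model(trace)
        mismatches = []

        def check(t_now, t_ev, pair, pos_now, vel_now):
            best = (math.inf, None)
            for p in model.pairs:
                dt = dyn.pair_event_time(pos_now[p.i] - pos_now[p.j],
                                         vel_now[p.i] - vel_now[p.j],
                                         p.d_min, p.d_max)
                if dt < best[0]:
                    best = (dt, (p.i, p.j))
            if abs((t_now + best[0]) - t_ev) > 1e-9 or best[1] != pair:
                mismatches.append((t_ev, pair, best))

        dyn.run_dmd(model, n_events=1000, sample_every=100, seed=3,
                    pre_event_hook=check)
        assert mismatches == []

    def test_two_bead_distance_follows_shell_density(self):
        """Canonical sampling of one square well: p(d) is proportional to
        d^2 on [d_min, d_max] (uniform over the shell volume)."""
        from scipy import stats
        trace = linear_ca_trace(2)
        model = dyn.build_square_well_model(trace)
        traj = dyn.run_dmd(model, n_events=60_000, sample_every=10, seed=2,
                           andersen_interval=2.0)
        d = np.linalg.norm(traj.frames[:, 0] - traj.frames[:, 1], axis=1)
        lo, hi = model.pairs[0].d_min, model.pairs[0].d_max
        cdf = lambda x: (np.clip(x, lo, hi) ** 3 - lo ** 3) / \
            (hi ** 3 - lo ** 3)
        assert stats.kstest(d, cdf).pvalue > 0.01

    def test_bad_event_count_rejected(self):
        model = dyn.build_square_well_model(linear_ca_trace(3))
        with pytest.raises(ValueError):
            dyn.run_dmd(model, n_events=0)

    def test_same_seed_reproduces_frames(self):
        model = dyn.build_square_well_model(linear_ca_trace(5))
        t1 = dyn.run_dmd(model, n_events=2000, sample_every=20, seed=9)
        t2 = dyn.run_dmd(model, n_events=2000, sample_every=20, seed=9)
        np.testing.assert_array_equal(t1.frames, t2.frames)


class TestENMSurrogate:
    def test_zero_temperature_freezes_frames(self, toy_dimer_trace):
        traj = dyn.sample_enm_ensemble(toy_dimer_trace, n_frames=5,
                                       temperature_scale=0.0, seed=0)
        for f in traj.frames:
            np.testing.assert_allclose(f, toy_dimer_trace.positions,
                                       atol=1e-12)

    def test_sample_covariance_converges_to_target(self, toy_dimer_trace):
        cov = dyn.enm_covariance(toy_dimer_trace.positions, 10.0)
        traj = dyn.sample_gaussian_ensemble(cov, 10_000, seed=1)
        est = dyn.compute_covariance(traj, superpose=False)
        err = np.linalg.norm(est.matrix - cov.matrix) / \
            np.linalg.norm(cov.matrix)
        assert err < 0.05

    def test_same_seed_identical_frames(self, toy_dimer_trace):
        a = dyn.sample_enm_ensemble(toy_dimer_trace, n_frames=4, seed=5)
        b = dyn.sample_enm_ensemble(toy_dimer_trace, n_frames=4, seed=5)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_disconnected_network_raises(self):
        pos = np.zeros((4, 3))
        pos[:2, 0] = [0.0, 3.8]
        pos[2:, 0] = [50.0, 53.8]
        trace = CaTrace(positions=pos,
                        residue_index_map=[("A", i + 1, "")
                                           for i in range(4)])
        with pytest.raises(dyn.ConnectivityError, match="cutoff"):
            dyn.sample_enm_ensemble(trace, spring_cutoff=10.0, n_frames=3,
                                    seed=0)

    def test_enm_bfactors_from_frames_match_analytic(self, toy_dimer_trace):
        cov = dyn.enm_covariance(toy_dimer_trace.positions, 10.0)
        analytic = dyn.compute_bfactors(cov).bfactor
        traj = dyn.sample_gaussian_ensemble(cov, 10_000, seed=2)
        sampled = dyn.compute_bfactors(
            dyn.compute_covariance(traj, superpose=False)).bfactor
        r = np.corrcoef(analytic, sampled)[0, 1]
        assert r > 0.98


class TestCovariance:
    def test_identical_frames_give_zero_matrix(self):
        frames = np.tile(np.arange(12.0).reshape(1, 4, 3), (5, 1, 1))
        cov = dyn.compute_covariance(
            dyn.TrajectoryEnsemble(frames=frames, source="external"),
            superpose=False)
        np.testing.assert_allclose(cov.matrix, 0.0, atol=1e-12)

    def test_diagonal_gaussian_recovered(self):
        rng = np.random.default_rng(0)
        var = np.linspace(0.5, 2.0, 12)
        frames = (rng.standard_normal((8000, 12)) * np.sqrt(var)).reshape(
            8000, 4, 3)
        cov = dyn.compute_covariance(
            dyn.TrajectoryEnsemble(frames=frames, source="external"),
            superpose=False)
        np.testing.assert_allclose(np.diag(cov.matrix), var, rtol=0.1)

    def test_symmetric_psd(self):
        rng = np.random.default_rng(1)
        frames = rng.standard_normal((50, 6, 3))
        cov = dyn.compute_covariance(
            dyn.TrajectoryEnsemble(frames=frames, source="external"))
        assert np.allclose(cov.matrix, cov.matrix.T)
        assert np.linalg.eigvalsh(cov.matrix).min() > -1e-10


class TestBfactors:
    def test_zero_covariance_zero_b(self):
        cov = dyn.CovarianceMatrix(matrix=np.zeros((9, 9)),
                                   mean=np.zeros((3, 3)))
        assert (dyn.compute_bfactors(cov).bfactor == 0).all()

    def test_isotropic_variance_formula(self):
        s2 = 0.7
        cov = dyn.CovarianceMatrix(matrix=np.eye(9) * s2,
                                   mean=np.zeros((3, 3)))
        np.testing.assert_allclose(dyn.compute_bfactors(cov).bfactor,
                                   8 * np.pi ** 2 * s2)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((9, 9))
        C = A @ A.T
        cov = dyn.CovarianceMatrix(matrix=C, mean=np.zeros((3, 3)))
        b = dyn.compute_bfactors(cov).bfactor
        perm = [2, 0, 1]
        P = np.zeros((9, 9))
        for new, old in enumerate(perm):
            P[3 * new:3 * new + 3, 3 * old:3 * old + 3] = np.eye(3)
        covp = dyn.CovarianceMatrix(matrix=P @ C @ P.T,
                                    mean=np.zeros((3, 3)))
        np.testing.assert_allclose(dyn.compute_bfactors(covp).bfactor,
                                   b[perm])


class TestSlowModes:
    def test_rank_one_concentrates_on_loaded_residue(self):
        v = np.zeros(9)
        v[3] = 1.0  # x of residue 1
        cov = dyn.CovarianceMatrix(matrix=np.outer(v, v),
                                   mean=np.zeros((3, 3)))
        prof = dyn.pca_slow_modes(cov, smooth_window=1)
        assert prof.profile[1] == pytest.approx(1.0)

    def test_profile_sums_to_one(self, toy_dimer_covariance):
        prof = dyn.pca_slow_modes(toy_dimer_covariance)
        assert prof.profile.sum() == pytest.approx(1.0)

    def test_modes_reconstruct_covariance(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((12, 12))
        C = A @ A.T
        w, V = np.linalg.eigh(C)
        recon = (V * w) @ V.T
        assert np.linalg.norm(recon - C) / np.linalg.norm(C) < 1e-10

    def test_too_many_modes_rejected(self, toy_dimer_covariance):
        with pytest.raises(ValueError):
            dyn.pca_slow_modes(toy_dimer_covariance, n_modes=10_000)

    def test_planted_hinge_is_detected_minimum(self, toy_dimer,
                                               toy_dimer_covariance):
        _, _, labels = toy_dimer
        n = labels["n_per_protomer"]
        prof = dyn.pca_slow_modes(toy_dimer_covariance,
                                  segments=[(0, n), (n, 2 * n)],
                                  smooth_window=3)
        assert prof.minima.size
        for h in labels["hinge_all"]:
            assert np.min(np.abs(prof.minima - h)) <= 2


def test_trajectory_pdb_roundtrip(tmp_path, toy_dimer_trace):
    traj = dyn.sample_enm_ensemble(toy_dimer_trace, n_frames=3, seed=0)
    path = tmp_path / "traj.pdb"
    dyn.write_trajectory_pdb(traj, toy_dimer_trace.residue_index_map, path)
    back = dyn.read_trajectory_pdb(path)
    assert back.n_frames == 3
    np.testing.assert_allclose(back.frames, traj.frames, atol=1e-3)
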