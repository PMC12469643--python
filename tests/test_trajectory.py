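"""Trajectory pipeline: alignment, N–H vectors, P2 ACF, fits, bootstrap."""

import math
import warnings

import numpy as np
import pytest

import MDAnalysis as mda

from relaxsel.spin import InteractionConstants, eval_J_simple, all_rates
from relaxsel.synthetic import (
    DynamicsSpec,
    ResidueDynamics,
    build_synthetic_trajectory_files,
    cone_order_parameter,
    simulate_nh_vectors,
)
from relaxsel.trajectory import (
    AcfSeries,
    VectorTrajectory,
    align_trajectory,
    backcalc_segment_rates,
    bootstrap_rate_errors,
    compute_p2_acf,
    extract_nh_vectors,
    fit_acf_multiexp,
)


def _static_vec(n_frames=500, dt_ns=0.01):
    v = np.tile(np.array([0.0, 0.0, 1.0]), (1, n_frames, 1))
    return VectorTrajectory(residues=np.array([1]), vectors=v, dt_ns=dt_ns)


def _random_vec(n_frames=4000, seed=0, dt_ns=0.01):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(1, n_frames, 3))
    v /= np.linalg.norm(v, axis=2, keepdims=True)
    return VectorTrajectory(residues=np.array([1]), vectors=v, dt_ns=dt_ns)


class TestP2Acf:
    def test_static_vector_acf_is_one(self):
        acf = compute_p2_acf(_static_vec(), 2.0)[1]
        assert np.allclose(acf.values, 1.0)

    def test_iid_sphere_vectors_decorrelate(self):
        acf = compute_p2_acf(_random_vec(), 2.0)[1]
        tail = acf.values[1:]
        bound = 3.0 / np.sqrt(acf.n_pairs[1:])
        assert np.all(np.abs(tail) < bound)

    def test_fft_and_direct_estimators_agree(self):
        vec = _random_vec(n_frames=800)
        a_fft = compute_p2_acf(vec, 3.0, method="fft")[1].values
        a_dir = compute_p2_acf(vec, 3.0, method="direct")[1].values
        assert np.abs(a_fft - a_dir).max() < 1e-10

    def test_time_reversal_invariance(self):
        vec = _random_vec(n_frames=600, seed=5)
        rev = VectorTrajectory(residues=vec.residues.copy(),
                               vectors=vec.vectors[:, ::-1].copy(),
                               dt_ns=vec.dt_ns)
        a = compute_p2_acf(vec, 2.0)[1].values
        b = compute_p2_acf(rev, 2.0)[1].values
        assert np.abs(a - b).max() < 1e-10

    def test_cone_plateau_matches_analytic_order_parameter(self):
        # fitted plateau a0 vs the closed-form cone order parameter
        spec = DynamicsSpec(
            residues=(ResidueDynamics("cone", theta0_deg=60.0),),
            dt_ps=1.0, n_frames=150000, seed=9)
        sim = simulate_nh_vectors(spec)
        acf = compute_p2_acf(sim.internal, 3.0)[1]
        fit = fit_acf_multiexp(acf)
        assert fit.a0 == pytest.approx(0.140625, abs=0.05)

    def test_lag_beyond_duration_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            compute_p2_acf(_static_vec(n_frames=100), 50.0)

    def test_short_segment_warns(self):
        with pytest.warns(UserWarning, match="10\\*tau_c"):
            compute_p2_acf(_static_vec(n_frames=500), 2.0, tau_c_ns=14.7)


class TestMultiExpFit:
    def test_exact_two_component_model(self):
        t = np.arange(0, 1500) * 0.01
        c = 0.8 + 0.2 * np.exp(-t / 1.0)
        acf = AcfSeries(lags_ns=t, values=c, n_pairs=np.full(t.size, 1000))
        fit = fit_acf_multiexp(acf)
        assert fit.a0 == pytest.approx(0.8, abs=1e-4)
        assert fit.m == 1
        assert fit.terms[0][1] == pytest.approx(1.0, rel=1e-3)

    def test_constant_acf_needs_no_exponentials(self):
        t = np.arange(0, 100) * 0.01
        acf = AcfSeries(lags_ns=t, values=np.ones_like(t),
                        n_pairs=np.full(t.size, 1000))
        fit = fit_acf_multiexp(acf)
        assert fit.m == 0 and fit.a0 == 1.0

    def test_noisy_two_exponential_amplitudes(self):
        rng = np.random.default_rng(11)
        t = np.arange(0, 3000) * 0.01
        c = 0.5 + 0.3 * np.exp(-t / 0.2) + 0.2 * np.exp(-t / 3.0)
        noisy = np.clip(c + 0.01 * rng.standard_normal(t.size), -1, 1)
        noisy[0] = 1.0   # C(0) is exact by construction
        acf = AcfSeries(lags_ns=t, values=noisy,
                        n_pairs=np.full(t.size, 1000))
        fit = fit_acf_multiexp(acf)
        assert fit.a0 == pytest.approx(0.5, abs=0.03)

    def test_amplitudes_sum_to_one_and_nonnegative(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 500) * 0.01
        c = 0.9 + 0.1 * np.exp(-t / 0.5) + 0.005 * rng.standard_normal(t.size)
        c[0] = 1.0
        fit = fit_acf_multiexp(AcfSeries(lags_ns=t, values=np.clip(c, -1, 1),
                                         n_pairs=np.full(t.size, 10)))
        total = fit.a0 + sum(a for a, _ in fit.terms)
        assert total == pytest.approx(1.0, abs=1e-6)
        assert fit.a0 >= 0 and all(a >= 0 for a, _ in fit.terms)

    def test_too_few_points_rejected(self):
        t = np.arange(0, 5) * 0.01
        acf = AcfSeries(lags_ns=t, values=np.ones_like(t),
                        n_pairs=np.full(t.size, 10))
        with pytest.raises(ValueError, match="lag points"):
            fit_acf_multiexp(acf)


class TestBackcalc:
    def test_rigid_fit_reproduces_analytic_rates(self, constants):
        from relaxsel.trajectory import MultiExpFit
        fit = MultiExpFit(a0=1.0, terms=(), rss=0.0, aicc=0.0, n_points=100)
        rates = backcalc_segment_rates({5: fit}, 14.7e-9, constants)[0]
        J = lambda w: eval_J_simple(1.0, 14.7e-9, w)  # noqa: E731
        want = all_rates(J, constants, with_r2=False)
        assert rates.r1 == pytest.approx(want["r1"], rel=1e-12)
        assert rates.eta_xy == pytest.approx(want["eta_xy"], rel=1e-12)
        assert rates.noe == pytest.approx(want["noe"], rel=1e-12)
        # rigid plateau at τc = 14.7 ns, 600 MHz sits near 14 s⁻¹
        assert 13.0 < rates.eta_xy < 16.5

    def test_invalid_tau_c_rejected(self, constants):
        with pytest.raises(ValueError):
            backcalc_segment_rates({}, -1.0, constants)


class TestBootstrap:
    def test_same_seed_reproduces_sds(self, constants):
        spec = DynamicsSpec(
            residues=(ResidueDynamics("cone", theta0_deg=40.0),),
            dt_ps=1.0, n_frames=20000, seed=4)
        vec = simulate_nh_vectors(spec).internal
        kwargs = dict(lag_max_ns=1.0, n_boot=10, seed=99)
        a = bootstrap_rate_errors(vec, 14.7e-9, constants, **kwargs)
        b = bootstrap_rate_errors(vec, 14.7e-9, constants, **kwargs)
        assert a == b

    def test_static_vectors_have_zero_dispersion(self, constants):
        vec = _static_vec(n_frames=2000)
        sds = bootstrap_rate_errors(vec, 14.7e-9, constants,
                                    lag_max_ns=1.0, n_boot=5, seed=0)[1]
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in sds.values())

    def test_overlong_block_rejected(self, constants):
        vec = _static_vec(n_frames=200)
        with pytest.raises(ValueError, match="block"):
            bootstrap_rate_errors(vec, 14.7e-9, constants,
                                  lag_max_ns=1.0, block_length_ns=1.0,
                                  n_boot=2, seed=0)


class TestAlignmentAndExtraction:
    @pytest.fixture(scope="class")
    def tumbling_files(self, tmp_path_factory):
        spec = DynamicsSpec(
            residues=(ResidueDynamics("rigid"),
                      ResidueDynamics("cone", theta0_deg=40.0,
                                      wobble_step_deg=12.0),
                      ResidueDynamics("rigid", proline=True),
                      ResidueDynamics("rigid")),
            dt_ps=10.0, n_frames=1500, seed=21, tumbling_tau_c_ns=3.0)
        prefix = tmp_path_factory.mktemp("traj") / "tumble"
        top, trj, sim = build_synthetic_trajectory_files(spec, str(prefix))
        return top, trj, sim, spec

    def test_pure_rotation_aligns_to_static(self, tumbling_files):
        top, trj, _, _ = tumbling_files
        u = mda.Universe(top, trj)
        align_trajectory(u, [(1, 1), (4, 4)])
        sel = u.select_atoms("name N CA C O")
        u.trajectory[0]
        ref = sel.positions.copy()
        worst = max(np.abs(sel.positions - ref).max()
                    for _ in u.trajectory)
        assert worst < 5e-3   # PDB coordinate precision is 1e-3 Å

    def test_alignment_idempotent(self, tumbling_files):
        top, trj, _, _ = tumbling_files
        u = mda.Universe(top, trj)
        align_trajectory(u, [(1, 1), (4, 4)])
        first = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
        align_trajectory(u, [(1, 1), (4, 4)])
        second = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
        assert np.abs(first - second).max() < 1e-3

    def test_extraction_skips_proline_and_terminus(self, tumbling_files):
        top, trj, _, _ = tumbling_files
        u = mda.Universe(top, trj)
        vec = extract_nh_vectors(u, dt_ns=0.01)
        assert list(vec.residues) == [2, 4]
        reasons = dict(vec.skipped)
        assert reasons[3] == "proline"
        assert reasons[1] == "n-terminus"

    def test_nh_vector_direction(self):
        # residue 6: H displaced along +z from N by the bond length
        u = mda.Universe.empty(4, n_residues=2, atom_resindex=[0, 0, 1, 1],
                               trajectory=True)
        u.add_TopologyAttr("names", ["N", "H", "N", "H"])
        u.add_TopologyAttr("resnames", ["ALA", "ALA"])
        u.add_TopologyAttr("resids", [5, 6])
        coords = np.zeros((1, 4, 3), dtype=np.float32)
        coords[0, 1] = (1.02, 0.0, 0.0)
        coords[0, 2] = (5.0, 0.0, 0.0)
        coords[0, 3] = (5.0, 0.0, 1.02)
        u.load_new(coords, dt=1.0)
        u.load_new(np.repeat(coords, 10, axis=0), dt=1.0)
        vec = extract_nh_vectors(u, dt_ns=0.001)
        assert list(vec.residues) == [6]
        np.testing.assert_allclose(vec.vectors[0, 0], [0.0, 0.0, 1.0],
                                   atol=1e-7)

    def test_alignment_restores_internal_acf(self, tumbling_files):
        top, trj, sim, spec = tumbling_files
        u = mda.Universe(top, trj)
        align_trajectory(u, [(1, 1), (4, 4)])
        vec = extract_nh_vectors(u, dt_ns=spec.dt_ps / 1000.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aligned = compute_p2_acf(vec, 3.0)
            reference = compute_p2_acf(sim.internal, 3.0)
        i = list(vec.residues).index(2)
        assert np.abs(aligned[2].values - reference[2].values).max() < 0.02

    def test_empty_rigid_selection_rejected(self, tumbling_files):
        top, trj, _, _ = tumbling_files
        u = mda.Universe(top, trj)
        with pytest.raises(ValueError):
            align_trajectory(u, [(900, 950)])


class TestVectorTrajectoryInvariants:
    def test_non_unit_vectors_rejected(self):
        v = np.full((1, 10, 3), 0.5)
        with pytest.raises(ValueError, match="unit-norm"):
            VectorTrajectory(residues=np.array([1]), vectors=v, dt_ns=0.01)

    def test_nan_frames_rejected(self):
        v = np.tile(np.array([0.0, 0.0, 1.0]), (1, 10, 1))
        v[0, 3] = np.nan
        with pytest.raises(ValueError):
            VectorTrajectory(residues=np.array([1]), vectors=v, dt_ns=0.01)
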