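"""TSH engine: integrator pieces, hop logic, trajectory-level invariants."""

import numpy as np
import pytest
from scipy.linalg import polar

from pfmhop.decoherence import DecoherenceConfig
from pfmhop.engine import (
    IntegratorConfig,
    attempt_hop,
    electronic_overlap_and_nac,
    electronic_substep_propagation,
    finish_nuclear_step,
    hop_probabilities,
    hop_rescale_factor,
    local_diabatization_matrix,
    nuclear_step,
    propagate_ensemble,
    run_trajectory,
)
from pfmhop.units import FS_TO_AU
from pfmhop.wigner import InitialEnsemble

from conftest import make_displaced_pair


class TestNuclearStep:
    def test_zero_force_uniform_motion(self):
        m = np.array([2000.0])
        r, v = np.array([[1.0]]), np.array([[0.01]])
        r2, v_half = nuclear_step(r, v, np.zeros((1, 1)), m, dt=10.0)
        assert r2[0, 0] == pytest.approx(1.1, rel=1e-15)
        assert v_half[0, 0] == 0.01

    def test_constant_force_displacement(self):
        m = np.array([2000.0])
        f = np.array([[0.004]])
        r2, v_half = nuclear_step(np.zeros((1, 1)), np.zeros((1, 1)), f, m, dt=10.0)
        assert r2[0, 0] == pytest.approx(0.5 * 0.004 * 100 / 2000, rel=1e-15)

    def test_harmonic_energy_drift(self):
        """Velocity Verlet on a harmonic surface: relative drift < 1e-7."""
        m, omega = 2000.0, 0.01
        k = m * omega * omega
        dt = 0.01 / omega  # omega dt = 0.01
        r, v = np.array([[0.5]]), np.array([[0.0]])
        masses = np.array([m])
        f = -k * r
        energies = []
        for _ in range(10_000):
            r, v_half = nuclear_step(r, v, f, masses, dt)
            f = -k * r
            v = finish_nuclear_step(v_half, f, masses, dt)
            energies.append(0.5 * k * r[0, 0] ** 2 + 0.5 * m * v[0, 0] ** 2)
        energies = np.array(energies)
        # instantaneous energy oscillates at O((w dt)^2) but, the integrator
        # being symplectic, the oscillation envelope shows no secular drift
        drift = abs(energies[-2000:].max() - energies[:2000].max())
        assert drift / energies.mean() < 1e-7


class TestOverlapAndNac:
    def test_identity(self):
        w = np.eye(3)
        s, k, _ = electronic_overlap_and_nac(w, w, dt=1.0)
        assert np.allclose(s, np.eye(3))
        assert np.allclose(k, 0.0)

    def test_small_rotation(self):
        theta, dt = 0.01, 1.0
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        s, k, _ = electronic_overlap_and_nac(np.eye(2), rot, dt)
        assert k[0, 1] == pytest.approx(-np.sin(theta), abs=1e-12)
        assert k[0, 0] == pytest.approx((1 - np.cos(theta)) / dt, abs=1e-12)

    def test_sign_continuity(self):
        w_now = -np.eye(2)  # flipped columns
        s, k, w_fixed = electronic_overlap_and_nac(np.eye(2), w_now, 1.0)
        assert np.allclose(w_fixed, np.eye(2))
        assert np.allclose(k, 0.0)


class TestLocalDiabatization:
    def test_identity_and_orthogonal_passthrough(self):
        assert np.allclose(local_diabatization_matrix(np.eye(2)), np.eye(2))
        theta = 0.3
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        assert np.allclose(local_diabatization_matrix(rot), rot, atol=1e-14)

    def test_noisy_orthogonal_vs_polar_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(q))
            noisy = q + rng.normal(scale=1e-3, size=(3, 3))
            u = local_diabatization_matrix(noisy)
            assert np.max(np.abs(u.T @ u - np.eye(3))) < 1e-12
            u_ref, _ = polar(noisy)  # independent orthogonalization
            u_ref *= np.sign(np.diag(u_ref))
            assert np.allclose(u, u_ref, atol=1e-10)
            assert np.max(np.abs(u - noisy)) < 10 * 1e-3

    def test_singular_rejected(self):
        with pytest.raises(Exception):
            local_diabatization_matrix(np.zeros((2, 2)))


class TestElectronicPropagation:
    def test_constant_diagonal_phases(self):
        e = np.array([0.1, 0.3])
        h = np.diag(e).astype(complex)
        c0 = np.sqrt(0.5) * np.ones(2, dtype=complex)
        t = 10.0
        c = electronic_substep_propagation(c0, h, h, t, n_substeps=51)
        assert np.allclose(c, c0 * np.exp(-1j * e * t), atol=1e-10)

    def test_rabi_populations(self):
        v12 = 0.001
        h = np.array([[0.0, v12], [v12, 0.0]], dtype=complex)
        c = electronic_substep_propagation(np.array([1.0, 0.0], dtype=complex),
                                           h, h, 100.0, n_substeps=51)
        assert np.abs(c[0]) ** 2 == pytest.approx(np.cos(v12 * 100.0) ** 2,
                                                  abs=1e-8)

    def test_zero_hamiltonian(self):
        c0 = np.array([0.6, 0.8j], dtype=complex)
        z = np.zeros((2, 2), dtype=complex)
        assert np.allclose(electronic_substep_propagation(c0, z, z, 50.0), c0)

    def test_non_finite_interpolant_rejected(self):
        z = np.full((2, 2), np.nan, dtype=complex)
        with pytest.raises(ValueError):
            electronic_substep_propagation(np.array([1, 0], dtype=complex),
                                           z, z, 1.0)


class TestHopLogic:
    def test_no_population_change(self):
        p = hop_probabilities(np.array([0.6, 0.4]), np.array([0.6, 0.4]), 0)
        assert np.all(p == 0.0)

    def test_single_gainer(self):
        p = hop_probabilities(np.array([0.6, 0.3, 0.1]),
                              np.array([0.5, 0.4, 0.1]), 0)
        assert p[1] == pytest.approx(1 / 6)
        assert p[2] == 0.0

    def test_split_gain(self):
        p = hop_probabilities(np.array([0.6, 0.2, 0.2]),
                              np.array([0.5, 0.25, 0.25]), 0)
        assert p[1] == pytest.approx(1 / 12)
        assert p[2] == pytest.approx(1 / 12)

    def test_zero_active_population(self):
        p = hop_probabilities(np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0)
        assert np.all(p == 0.0)

    def test_rescale_factors(self):
        assert hop_rescale_factor(0.0, 0.01) == pytest.approx(1.0)
        assert hop_rescale_factor(0.0025, 0.01) == pytest.approx(np.sqrt(0.75))

    def test_frustrated_hop(self):
        energies = np.array([0.0, 0.5])
        active, hopped, frustrated = attempt_hop(
            0, np.array([0.0, 0.9]), 0.5, energies, kinetic=0.1)
        assert active == 0 and not hopped and frustrated

    def test_allowed_hop_selection(self):
        energies = np.array([0.0, 0.01, 0.02])
        active, hopped, _ = attempt_hop(
            0, np.array([0.0, 0.3, 0.3]), 0.45, energies, kinetic=1.0)
        assert hopped and active == 2  # cumulative interval (0.3, 0.6]


@pytest.fixture(scope="module")
def scattering_setup(preset_models):
    model = preset_models["avoided_crossing_2s"]
    rng = np.random.default_rng(10)
    n = 4
    pos = rng.normal(2.6, 0.05, (n, 1))
    mom = rng.normal(0.0, 10.0, (n, 1))
    coeffs = np.tile([1.0 + 0j, 0.0j], (n, 1))
    cfg = IntegratorConfig(dt=0.1 * FS_TO_AU,
                           decoherence=DecoherenceConfig("fmi", sigma=0.05,
                                                         mu=20000.0))
    return model, pos, mom, coeffs, cfg


class TestTrajectoryPropagation:
    def test_same_seed_bit_identical(self, scattering_setup):
        model, pos, mom, coeffs, cfg = scattering_setup
        a = run_trajectory(model, pos[0], mom[0], coeffs[0], cfg, 200, seed=5)
        b = run_trajectory(model, pos[0], mom[0], coeffs[0], cfg, 200, seed=5)
        assert np.array_equal(a.coeffs, b.coeffs)
        assert np.array_equal(a.active, b.active)
        assert np.array_equal(a.e_tot, b.e_tot)

    def test_batch_equals_sequential(self, scattering_setup):
        """Batched propagation reproduces one-at-a-time runs exactly."""
        model, pos, mom, coeffs, cfg = scattering_setup
        batch = propagate_ensemble(model, InitialEnsemble(pos, mom, coeffs),
                                   cfg, 200, base_seed=5)
        for i in range(pos.shape[0]):
            single = run_trajectory(model, pos[i], mom[i], coeffs[i], cfg, 200,
                                    seed=5, trajectory_index=i)
            assert np.array_equal(single.coeffs[0], batch.coeffs[i])
            assert np.array_equal(single.active[0], batch.active[i])

    def test_invariants_along_trajectories(self, scattering_setup):
        model, pos, mom, coeffs, cfg = scattering_setup
        raw = propagate_ensemble(model, InitialEnsemble(pos, mom, coeffs),
                                 cfg, 400, base_seed=5)
        norms = np.sum(np.abs(raw.coeffs) ** 2, axis=2)
        assert np.max(np.abs(norms - 1.0)) < 1e-10
        gram = np.einsum("nki,nkj->nij", raw.u_cumulative, raw.u_cumulative)
        assert np.max(np.abs(gram - np.eye(model.n_states))) < 1e-10
        # total energy conserved (hop discontinuities compensated by rescaling)
        assert np.max(raw.drift) < 1e-5

    def test_zero_coupling_freezes_populations(self):
        model = make_displaced_pair(gap=0.05, displacement=0.4)
        rng = np.random.default_rng(2)
        n = 6
        ens = InitialEnsemble(rng.normal(0, 0.2, (n, 1)),
                              rng.normal(0, 2.0, (n, 1)),
                              np.tile([np.sqrt(0.5) + 0j, np.sqrt(0.5)], (n, 1)))
        cfg = IntegratorConfig(dt=0.1 * FS_TO_AU,
                               decoherence=DecoherenceConfig("nd"))
        raw = propagate_ensemble(model, ens, cfg, 1000, base_seed=1,
                                 initial_basis="adiabatic")
        pops = np.abs(raw.coeffs) ** 2
        assert np.max(np.abs(pops - pops[:, :1])) < 1e-10
        assert raw.hop_count.sum() == 0
        assert np.max(raw.drift) < 1e-6  # hartree, over 100 fs

    def test_fewest_switches_scheme_runs_equivalently(self, scattering_setup):
        """The classic coefficient/NAC hop formula is a drop-in alternative."""
        model, pos, mom, coeffs, cfg = scattering_setup
        alt = IntegratorConfig(dt=cfg.dt, hop_scheme="fewest_switches",
                               decoherence=cfg.decoherence)
        raw = propagate_ensemble(model, InitialEnsemble(pos, mom, coeffs),
                                 alt, 400, base_seed=5)
        norms = np.sum(np.abs(raw.coeffs) ** 2, axis=2)
        assert np.max(np.abs(norms - 1.0)) < 1e-10
        assert np.max(raw.drift) < 1e-5

    def test_multidimensional_lvc_with_pfmi(self, preset_models):
        """The multi-D pathway (TVP auxiliary scalars) conserves the
        invariants on the linear-vibronic-coupling preset."""
        from pfmhop.wigner import harmonic_wigner_sample, width_parameters

        model = preset_models["lvc_nd"]
        spec = width_parameters(model.normal_modes)
        ens = harmonic_wigner_sample(model.normal_modes, 16, seed=12) \
            .with_coefficients([0.0, 1.0])
        cfg = IntegratorConfig(dt=0.1 * FS_TO_AU,
                               decoherence=DecoherenceConfig(
                                   "pfmi", omega=spec.omega, n_d=spec.n_d))
        raw = propagate_ensemble(model, ens, cfg, 300, base_seed=4,
                                 initial_basis="adiabatic")
        norms = np.sum(np.abs(raw.coeffs) ** 2, axis=2)
        assert np.max(np.abs(norms - 1.0)) < 1e-10
        assert not raw.failed.any()
        assert raw.hop_count.sum() > 0
        # intersection-seam passages leave O(dt) energy kinks; the standard
        # 1 eV drift criterion must hold and typical trajectories stay tight
        assert np.max(raw.drift) < 1.0 / 27.211386
        assert np.median(raw.drift) < 5e-3

    def test_hop_log_records_events(self, scattering_setup):
        model, pos, mom, coeffs, cfg = scattering_setup
        raw = propagate_ensemble(model, InitialEnsemble(pos, mom, coeffs),
                                 cfg, 400, base_seed=5)
        n_events = raw.hop_count.sum() + raw.frustrated_count.sum()
        assert len(raw.hop_log) == n_events

    def test_record_io(self, tmp_path, scattering_setup):
        model, pos, mom, coeffs, cfg = scattering_setup
        raw = run_trajectory(model, pos[0], mom[0], coeffs[0], cfg, 50, seed=5)
        df = raw.trajectory_frame(0)
        assert {"t", "x0", "active", "e_tot", "re_c0", "p_aux0"} <= set(df.columns)
        assert len(df) == raw.t.size
        path = tmp_path / "raw.h5"
        raw.to_hdf5(path)
        import h5py

        with h5py.File(path) as f:
            assert np.allclose(f["coeffs"][:], raw.coeffs)
            assert f.attrs["base_seed"] == 5
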