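"""Decoherence rates, auxiliary force/momentum machinery, coefficient damping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfmhop.decoherence import (
    DecoherenceConfig,
    apply_decoherence,
    aux_momentum_update,
    collapse_subthreshold,
    edc_rate,
    fm_rate_1d,
    fm_rate_normal_modes,
    initial_aux_momentum,
    pfm_rate,
    tvp_force,
)

finite = st.floats(-50, 50, allow_nan=False)
positive = st.floats(1e-3, 50, allow_nan=False)


class TestEdcRate:
    def test_rest_gives_zero(self):
        assert edc_rate(0.1, 0.0, 0.1) == 0.0

    def test_direct_value(self):
        assert edc_rate(0.1, 0.1, 0.1) == pytest.approx(0.05)

    def test_high_kinetic_limit(self):
        c = 0.1
        k = edc_rate(0.1, 1e6 * c, c)
        assert k == pytest.approx(0.1, rel=1e-6)


class TestFmRate1d:
    def test_zero_momentum(self):
        assert fm_rate_1d(0.0, 5.0, 1.0, 1.0) == 0.0

    def test_direct_values(self):
        assert fm_rate_1d(1.0, 0.0, 1.0, 1.0) == pytest.approx(0.5)
        assert fm_rate_1d(2.0, 3.0, 1.0, 1.0) == pytest.approx(
            0.5 * (6.0 + 2.0 * np.sqrt(10.0)))


class TestPfmRate:
    def test_zero_momentum(self):
        assert pfm_rate(0.0, 1.0, 1.0, 8) == 0.0

    def test_force_free(self):
        assert pfm_rate(1.0, 0.0, 1.0, 8) == pytest.approx(np.pi)

    def test_direct_value(self):
        # pi^2/(8 w)|P||F| + |P| sqrt(pi^2 N_D w / 8) at w=2, N_D=2
        expected = np.pi ** 2 / 16 + np.pi / np.sqrt(2)
        assert pfm_rate(1.0, 1.0, 2.0, 2) == pytest.approx(expected)


def test_fm_normal_mode_reduction_to_1d():
    """Single-mode mass-weighted rate equals the 1-D bond-coordinate rate."""
    rng = np.random.default_rng(0)
    for _ in range(200):
        mu = rng.uniform(100, 5e4)
        sigma = rng.uniform(0.02, 1.0)
        p, f = rng.normal(0, 5, 2)
        omega = 1.0 / (2 * mu * sigma ** 2)
        k_nm = fm_rate_normal_modes([p / np.sqrt(mu)], [f / np.sqrt(mu)], [omega])
        k_1d = fm_rate_1d(p, f, sigma, mu)
        # roundoff scale: the (possibly cancelling) terms of the sum
        root = np.sqrt(f * f + 1.0 / (mu ** 2 * sigma ** 6))
        scale = 0.5 * sigma ** 2 * (abs(p * f) + abs(p) * root)
        assert abs(k_nm - k_1d) < 1e-12 * scale + 1e-18


def test_common_frequency_upper_bound():
    """(1/2w)|qd||qdd| + |qd| sqrt(N_D w/2) bounds the per-mode sum (10^4 draws)."""
    rng = np.random.default_rng(1)
    n_d = 6
    for _ in range(10_000):
        omega = rng.uniform(1e-3, 1.0)
        qd = rng.normal(0, 3, n_d)
        qdd = rng.normal(0, 3, n_d)
        exact = fm_rate_normal_modes(qd, qdd, np.full(n_d, omega))
        bound = (np.linalg.norm(qd) * np.linalg.norm(qdd) / (2 * omega)
                 + np.linalg.norm(qd) * np.sqrt(n_d * omega / 2))
        assert exact <= bound * (1 + 1e-12)


def test_all_rates_nonnegative():
    rng = np.random.default_rng(2)
    n = 100_000
    p = rng.normal(0, 10, n)
    f = rng.normal(0, 10, n)
    sigma = rng.uniform(0.01, 2.0, n)
    mu = rng.uniform(10, 1e5, n)
    omega = rng.uniform(1e-4, 1.0, n)
    gap = rng.normal(0, 1, n)
    kin = rng.uniform(0, 10, n)
    assert np.all(fm_rate_1d(p, f, sigma, mu) >= 0)
    assert np.all(pfm_rate(p, f, omega, 5) >= 0)
    assert np.all(edc_rate(gap, kin, 0.1) >= 0)
    qd = rng.normal(0, 5, (n // 10, 4))
    qdd = rng.normal(0, 5, (n // 10, 4))
    om = rng.uniform(1e-3, 1.0, (n // 10, 4))
    assert np.all(fm_rate_normal_modes(qd, qdd, om) >= 0)


class TestTvpForce:
    def test_direct(self):
        assert tvp_force(0.0, 0.01, 0.5, 10.0) == pytest.approx(-0.002)

    def test_velocity_threshold(self):
        assert tvp_force(0.0, 0.01, 1e-10, 10.0, kappa=1e-9) == 0.0

    def test_constant_energy(self):
        assert tvp_force(0.3, 0.3, 0.7, 5.0) == 0.0


class TestAuxMomentumUpdate:
    def test_initial_equality_makes_rates_vanish(self):
        """Equal initial auxiliary momenta and zero initial forces give k=0."""
        p0 = initial_aux_momentum(np.array([[0.3, 0.1]]),
                                  np.array([100.0, 200.0]), "tvp")
        paux = np.tile(p0[:, None], (1, 3))
        p_ij = paux - paux[:, :1]
        assert np.all(pfm_rate(np.abs(p_ij), 0.0, 0.01, 2) == 0.0)

    def test_subthreshold_reset(self):
        """P_i = P_a sqrt(1 - E_ia/T) for states without their own packet."""
        paux = np.array([[10.0, 0.0]])
        faux = np.zeros((1, 2))
        kinetic = np.array([1.0])
        energies = np.array([[0.0, 0.75]])  # E_ia = 0.75 T
        pops = np.array([[1.0, 1e-6]])
        out = aux_momentum_update(paux, faux, pops, pops, energies, kinetic,
                                  np.array([0]), np.array([0]),
                                  np.array([1.0]), dt=1.0, eta=1e-4,
                                  injection=False)
        assert out[0, 1] == pytest.approx(5.0)

    def test_injection_blend(self):
        """P_i <- P_i (1 - dr/|c|^2) + (dr/|c|^2) P_a sqrt(1 - E_ia/T)."""
        paux = np.array([[8.0, 4.0]])
        faux = np.zeros((1, 2))
        kinetic = np.array([1.0])
        energies = np.array([[0.0, 0.0]])  # rescale factor 1 -> term = P_a = 8
        pop_prev = np.array([[0.9, 0.1]])
        pop_new = np.array([[0.8, 0.2]])
        out = aux_momentum_update(paux, faux, pop_prev, pop_new, energies,
                                  kinetic, np.array([0]), np.array([0]),
                                  np.array([1.0]), dt=1.0, eta=1e-4,
                                  injection=True)
        assert out[0, 1] == pytest.approx(4 * 0.5 + 0.5 * 8)

    def test_active_continuity_and_rescale_on_hop(self):
        paux = np.array([[3.0, 7.0]])
        faux = np.array([[0.5, 0.25]])
        energies = np.array([[0.0, 0.0]])
        pops = np.array([[0.5, 0.5]])
        out = aux_momentum_update(paux, faux, pops, pops, energies,
                                  np.array([2.0]), np.array([0]), np.array([1]),
                                  np.array([0.8]), dt=2.0, eta=1e-4,
                                  injection=False)
        # new active slot continues from previous active momentum
        assert out[0, 1] == pytest.approx((3.0 + 0.25 * 2.0) * 0.8)


class TestApplyDecoherence:
    def test_zero_rates_identity(self):
        c = np.array([0.6, 0.8j], dtype=complex)
        out = apply_decoherence(c, np.zeros(2), 1, 0.1)
        assert np.allclose(out, c)

    def test_half_damping_example(self):
        c = np.sqrt(0.5) * np.array([1.0, 1.0], dtype=complex)
        k = np.array([np.log(2.0), 0.0])  # e^{-k dt} = 0.5 at dt = 1
        out = apply_decoherence(c, k, 1, 1.0)
        assert np.abs(out[0]) ** 2 == pytest.approx(0.125)
        assert np.abs(out[1]) ** 2 == pytest.approx(0.875)

    def test_infinite_rate_collapses(self):
        c = np.sqrt(0.5) * np.array([1.0, 1.0], dtype=complex)
        out = apply_decoherence(c, np.array([1e9, 0.0]), 1, 1.0)
        assert np.abs(out[0]) < 1e-12
        assert np.abs(out[1]) == pytest.approx(1.0)

    def test_zero_active_amplitude_raises(self):
        c = np.array([1.0, 0.0], dtype=complex)
        with pytest.raises(ZeroDivisionError):
            apply_decoherence(c, np.array([1.0, 0.0]), 1, 1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(finite, finite), min_size=2, max_size=5),
           st.lists(st.floats(0, 20), min_size=5, max_size=5),
           st.floats(1e-3, 2.0))
    def test_norm_preserved_and_inactive_never_grow(self, amps, rates, dt):
        c = np.array([complex(a, b) for a, b in amps])
        if np.linalg.norm(c) < 1e-6:
            return
        c /= np.linalg.norm(c)
        rates = np.array(rates[:len(c)])
        active = int(np.argmax(np.abs(c)))
        if np.abs(c[active]) == 0:
            return
        out = apply_decoherence(c, rates, active, dt)
        assert np.sum(np.abs(out) ** 2) == pytest.approx(1.0, abs=1e-12)
        inactive = np.arange(len(c)) != active
        assert np.all(np.abs(out[inactive]) <= np.abs(c[inactive]) + 1e-15)


def test_collapse_subthreshold_moves_residual():
    c = np.array([np.sqrt(0.99995), np.sqrt(5e-5)], dtype=complex)
    pop_prev = np.array([0.9995, 5e-4])
    out = collapse_subthreshold(c, 0, pop_prev, eta=1e-4)
    assert out[1] == 0.0
    assert np.abs(out[0]) == pytest.approx(1.0, abs=1e-12)


def test_config_validation():
    with pytest.raises(ValueError, match="variant"):
        DecoherenceConfig("bogus")
    with pytest.raises(ValueError, match="sigma"):
        DecoherenceConfig("fm", sigma=-0.1, mu=100.0)
    with pytest.raises(ValueError, match="omega"):
        DecoherenceConfig("pfmi", omega=-1.0, n_d=2)
    with pytest.raises(ValueError, match="FM"):
        DecoherenceConfig("fm").require_width()
    cfg = DecoherenceConfig("fmi", sigma=0.1, mu=1000.0)
    assert cfg.injection
    assert not DecoherenceConfig("fm", sigma=0.1, mu=1000.0).injection
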