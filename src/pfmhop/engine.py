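"""Fewest-switches surface-hopping propagation.

One nuclear time step follows the classic local-diabatization loop:

1. first Velocity-Verlet half-step (midpoint velocity, end-of-step position);
2. adiabatize the potential at the new position, align eigenvector signs
   with the previous step, build the state-overlap matrix S and the
   finite-difference time-derivative coupling K = (1 - S)/dt;
3. construct the step diabatization matrix U as the closest orthogonal
   matrix to S (polar decomposition) and transform potential and residual
   coupling to the local diabatic basis;
4. propagate the electronic coefficients with RK4 over electronic substeps
   (default 51) using linearly interpolated matrices, transforming to the
   adiabatic basis each substep to evaluate density-flux hopping and the
   decoherence correction;
5. second Velocity-Verlet half-step; if the active surface changed, rescale
   the velocities isotropically to conserve total energy (frustrated hops
   leave the velocity untouched);
6. propagate the auxiliary momenta of the decoherence model and collapse
   fully-decohered inactive states.

The propagator acts on a whole batch of trajectories at once (arrays with a
leading trajectory axis); each trajectory owns an independent RNG stream
seeded from ``(base_seed, trajectory_index)``, so batched propagation is
identical to running trajectories one at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import decoherence as deco
from .decoherence import DecoherenceConfig
from .models import DiabaticModel, adiabatize_batch, batched_active_gradient
from .wigner import InitialEnsemble

__all__ = [
    "IntegratorConfig",
    "TrajectoryState",
    "RawEnsemble",
    "nuclear_step",
    "electronic_overlap_and_nac",
    "local_diabatization_matrix",
    "electronic_substep_propagation",
    "hop_probabilities",
    "attempt_hop",
    "hop_rescale_factor",
    "run_trajectory",
    "propagate_ensemble",
]


@dataclass
class IntegratorConfig:
    """Propagation parameters (atomic units)."""

    dt: float = 4.1341374575751  # 0.1 fs
    n_substeps: int = 51
    interpolation: str = "linear"
    hop_scheme: str = "density_flux"  # or "fewest_switches"
    decoherence: DecoherenceConfig = field(default_factory=lambda: DecoherenceConfig("nd"))

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_substeps < 2:
            raise ValueError("need at least 2 electronic substeps")
        if self.interpolation != "linear":
            raise ValueError("only linear substep interpolation is implemented")
        if self.hop_scheme not in ("density_flux", "fewest_switches"):
            raise ValueError(f"unknown hop scheme {self.hop_scheme!r}")


@dataclass
class TrajectoryState:
    """Live state of a single trajectory (atomic units)."""

    time: float
    positions: np.ndarray
    velocities: np.ndarray
    active: int
    coefficients: np.ndarray  # adiabatic, unit norm
    u_cumulative: np.ndarray  # U(0, t)
    eigenvectors: np.ndarray  # W(t), gauge-continuous
    aux: deco.AuxiliaryBundle | None
    e_total: float


@dataclass
class RawEnsemble:
    """Recorded trajectory-ensemble time series (leading axis = trajectory)."""

    t: np.ndarray  # (T,)
    coeffs: np.ndarray  # (N, T, n) complex adiabatic coefficients
    active: np.ndarray  # (N, T) int
    e_tot: np.ndarray  # (N, T)
    positions: np.ndarray | None  # (N, T, d)
    drift: np.ndarray  # (N,) max_t |E_tot(t) - E_tot(0)| over *all* steps
    init_active: np.ndarray  # (N,)
    failed: np.ndarray  # (N,) bool
    hop_count: np.ndarray  # (N,)
    frustrated_count: np.ndarray  # (N,)
    base_seed: int | None = None
    aux_momenta: np.ndarray | None = None  # (N, T, n) when recorded
    hop_log: list | None = None  # [(t, traj, from, to, frustrated), ...]
    u_cumulative: np.ndarray | None = None  # (N, n, n) U(0, t_final)

    @property
    def n_traj(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_states(self) -> int:
        return self.coeffs.shape[2]

    def trajectory_frame(self, index: int):
        """Per-trajectory time series (t, R, active, Re/Im c_j, E_tot, P^aux)."""
        import pandas as pd

        data = {"t": self.t, "active": self.active[index],
                "e_tot": self.e_tot[index]}
        if self.positions is not None:
            for d in range(self.positions.shape[2]):
                data[f"x{d}"] = self.positions[index, :, d]
        for j in range(self.n_states):
            data[f"re_c{j}"] = self.coeffs[index, :, j].real
            data[f"im_c{j}"] = self.coeffs[index, :, j].imag
        if self.aux_momenta is not None:
            for j in range(self.n_states):
                data[f"p_aux{j}"] = self.aux_momenta[index, :, j]
        return pd.DataFrame(data)

    def to_hdf5(self, path) -> None:
        """Full ensemble record, with the hop log as a separate table."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = 1
            if self.base_seed is not None:
                f.attrs["base_seed"] = self.base_seed
            for name in ("t", "coeffs", "active", "e_tot", "drift",
                         "init_active", "failed", "hop_count",
                         "frustrated_count"):
                f.create_dataset(name, data=getattr(self, name))
            for name in ("positions", "aux_momenta", "u_cumulative"):
                val = getattr(self, name)
                if val is not None:
                    f.create_dataset(name, data=val)
            if self.hop_log:
                log = np.array([(t, tr, a, b, fr)
                                for t, tr, a, b, fr in self.hop_log])
                f.create_dataset("hop_log", data=log)


# ---------------------------------------------------------------------------
# Elementary operations (all batched over an optional leading axis)


def nuclear_step(positions, velocities, force, masses, dt):
    """First Velocity-Verlet half-step: end position and midpoint velocity."""
    v_half = velocities + 0.5 * dt * force / masses
    return positions + dt * v_half, v_half


def finish_nuclear_step(v_half, force_new, masses, dt):
    """Second Velocity-Verlet half-step: end-of-step velocity."""
    return v_half + 0.5 * dt * force_new / masses


def align_eigenvectors(w_prev, w_now):
    """Flip eigenvector column signs for temporal continuity."""
    diag = np.einsum("...ki,...ki->...i", w_now, w_prev)
    sign = np.where(diag < 0, -1.0, 1.0)
    return w_now * sign[..., None, :]


def electronic_overlap_and_nac(w_prev, w_now, dt):
    """State overlaps S_ij = <psi_i(t)|psi_j(t-dt)> and K = (1 - S)/dt.

    Eigenvector sign continuity is enforced first; the (possibly flipped)
    current eigenvectors are returned along with S and K.
    """
    w_prev = np.asarray(w_prev, dtype=float)
    w_now = np.asarray(w_now, dtype=float)
    if w_prev.shape != w_now.shape:
        raise ValueError("eigenvector matrices must have matching shapes")
    w_now = align_eigenvectors(w_prev, w_now)
    s = np.einsum("...ki,...kj->...ij", w_now, w_prev)
    eye = np.eye(s.shape[-1])
    k = (eye - s) / dt
    return s, k, w_now


def local_diabatization_matrix(s):
    """Closest orthogonal matrix to the overlap matrix S (polar decomposition).

    Column signs are fixed so the diagonal is non-negative; the cumulative
    diabatization matrix is maintained by the caller as
    U(0, t+dt) = U(t, t+dt) U(0, t).
    """
    s = np.asarray(s, dtype=float)
    u_svd, sv, vt = np.linalg.svd(s)
    if np.any(sv < 1e-8):
        raise np.linalg.LinAlgError("overlap matrix is (near-)singular")
    if np.any(np.abs(sv - 1.0) > 0.5):
        raise ValueError("overlap matrix too far from orthogonal")
    u = u_svd @ vt if s.ndim == 2 else np.einsum("...ij,...jk->...ik", u_svd, vt)
    diag = np.einsum("...ii->...i", u)
    sign = np.where(diag < 0, -1.0, 1.0)
    return u * sign[..., None, :]


def _orthogonal_powers(u, taus):
    """Fractional powers U^tau of orthogonal matrices for all tau at once.

    Geodesic interpolation between the identity and U along the rotation
    group: closed forms for 2x2 (rotation angle) and 3x3 (Rodrigues), the
    unitary eigen-decomposition of the normal matrix U otherwise.  Returns
    shape ``(len(taus),) + u.shape``; the last entry is replaced by U itself
    so the step endpoint is exact.
    """
    u = np.asarray(u, dtype=float)
    n = u.shape[-1]
    dets = np.linalg.det(u)
    if n == 2 and np.all(dets > 0):
        theta = np.arctan2(u[..., 1, 0], u[..., 0, 0])
        ang = np.multiply.outer(taus, theta)  # (S, N)
        c, s = np.cos(ang), np.sin(ang)
        out = np.empty((len(taus),) + u.shape)
        out[..., 0, 0] = c
        out[..., 0, 1] = -s
        out[..., 1, 0] = s
        out[..., 1, 1] = c
        out[-1] = u
        return out
    if n == 3 and np.all(dets > 0):
        w = 0.5 * np.stack([u[..., 2, 1] - u[..., 1, 2],
                            u[..., 0, 2] - u[..., 2, 0],
                            u[..., 1, 0] - u[..., 0, 1]], axis=-1)
        sin_t = np.linalg.norm(w, axis=-1)
        cos_t = 0.5 * (np.trace(u, axis1=-2, axis2=-1) - 1.0)
        theta = np.arctan2(sin_t, cos_t)
        if np.all((sin_t > 1e-12) | (cos_t > 0)):
            axis = w / np.where(sin_t > 1e-12, sin_t, 1.0)[..., None]
            k = np.zeros_like(u)
            k[..., 0, 1], k[..., 0, 2] = -axis[..., 2], axis[..., 1]
            k[..., 1, 0], k[..., 1, 2] = axis[..., 2], -axis[..., 0]
            k[..., 2, 0], k[..., 2, 1] = -axis[..., 1], axis[..., 0]
            k2 = k @ k
            ang = np.multiply.outer(taus, theta)[..., None, None]  # (S,N,1,1)
            out = np.eye(3) + np.sin(ang) * k + (1.0 - np.cos(ang)) * k2
            out[-1] = u
            return out
    # general / improper fallback: normal-matrix eigen-decomposition
    lam, z = np.linalg.eig(u)
    phi = np.angle(lam)
    phase = np.exp(1j * np.multiply.outer(taus, phi))  # (S, ..., n)
    out = np.real(np.einsum("...ij,s...j,...kj->s...ik", z, phase, z.conj()))
    out[-1] = u
    return out


def electronic_substep_propagation(c, h_start, h_end, dt, n_substeps=51,
                                   renormalize=True):
    """RK4 integration of i dc/dt = H(t) c with linearly interpolated H.

    ``H`` is the (generally non-Hermitian) local-diabatic generator
    V~ - i K~.  Returns the coefficients after ``n_substeps`` equal substeps
    covering ``dt``; the norm is restored after every substep when
    ``renormalize`` (the generator is anti-Hermitian up to the small residual
    coupling, so this is a tiny correction).
    """
    c = np.asarray(c, dtype=complex)
    h_start = np.asarray(h_start, dtype=complex)
    h_end = np.asarray(h_end, dtype=complex)
    if not (np.all(np.isfinite(h_start)) and np.all(np.isfinite(h_end))):
        raise ValueError("non-finite interpolant")
    ds = 1.0 / n_substeps
    dh = h_end - h_start
    for step in range(n_substeps):
        s0 = step * ds
        c = _rk4_substep(c, h_start, dh, s0, ds, dt)
        if renormalize:
            c = c / np.linalg.norm(c, axis=-1, keepdims=True)
    return c


def _rk4_substep(c, h0, dh, s0, ds, dt):
    """One RK4 substep of i dc/dt = (h0 + s dh) c, s the step fraction."""
    def deriv(cv, s):
        h = h0 + s * dh
        return -1j * dt * np.einsum("...ij,...j->...i", h, cv)

    k1 = deriv(c, s0)
    k2 = deriv(c + 0.5 * ds * k1, s0 + 0.5 * ds)
    k3 = deriv(c + 0.5 * ds * k2, s0 + 0.5 * ds)
    k4 = deriv(c + ds * k3, s0 + ds)
    return c + (ds / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def hop_probabilities(rho_before, rho_after, active):
    """Density-flux hopping probabilities between two substeps.

    P_{a->k} = [max(0, rho_aa - rho_aa') / rho_aa]
               * [max(0, d rho_kk) / sum_l max(0, d rho_ll)];
    all zero when the active population did not decrease (or is zero).
    """
    rb = np.atleast_2d(np.asarray(rho_before, dtype=float))
    ra = np.atleast_2d(np.asarray(rho_after, dtype=float))
    act = np.atleast_1d(np.asarray(active))
    idx = np.arange(rb.shape[0])
    loss = np.clip(rb[idx, act] - ra[idx, act], 0.0, None)
    gains = np.clip(ra - rb, 0.0, None)
    gains[idx, act] = 0.0
    tot = np.sum(gains, axis=1)
    denom_a = rb[idx, act]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(denom_a > 0, loss / np.where(denom_a > 0, denom_a, 1.0), 0.0)
        share = np.where(tot[:, None] > 0, gains / np.where(tot[:, None] > 0, tot[:, None], 1.0), 0.0)
    p = frac[:, None] * share
    if np.asarray(rho_before).ndim == 1:
        return p[0]
    return p


def fewest_switches_probabilities(c_ad, nac, active, dt):
    """Classic fewest-switches probabilities from coefficients and NAC."""
    c = np.atleast_2d(np.asarray(c_ad, dtype=complex))
    act = np.atleast_1d(np.asarray(active))
    idx = np.arange(c.shape[0])
    ca = c[idx, act]
    k_a = np.take_along_axis(nac, act[:, None, None], axis=1)[:, 0, :]  # K_{a k}
    flux = 2.0 * np.real(k_a * ca.conj()[:, None] * c)  # contribution to -d rho_aa
    flux[idx, act] = 0.0
    pop_a = np.abs(ca) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(pop_a[:, None] > 0,
                     np.clip(flux, 0.0, None) * dt / np.where(pop_a[:, None] > 0, pop_a[:, None], 1.0),
                     0.0)
    if np.asarray(c_ad).ndim == 1:
        return p[0]
    return p


def attempt_hop(active, probabilities, draw, energies, kinetic):
    """Cumulative-interval target selection with kinetic-energy frustration.

    Returns ``(new_active, hopped, frustrated)``.  A selected hop to state k
    is carried out only if E_a + T >= E_k; otherwise it is frustrated and the
    active state (and, elsewhere, the velocity) is left unchanged.
    """
    p = np.atleast_2d(np.asarray(probabilities, dtype=float))
    act = np.atleast_1d(np.asarray(active)).copy()
    r = np.atleast_1d(np.asarray(draw, dtype=float))
    e = np.atleast_2d(np.asarray(energies, dtype=float))
    t = np.atleast_1d(np.asarray(kinetic, dtype=float))
    idx = np.arange(p.shape[0])
    cum = np.cumsum(p, axis=1)
    selected = r < cum[:, -1]
    target = np.argmax(cum >= r[:, None], axis=1)
    allowed = e[idx, act] + t >= e[idx, target]
    hopped = selected & allowed
    frustrated = selected & ~allowed
    act[hopped] = target[hopped]
    if np.asarray(probabilities).ndim == 1:
        return int(act[0]), bool(hopped[0]), bool(frustrated[0])
    return act, hopped, frustrated


def hop_rescale_factor(delta_e, kinetic):
    """Isotropic velocity-rescaling factor sqrt(1 - dE/T) after a hop."""
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.where(kinetic > 0, 1.0 - delta_e / np.where(kinetic > 0, kinetic, 1.0), 0.0)
    return np.sqrt(np.clip(arg, 0.0, None))


# ---------------------------------------------------------------------------
# Batched propagation


class _DrawBuffer:
    """Per-trajectory uniform draws, consumed in trajectory-stream order."""

    def __init__(self, base_seed, n_traj, block=64, offset=0):
        self.gens = [np.random.default_rng(
            np.random.SeedSequence((base_seed, offset + i)))
            for i in range(n_traj)]
        self.block = block
        self._buf = None
        self._pos = 0

    def initial(self):
        """One uniform per trajectory (initial active-state collapse)."""
        return np.array([g.random() for g in self.gens])

    def substep_draws(self, n_substeps):
        """(N, n_substeps) uniforms, refilled in blocks of nuclear steps."""
        if self._buf is None or self._pos + n_substeps > self._buf.shape[1]:
            self._buf = np.stack([g.random(self.block * n_substeps)
                                  for g in self.gens])
            self._pos = 0
        out = self._buf[:, self._pos:self._pos + n_substeps]
        self._pos += n_substeps
        return out


def _decoherence_rate_matrix(cfg: DecoherenceConfig, paux, faux, energies, kinetic):
    """Pairwise rate matrix k[i, j] = damping rate of i against active j."""
    n = paux.shape[-1]
    if cfg.variant == "nd":
        return None
    if cfg.variant == "edc":
        gap = np.abs(energies[..., :, None] - energies[..., None, :])
        return deco.edc_rate(gap, kinetic[..., None, None], cfg.C)
    p_ij = paux[..., :, None] - paux[..., None, :]
    f_ij = faux[..., :, None] - faux[..., None, :]
    if cfg.variant in ("fm", "fmi"):
        return deco.fm_rate_1d(p_ij, f_ij, cfg.sigma, cfg.mu)
    return deco.pfm_rate(np.abs(p_ij), np.abs(f_ij), cfg.omega, cfg.n_d)


def prepare_initial_state(model: DiabaticModel, ensemble: InitialEnsemble,
                          basis: str = "diabatic"):
    """Adiabatic coefficients and eigenbasis at the initial geometries.

    Diabatic-basis amplitude specifications are transformed per trajectory by
    W^T(R(0)); because the transformation depends on the sampled geometry
    this produces small nonzero occupations of the other adiabatic states
    even at t = 0.
    """
    if ensemble.coefficients is None:
        raise ValueError("initial ensemble carries no electronic coefficients")
    r0 = ensemble.positions
    energies, w = adiabatize_batch(model.V(r0))
    if basis == "diabatic":
        c_ad = np.einsum("nji,nj->ni", w, ensemble.coefficients)
    elif basis == "adiabatic":
        c_ad = ensemble.coefficients.copy()
    else:
        raise ValueError(f"unknown basis {basis!r}")
    c_ad = c_ad / np.linalg.norm(c_ad, axis=1, keepdims=True)
    return c_ad, energies, w


def propagate_ensemble(model: DiabaticModel, ensemble: InitialEnsemble,
                       config: IntegratorConfig, n_steps: int, base_seed: int,
                       initial_basis: str = "diabatic", record_stride: int = 1,
                       record_positions: bool | None = None,
                       record_aux: bool = False,
                       stream_offset: int = 0) -> RawEnsemble:
    """Propagate all trajectories of ``ensemble`` for ``n_steps`` steps."""
    dcfg = config.decoherence
    dcfg.require_width()
    dt = config.dt
    n_sub = config.n_substeps
    sub_dt = dt / n_sub
    masses = model.masses
    sqrt_m = np.sqrt(masses)
    n_traj = ensemble.n_samples
    n_states = model.n_states
    idx = np.arange(n_traj)
    if record_positions is None:
        record_positions = model.n_dof <= 4

    r = ensemble.positions.copy()
    vel = ensemble.momenta / masses
    c_ad, e_prev, w_prev = prepare_initial_state(model, ensemble, initial_basis)

    draws = _DrawBuffer(base_seed, n_traj, offset=stream_offset)
    r0_draw = draws.initial()
    pops0 = np.abs(c_ad) ** 2
    cum0 = np.cumsum(pops0 / pops0.sum(axis=1, keepdims=True), axis=1)
    active = np.argmax(cum0 >= r0_draw[:, None], axis=1)
    init_active = active.copy()

    force = -batched_active_gradient(model, r, w_prev, active)
    kinetic = 0.5 * np.sum(masses * vel * vel, axis=1)
    e_tot0 = e_prev[idx, active] + kinetic
    # FM works with actual bond momenta/forces (diatomics); PFM with the
    # mass-weighted trajectory-velocity-projected scalars
    bond_aux = dcfg.variant in ("fm", "fmi")
    if bond_aux and model.n_dof != 1:
        raise ValueError("FM decoherence is defined for 1-D (diatomic) models; "
                         "use pfm/pfmi for multidimensional dynamics")
    paux = np.tile(deco.initial_aux_momentum(
        vel, masses, "bond" if bond_aux else "tvp")[:, None], (1, n_states))
    pop_prev = np.abs(c_ad) ** 2

    # recording
    rec_steps = list(range(0, n_steps + 1, record_stride))
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)
    rec_index = {s: k for k, s in enumerate(rec_steps)}
    n_rec = len(rec_steps)
    rec_t = np.array(rec_steps, dtype=float) * dt
    rec_c = np.empty((n_traj, n_rec, n_states), dtype=complex)
    rec_a = np.empty((n_traj, n_rec), dtype=np.int16)
    rec_e = np.empty((n_traj, n_rec))
    rec_r = np.empty((n_traj, n_rec, model.n_dof)) if record_positions else None
    rec_p = np.empty((n_traj, n_rec, n_states)) if record_aux else None
    hop_log: list = []

    def record(step_no, e_tot):
        k = rec_index.get(step_no)
        if k is None:
            return
        rec_c[:, k] = c_ad
        rec_a[:, k] = active
        rec_e[:, k] = e_tot
        if rec_r is not None:
            rec_r[:, k] = r
        if rec_p is not None:
            rec_p[:, k] = paux

    u_cum = np.tile(np.eye(n_states), (n_traj, 1, 1))
    drift = np.zeros(n_traj)
    failed = np.zeros(n_traj, dtype=bool)
    hop_count = np.zeros(n_traj, dtype=np.int64)
    frustrated_count = np.zeros(n_traj, dtype=np.int64)
    record(0, e_tot0)

    taus = np.arange(1, n_sub + 1) / n_sub
    eye = np.eye(n_states)

    for step in range(1, n_steps + 1):
        # i. first Velocity-Verlet half-step
        r_new, v_half = nuclear_step(r, vel, force, masses, dt)
        bad = ~np.all(np.isfinite(r_new), axis=1) | ~np.all(np.isfinite(v_half), axis=1)
        if np.any(bad & ~failed):
            failed |= bad
        if np.any(failed):
            r_new[failed] = r[failed]
            v_half[failed] = 0.0

        # ii. adiabatize at the new position, align gauge
        v_mat = model.V(r_new)
        bad_v = ~np.all(np.isfinite(v_mat), axis=(1, 2))
        if np.any(bad_v):
            # freeze diverged trajectories at their last valid geometry
            failed |= bad_v
            r_new[bad_v] = r[bad_v]
            v_half[bad_v] = 0.0
            v_mat[bad_v] = model.V(r[bad_v])
        e_new, w_raw = adiabatize_batch(v_mat)
        s_mat, nac, w_new = electronic_overlap_and_nac(w_prev, w_raw, dt)

        # iii. auxiliary forces from the forward energy derivative,
        #      midpoint velocity as the reference
        if bond_aux:
            v_ref = v_half[:, 0]
        else:
            v_ref = np.linalg.norm(v_half * sqrt_m, axis=1)
        faux = deco.tvp_force(e_prev, e_new, v_ref[:, None], dt, dcfg.kappa)

        # iv. local diabatization matrix for the step; cumulative
        #     U(0, t+dt) = U(t, t+dt) U(0, t)
        u_step = local_diabatization_matrix(s_mat)
        u_cum = np.einsum("nij,njk->nik", u_step, u_cum)
        u_taus = _orthogonal_powers(u_step, taus)  # (n_sub, N, n, n)

        # v. potential and residual coupling in the local diabatic basis
        v_end = np.einsum("nij,ni,nik->njk", u_step, e_new, u_step)
        k_end = (eye - np.einsum("nji,njk->nik", u_step, s_mat)) / dt
        h_start = (eye * e_prev[:, None, :]).astype(complex)
        h_end = v_end - 1j * k_end
        dh = h_end - h_start

        # decoherence rates for this step, from step-start auxiliary data;
        # the per-substep damping factors e^{-k dt_sub} are constant across
        # the substeps and precomputed as a matrix over (state, active) pairs
        rate_matrix = _decoherence_rate_matrix(dcfg, paux, faux, e_prev, kinetic)
        damp = None
        if rate_matrix is not None:
            damp = np.exp(-np.clip(rate_matrix, 0.0, None) * sub_dt)

        t_half = 0.5 * np.sum(masses * v_half * v_half, axis=1)
        sub_draws = draws.substep_draws(n_sub)
        active_start = active.copy()
        ds = 1.0 / n_sub
        # generator -i dt H at the 2*n_sub+1 RK4 stage nodes, and the
        # adiabatic energies interpolated to the substep end points
        coef = (np.arange(2 * n_sub + 1) * (0.5 * ds))[:, None, None, None]
        a_nodes = (-1j * dt) * (h_start[None] + coef * dh[None])
        e_taus = e_prev[None] + taus[:, None, None] * (e_new - e_prev)[None]

        c_tilde = c_ad.astype(complex)
        c_sub = c_tilde
        pops_sub = np.abs(c_ad) ** 2
        log_hops = n_traj <= 16
        for s in range(n_sub):
            # A. one RK4 substep in the local diabatic basis
            aa, am, ae = a_nodes[2 * s], a_nodes[2 * s + 1], a_nodes[2 * s + 2]
            k1 = np.einsum("nij,nj->ni", aa, c_tilde)
            k2 = np.einsum("nij,nj->ni", am, c_tilde + (0.5 * ds) * k1)
            k3 = np.einsum("nij,nj->ni", am, c_tilde + (0.5 * ds) * k2)
            k4 = np.einsum("nij,nj->ni", ae, c_tilde + ds * k3)
            c_tilde = c_tilde + (ds / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            nrm = np.einsum("ni,ni->n", c_tilde.conj(), c_tilde).real
            good = np.isfinite(nrm) & (nrm > 0)
            c_tilde = c_tilde / np.sqrt(np.where(good, nrm, 1.0))[:, None]
            # B. transform to the adiabatic basis at the substep time
            u_tau = u_taus[s]
            c_sub = np.einsum("nij,nj->ni", u_tau, c_tilde)
            pops_new = c_sub.real ** 2 + c_sub.imag ** 2
            # C./D. hopping
            if config.hop_scheme == "density_flux":
                pa_prev = pops_sub[idx, active]
                loss = pa_prev - pops_new[idx, active]
                gains = pops_new - pops_sub
                np.clip(gains, 0.0, None, out=gains)
                gains[idx, active] = 0.0
                tot = gains.sum(axis=1)
                denom = pa_prev * tot
                scale_p = np.where((loss > 0) & (denom > 0),
                                   np.clip(loss, 0.0, None) /
                                   np.where(denom > 0, denom, 1.0), 0.0)
                probs = gains * scale_p[:, None]
            else:
                nac_sub = np.einsum("nij,njk,nlk->nil", u_tau, nac, u_tau)
                probs = fewest_switches_probabilities(c_sub, nac_sub, active, sub_dt)
            cum = np.cumsum(probs, axis=1)
            r = sub_draws[:, s]
            sel = r < cum[:, -1]
            if np.any(sel):
                target = np.argmax(cum >= r[:, None], axis=1)
                e_interp = e_taus[s]
                allowed = e_interp[idx, active] + t_half >= e_interp[idx, target]
                hopped = sel & allowed
                frus = sel & ~allowed
                if log_hops:
                    t_sub = (step - 1) * dt + (s + 1) * sub_dt
                    for tr in np.nonzero(sel)[0]:
                        hop_log.append((t_sub, int(tr), int(active[tr]),
                                        int(target[tr]), bool(frus[tr])))
                hop_count += hopped
                frustrated_count += frus
                active = np.where(hopped, target, active)
            # E. decoherence correction on the adiabatic coefficients
            if damp is not None:
                dmp = damp[idx, :, active]  # (N, n): damping of i vs active
                c_sub = c_sub * dmp
                ca = c_sub[idx, active]
                ca_abs2 = ca.real ** 2 + ca.imag ** 2
                inact = (c_sub.real ** 2 + c_sub.imag ** 2).sum(axis=1) - ca_abs2
                scale_a = np.where(ca_abs2 > 0,
                                   np.sqrt(np.clip(1.0 - inact, 0.0, None) /
                                           np.where(ca_abs2 > 0, ca_abs2, 1.0)),
                                   1.0)
                c_sub[idx, active] = ca * scale_a
                c_tilde = np.einsum("nji,nj->ni", u_tau, c_sub)
                pops_sub = c_sub.real ** 2 + c_sub.imag ** 2
            else:
                pops_sub = pops_new
        # the last substep sits exactly at the step end (u_taus[-1] = U)
        c_ad = c_sub if damp is not None else np.einsum(
            "nij,nj->ni", u_taus[-1], c_tilde)

        # viii. second Velocity-Verlet half-step on the (new) active surface
        force_new = -batched_active_gradient(model, r_new, w_new, active)
        force_new[failed] = 0.0
        vel_new = finish_nuclear_step(v_half, force_new, masses, dt)

        # ix. isotropic velocity rescaling when the active surface changed
        t_new = 0.5 * np.sum(masses * vel_new * vel_new, axis=1)
        hop_happened = active != active_start
        delta_e = e_new[idx, active] + t_new - (e_prev[idx, active_start] + kinetic)
        scale = np.where(hop_happened, hop_rescale_factor(delta_e, t_new), 1.0)
        vel_new = vel_new * scale[:, None]
        t_after = 0.5 * np.sum(masses * vel_new * vel_new, axis=1)

        # x./xi. auxiliary-momentum propagation (with optional injection)
        pop_new = np.abs(c_ad) ** 2
        paux = deco.aux_momentum_update(paux, faux, pop_prev, pop_new, e_new,
                                        t_after, active_start, active, scale,
                                        dt, dcfg.eta, dcfg.injection)

        # xii. collapse inactive populations that fell below the threshold
        if dcfg.variant in ("fm", "fmi", "pfm", "pfmi"):
            c_ad = deco.collapse_subthreshold(c_ad, active, pop_prev, dcfg.eta)
            pop_new = np.abs(c_ad) ** 2

        r, vel, kinetic = r_new, vel_new, t_after
        e_prev, w_prev, force, pop_prev = e_new, w_new, force_new, pop_new
        e_tot = e_prev[idx, active] + kinetic
        drift = np.maximum(drift, np.abs(e_tot - e_tot0))
        record(step, e_tot)

    return RawEnsemble(
        t=rec_t, coeffs=rec_c, active=rec_a, e_tot=rec_e, positions=rec_r,
        drift=drift, init_active=init_active, failed=failed,
        hop_count=hop_count, frustrated_count=frustrated_count,
        base_seed=base_seed, aux_momenta=rec_p,
        hop_log=hop_log if hop_log or n_traj <= 16 else None,
        u_cumulative=u_cum)


def run_trajectory(model: DiabaticModel, positions, momenta, amplitudes,
                   config: IntegratorConfig, n_steps: int, seed: int,
                   initial_basis: str = "diabatic",
                   trajectory_index: int = 0) -> RawEnsemble:
    """Propagate a single trajectory with full recording.

    ``seed`` is the ensemble base seed; the trajectory draws its RNG stream
    from ``(seed, trajectory_index)`` exactly as it would inside an ensemble
    run, so the result matches the corresponding member of a batched run
    bit for bit.
    """
    amp = np.asarray(amplitudes, dtype=complex)
    ens = InitialEnsemble(np.atleast_2d(positions), np.atleast_2d(momenta),
                          (amp / np.linalg.norm(amp))[None, :])
    return propagate_ensemble(model, ens, config, n_steps, seed,
                              initial_basis=initial_basis, record_stride=1,
                              record_positions=True, record_aux=True,
                              stream_offset=trajectory_index)
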