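"""Electronic decoherence corrections for surface-hopping trajectories.

Implements the first-order nuclear-overlap decay rates and the auxiliary
force/momentum machinery that feeds them:

* ``edc_rate`` — energy-based decoherence correction,
  k = |E_ia| * T / (T + C);
* ``fm_rate_1d`` — forces-and-momenta rate for a diatomic,
  k = (sigma^2/2) (p f + |p| sqrt(f^2 + 1/(mu^2 sigma^6)))
  with p, f the bond momentum/force differences between the two surfaces;
* ``pfm_rate`` — projected-forces-and-momenta rate for N_D > 1,
  k = (pi^2/(8 omega)) |P| |F| + |P| sqrt(pi^2 N_D omega / 8),
  built from the mass-weighted trajectory-velocity-projected (TVP) force and
  momentum differences, with the |cos| projection angle replaced by its
  isotropic average 2/pi;
* ``fm_rate_normal_modes`` — the per-mode rate the 1-D and PFM expressions
  descend from (kept as an independent cross-check, not used in propagation).

The TVP auxiliary forces are numerical forward time derivatives of the
potential energies divided by the reference velocity (``tvp_force``); the
auxiliary momenta follow classical equations of motion with births, deaths
and optional injection of rescaled active-surface momentum whenever an
inactive population grows (``aux_momentum_update``) — the "i" in FMi/PFMi.

All rate functions accept scalars or broadcastable arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DecoherenceConfig",
    "AuxiliaryBundle",
    "edc_rate",
    "fm_rate_1d",
    "pfm_rate",
    "fm_rate_normal_modes",
    "tvp_force",
    "initial_aux_momentum",
    "aux_momentum_update",
    "apply_decoherence",
    "collapse_subthreshold",
]

VARIANTS = ("nd", "edc", "fm", "fmi", "pfm", "pfmi")


@dataclass
class DecoherenceConfig:
    """Decoherence variant and its parameters (atomic units).

    eta is the inactive-population threshold above which a state is assumed
    to carry its own wave packet; kappa the velocity threshold below which
    auxiliary forces are zeroed; C the EDC kinetic-energy parameter; sigma/mu
    the 1-D packet width and reduced mass (FM); omega/n_d the common
    frequency and mode count (PFM).
    """

    variant: str = "fmi"
    eta: float = 1e-4
    kappa: float = 1e-9
    C: float = 0.1
    sigma: float | None = None
    mu: float | None = None
    omega: float | None = None
    n_d: int | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown decoherence variant {self.variant!r}; "
                             f"choose from {VARIANTS}")
        for name in ("eta", "kappa", "C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # sigma/omega may stay None at construction (filled from the sampled
        # ensemble / normal modes before propagation); if given, be positive
        if self.variant in ("fm", "fmi"):
            for name in ("sigma", "mu"):
                val = getattr(self, name)
                if val is not None and val <= 0:
                    raise ValueError(f"FM decoherence requires positive {name}")
        if self.variant in ("pfm", "pfmi"):
            if self.omega is not None and self.omega <= 0:
                raise ValueError("PFM decoherence requires positive omega")
            if self.n_d is not None and self.n_d < 1:
                raise ValueError("PFM decoherence requires n_d >= 1")

    def require_width(self):
        """Check that the width parameters of the chosen variant are set."""
        if self.variant in ("fm", "fmi") and not (self.sigma and self.mu):
            raise ValueError("FM decoherence requires sigma and mu")
        if self.variant in ("pfm", "pfmi") and not (self.omega and self.n_d):
            raise ValueError("PFM decoherence requires omega and n_d")

    @property
    def injection(self) -> bool:
        return self.variant in ("fmi", "pfmi")


@dataclass
class AuxiliaryBundle:
    """Per-state auxiliary momenta and their threshold bookkeeping."""

    momenta: np.ndarray  # (..., n_states) scalar auxiliary momenta
    prev_populations: np.ndarray  # (..., n_states)
    eta: float = 1e-4
    kappa: float = 1e-9

    @property
    def above_threshold(self) -> np.ndarray:
        return self.prev_populations >= self.eta


# ---------------------------------------------------------------------------
# Rates


def edc_rate(e_gap_abs, kinetic, c=0.1):
    """Energy-based decoherence rate |E_ia| * T / (T + C)."""
    e_gap_abs = np.abs(e_gap_abs)
    return e_gap_abs * kinetic / (kinetic + c)


def fm_rate_1d(p_ij, f_ij, sigma, mu):
    """1-D forces-and-momenta rate from bond momentum/force differences."""
    root = np.sqrt(f_ij * f_ij + 1.0 / (mu * mu * sigma ** 6))
    return 0.5 * sigma * sigma * (p_ij * f_ij + np.abs(p_ij) * root)


def pfm_rate(p_abs, f_abs, omega, n_d):
    """Projected-forces-and-momenta rate from |TVP| differences (N_D >= 1)."""
    p_abs = np.abs(p_abs)
    f_abs = np.abs(f_abs)
    return (np.pi ** 2 / (8.0 * omega)) * p_abs * f_abs \
        + p_abs * np.sqrt(np.pi ** 2 * n_d * omega / 8.0)


def fm_rate_normal_modes(qdot_ij, qddot_ij, omegas):
    """Per-mode rate sum_a (1/4 w_a)(qd qdd + |qd| sqrt(qdd^2 + 8 w_a^3)).

    Independent reference form in mass-weighted normal-mode coordinates;
    the 1-D rate is its single-mode special case under
    qdot = p/sqrt(mu), qddot = f/sqrt(mu), omega = 1/(2 mu sigma^2).
    """
    qdot_ij = np.asarray(qdot_ij, dtype=float)
    qddot_ij = np.asarray(qddot_ij, dtype=float)
    omegas = np.asarray(omegas, dtype=float)
    root = np.sqrt(qddot_ij ** 2 + 8.0 * omegas ** 3)
    terms = (qdot_ij * qddot_ij + np.abs(qdot_ij) * root) / (4.0 * omegas)
    return np.sum(terms, axis=-1)


# ---------------------------------------------------------------------------
# Auxiliary forces and momenta


def tvp_force(e_now, e_next, v_ref, dt, kappa=1e-9):
    """Auxiliary force from the forward time derivative of the energy.

    F = -(E(t+dt) - E(t)) / (v dt), zeroed where |v| < kappa.  ``v_ref`` is
    the mass-weighted speed (multi-D TVP) or the signed bond velocity (1-D);
    it broadcasts against the state axis of the energies.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    e_now = np.asarray(e_now, dtype=float)
    e_next = np.asarray(e_next, dtype=float)
    v = np.asarray(v_ref, dtype=float)
    small = np.abs(v) < kappa
    safe_v = np.where(small, 1.0, v)
    force = -(e_next - e_now) / (safe_v * dt)
    return np.where(small, 0.0, force)


def initial_aux_momentum(velocities, masses, convention):
    """Common initial auxiliary momentum P^aux(0) for every state.

    ``convention='bond'`` (FM, diatomics): the actual bond momentum
    mu * rdot(0), signed.  ``convention='tvp'`` (PFM): the mass-weighted
    trajectory-velocity-projected momentum Qdot . e_vm = |Qdot|.
    """
    v = np.atleast_2d(np.asarray(velocities, dtype=float))
    if convention == "bond":
        if v.shape[-1] != 1:
            raise ValueError("bond-momentum convention requires one dof")
        return masses[0] * v[..., 0]
    if convention == "tvp":
        return np.linalg.norm(v * np.sqrt(masses), axis=-1)
    raise ValueError(f"unknown auxiliary-momentum convention {convention!r}")


def _rescale_term(p_active, e_i, e_active, kinetic):
    """Active momentum rescaled for an energy-conserving transfer,
    P_a * sqrt(max{0, 1 - E_ia/T})."""
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = 1.0 - (e_i - e_active[..., None]) / kinetic[..., None]
    arg = np.where(kinetic[..., None] > 0, arg, 0.0)
    return p_active[..., None] * np.sqrt(np.clip(arg, 0.0, None))


def aux_momentum_update(paux, faux, pop_prev, pop_new, energies, kinetic,
                        active_prev, active_new, hop_scale, dt, eta,
                        injection):
    """One nuclear-step update of all per-state auxiliary momenta.

    Works on batches: every array argument has a leading trajectory axis
    (use shape (1, ...) for a single trajectory).

    * active state: P <- P[a_prev] + F[a_new] dt (continuity across hops),
      multiplied by the isotropic-rescaling factor ``hop_scale`` (1 when no
      hop occurred);
    * inactive states above the population threshold at both step ends:
      classical propagation P <- P + F dt, optionally blending in rescaled
      active momentum proportional to the population gained (``injection``);
    * inactive states below threshold at either end: reset to the rescaled
      active value (covers deaths and supplies the birth initial condition).
    """
    paux = np.asarray(paux, dtype=float)
    n = paux.shape[-1]
    idx = np.arange(paux.shape[0])

    p_active_new = (paux[idx, active_prev] + faux[idx, active_new] * dt) * hop_scale

    e_active = energies[idx, active_new]
    resc = _rescale_term(p_active_new, energies, e_active, kinetic)  # (N, n)

    above = (pop_prev >= eta) & (pop_new >= eta)
    propagated = paux + faux * dt
    if injection:
        drho = np.clip(pop_new - pop_prev, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(pop_new > 0, drho / pop_new, 0.0)
        propagated = propagated * (1.0 - w) + w * resc

    out = np.where(above, propagated, resc)
    out[idx, active_new] = p_active_new
    return out


# ---------------------------------------------------------------------------
# Coefficient damping


def apply_decoherence(coefficients, rates, active, dt):
    """Damp inactive coefficients and rescale the active one (norm -> 1).

    c_i <- c_i exp(-k_ia dt) for i != a; |c_a| is then scaled so the total
    norm is exactly one, keeping its phase.  Batched over a leading axis.
    Raises when the active amplitude vanishes while damping is requested
    (the renormalization would be ill-posed).
    """
    arr = np.asarray(coefficients, dtype=complex)
    single = arr.ndim == 1
    c = np.atleast_2d(arr).copy()
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    active = np.atleast_1d(np.asarray(active))
    idx = np.arange(c.shape[0])
    damp = np.exp(-np.clip(rates, 0.0, None) * dt)
    damp[idx, active] = 1.0
    c *= damp
    ca = c[idx, active]
    inactive_pop = np.sum(np.abs(c) ** 2, axis=1) - np.abs(ca) ** 2
    any_damping = np.any(damp < 1.0, axis=1)
    if np.any((np.abs(ca) == 0) & any_damping):
        raise ZeroDivisionError("active coefficient vanished; cannot rescale")
    scale = np.where(np.abs(ca) > 0,
                     np.sqrt(np.clip(1.0 - inactive_pop, 0.0, None)) /
                     np.where(np.abs(ca) > 0, np.abs(ca), 1.0),
                     1.0)
    c[idx, active] = ca * scale
    return c[0] if single else c


def collapse_subthreshold(coefficients, active, pop_prev, eta):
    """Move fully-decohered residual population onto the active state.

    For inactive states whose population crossed below ``eta`` during the
    step (was >= eta before, is < eta now), the residual |c_i|^2 is added to
    the active state (phase kept) and c_i is zeroed.
    """
    arr = np.asarray(coefficients, dtype=complex)
    single = arr.ndim == 1
    c = np.atleast_2d(arr).copy()
    pop_prev = np.atleast_2d(np.asarray(pop_prev, dtype=float))
    active = np.atleast_1d(np.asarray(active))
    idx = np.arange(c.shape[0])
    pop_now = np.abs(c) ** 2
    dead = (pop_prev >= eta) & (pop_now < eta)
    dead[idx, active] = False
    moved = np.sum(pop_now * dead, axis=1)
    ca = c[idx, active]
    ca_pop = np.abs(ca) ** 2
    scale = np.sqrt(np.where(ca_pop > 0, 1.0 + moved / np.where(ca_pop > 0, ca_pop, 1.0), 1.0))
    c[idx, active] = ca * scale
    c[dead] = 0.0
    return c[0] if single else c
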