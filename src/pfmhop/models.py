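"""Analytic diabatic model Hamiltonians, their adiabatization and gradients.

A :class:`DiabaticModel` bundles a real-symmetric diabatic potential matrix
``V(R)`` (hartree), its gradient tensor ``dV(R)`` (hartree/bohr) and the
nuclear masses (electron masses).  Both callables are vectorized: for input
of shape ``(..., n_dof)`` they return ``(..., n_states, n_states)`` and
``(..., n_states, n_states, n_dof)``.  This lets the same model definition
serve grid-based quantum propagation (batch over grid points) and
trajectory-ensemble propagation (batch over trajectories).

Shipped presets
---------------
``avoided_crossing_2s``
    Two-state single avoided crossing in one dimension (scattering), with
    exponential-step diagonal terms of opposite sign and a Gaussian coupling.
``ibr_surrogate_3s``
    Three-state 1-D surrogate of a heavy diatomic interhalogen: a bound Morse
    ground state, a bound excited diabat crossed on its outer limb by a
    repulsive diabat, and a constant coupling between the two excited states
    (the ground state is a spectator).  The crossing sits away from the
    Franck-Condon point so that a promoted wave packet reaches it only after
    several tens of fs and splits into two dissociation channels.
``tully3_sloped``
    Extended-coupling sloped-crossing model (flat diabats, exponentially
    saturating coupling), the classic "model III" reflection benchmark.
``lvc_nd``
    Two-state, three-mode linear vibronic coupling model in mass-weighted
    normal-mode coordinates (multidimensional test bed, ``n_D > 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .units import AMU_TO_ME

__all__ = [
    "NormalModeSpec",
    "AdiabaticPoint",
    "DiabaticModel",
    "DegenerateCrossingError",
    "build_model",
    "adiabatize",
    "adiabatize_batch",
    "adiabatic_gradient",
    "PRESETS",
]

#: Energy-gap tolerance below which Hellmann-Feynman gradients are refused.
DEGENERACY_TOL = 1e-10


class DegenerateCrossingError(RuntimeError):
    """Raised when adiabatic states are degenerate at the requested point."""


@dataclass(frozen=True)
class NormalModeSpec:
    """Harmonic normal modes: frequencies > 0 and orthonormal mode vectors.

    ``mode_vectors`` has shape ``(n_dof, n_modes)``; columns are orthonormal
    in the mass-weighted frame.  Only modes with nonzero frequency are stored
    (translations/rotations are removed before construction).
    """

    frequencies: np.ndarray
    mode_vectors: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        freq = np.asarray(self.frequencies, dtype=float)
        vecs = np.asarray(self.mode_vectors, dtype=float)
        masses = np.asarray(self.masses, dtype=float)
        if freq.ndim != 1 or np.any(freq <= 0):
            raise ValueError("normal-mode frequencies must be strictly positive")
        if vecs.shape != (masses.size, freq.size):
            raise ValueError("mode_vectors must have shape (n_dof, n_modes)")
        gram = vecs.T @ vecs
        if not np.allclose(gram, np.eye(freq.size), atol=1e-10):
            raise ValueError("mode vectors must be orthonormal to 1e-10")
        object.__setattr__(self, "frequencies", freq)
        object.__setattr__(self, "mode_vectors", vecs)
        object.__setattr__(self, "masses", masses)

    @property
    def n_d(self) -> int:
        return self.frequencies.size


@dataclass(frozen=True)
class AdiabaticPoint:
    """Eigen-decomposition of the diabatic potential at one position.

    ``energies`` ascend; columns of ``transformation`` are the adiabatic
    eigenvectors expressed in the diabatic basis, sign-gauged so that the
    largest-magnitude component of each column is positive.
    """

    energies: np.ndarray
    transformation: np.ndarray
    position: np.ndarray | None = None


@dataclass
class DiabaticModel:
    """Analytic diabatic potential matrix with gradients and masses."""

    name: str
    n_states: int
    n_dof: int
    masses: np.ndarray
    V: Callable[[np.ndarray], np.ndarray]
    dV: Callable[[np.ndarray], np.ndarray]
    operators: dict[str, Callable[[np.ndarray], np.ndarray]] = field(default_factory=dict)
    normal_modes: NormalModeSpec | None = None
    #: Optional preset metadata (initial-condition defaults etc.).
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (self.n_dof,) or np.any(self.masses <= 0):
            raise ValueError("need one positive mass per degree of freedom")

    @property
    def reduced_mass(self) -> float:
        """Mass of the single coordinate (only meaningful for 1-D models)."""
        if self.n_dof != 1:
            raise ValueError("reduced_mass is defined for 1-D models only")
        return float(self.masses[0])

    def check_symmetry(self, positions: np.ndarray) -> float:
        v = self.V(np.asarray(positions, dtype=float))
        return float(np.max(np.abs(v - np.swapaxes(v, -1, -2))))


# ---------------------------------------------------------------------------
# Pointwise algebra


def _sign_gauge(w: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component of each eigenvector column positive."""
    idx = np.argmax(np.abs(w), axis=-2)
    picked = np.take_along_axis(w, idx[..., None, :], axis=-2)[..., 0, :]
    sign = np.where(picked < 0.0, -1.0, 1.0)
    return w * sign[..., None, :]


def adiabatize_batch(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched eigen-decomposition (ascending energies, gauged eigenvectors)."""
    v = np.asarray(v, dtype=float)
    if not np.allclose(v, np.swapaxes(v, -1, -2), atol=1e-12):
        raise ValueError("diabatic potential matrix must be symmetric")
    energies, w = np.linalg.eigh(v)
    return energies, _sign_gauge(w)


def adiabatize(v: np.ndarray, position: np.ndarray | None = None) -> AdiabaticPoint:
    """Adiabatize a single diabatic potential matrix."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("expected a square matrix")
    energies, w = adiabatize_batch(v)
    return AdiabaticPoint(energies=energies, transformation=w, position=position)


def adiabatic_gradient(model: DiabaticModel, position: np.ndarray, state: int) -> np.ndarray:
    """Hellmann-Feynman gradient of adiabatic energy ``E_state`` at ``position``.

    grad E_i = w_i^T (dV) w_i.  Raises :class:`DegenerateCrossingError` when
    the state is degenerate with a neighbour (gap below 1e-10 hartree); the
    caller may then fall back to finite differences of the adiabatized
    energies.
    """
    position = np.atleast_1d(np.asarray(position, dtype=float))
    energies, w = adiabatize_batch(model.V(position))
    gaps = np.diff(energies)
    lo = gaps[state - 1] if state > 0 else np.inf
    hi = gaps[state] if state < model.n_states - 1 else np.inf
    if min(lo, hi) < DEGENERACY_TOL:
        raise DegenerateCrossingError(
            f"states degenerate at {position} (gap < {DEGENERACY_TOL:g} hartree)"
        )
    dv = model.dV(position)
    wi = w[:, state]
    return np.einsum("j,jkd,k->d", wi, dv, wi)


def batched_active_gradient(model: DiabaticModel, positions: np.ndarray,
                            w: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Gradient of the active adiabatic energy for a batch of trajectories.

    ``positions``: (N, n_dof); ``w``: (N, n, n) gauged eigenvectors;
    ``active``: (N,) state indices.  Returns (N, n_dof).
    """
    dv = model.dV(positions)  # (N, n, n, d)
    wa = np.take_along_axis(w, active[:, None, None], axis=2)[:, :, 0]  # (N, n)
    return np.einsum("nj,njkd,nk->nd", wa, dv, wa)


# ---------------------------------------------------------------------------
# Functional forms for table-built models

def _diag_term(form: str, p: Mapping[str, float]):
    """Return (f, df) callables for a diagonal diabatic term, x of shape (...,)."""
    if form == "harmonic":
        k, x0, e0 = p["k"], p.get("x0", 0.0), p.get("e0", 0.0)
        return (lambda x: e0 + 0.5 * k * (x - x0) ** 2,
                lambda x: k * (x - x0))
    if form == "morse":
        d, a, x0, e0 = p["d"], p["a"], p.get("x0", 0.0), p.get("e0", 0.0)

        def f(x):
            g = 1.0 - np.exp(-a * (x - x0))
            return e0 + d * g * g

        def df(x):
            e = np.exp(-a * (x - x0))
            return 2.0 * d * (1.0 - e) * a * e

        return f, df
    if form == "exponential":
        # Repulsive wall decaying to an asymptote: e0 + amp * exp(-a (x - x0))
        amp, a, x0, e0 = p["amp"], p["a"], p.get("x0", 0.0), p.get("e0", 0.0)
        return (lambda x: e0 + amp * np.exp(-a * (x - x0)),
                lambda x: -a * amp * np.exp(-a * (x - x0)))
    if form == "constant":
        e0 = p.get("e0", 0.0)
        return (lambda x: e0 + 0.0 * x, lambda x: 0.0 * x)
    raise ValueError(f"unknown diagonal form {form!r}")


def _coupling_term(form: str, p: Mapping[str, float]):
    if form == "constant":
        c = p["value"]
        return (lambda x: c + 0.0 * x, lambda x: 0.0 * x)
    if form == "gaussian":
        c, b, x0 = p["value"], p["width"], p.get("x0", 0.0)
        return (lambda x: c * np.exp(-b * (x - x0) ** 2),
                lambda x: -2.0 * b * (x - x0) * c * np.exp(-b * (x - x0) ** 2))
    raise ValueError(f"unknown coupling form {form!r}")


def _model_from_table(table: Mapping) -> DiabaticModel:
    """Build a 1-D model from a parameter table (see config docs)."""
    states = table["states"]
    n = len(states)
    if n < 2:
        raise ValueError("need at least two states")
    masses = table.get("masses")
    if masses is None:
        raise ValueError("missing mass specification")
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    if table.get("masses_in_amu", False):
        masses = masses * AMU_TO_ME

    diag = [_diag_term(s["form"], s) for s in states]
    seen: dict[tuple[int, int], Mapping] = {}
    for cpl in table.get("couplings", []):
        i, j = int(cpl["i"]), int(cpl["j"])
        if i == j or not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"invalid coupling indices ({i},{j})")
        key = (min(i, j), max(i, j))
        if key in seen:
            prev = seen[key]
            same = prev.get("form") == cpl.get("form") and all(
                prev.get(k) == cpl.get(k) for k in ("value", "width", "x0")
            )
            if not same:
                raise ValueError(
                    f"coupling table not symmetric: V{key} given twice with different values"
                )
            continue
        seen[key] = cpl
    cpls = {key: _coupling_term(c["form"], c) for key, c in seen.items()}

    def V(r):
        x = np.asarray(r, dtype=float)[..., 0]
        out = np.zeros(x.shape + (n, n))
        for s, (f, _) in enumerate(diag):
            out[..., s, s] = f(x)
        for (i, j), (f, _) in cpls.items():
            out[..., i, j] = out[..., j, i] = f(x)
        return out

    def dV(r):
        x = np.asarray(r, dtype=float)[..., 0]
        out = np.zeros(x.shape + (n, n, 1))
        for s, (_, df) in enumerate(diag):
            out[..., s, s, 0] = df(x)
        for (i, j), (_, df) in cpls.items():
            out[..., i, j, 0] = out[..., j, i, 0] = df(x)
        return out

    return DiabaticModel(name=table.get("name", "table"), n_states=n, n_dof=1,
                         masses=masses, V=V, dV=dV)


# ---------------------------------------------------------------------------
# Presets


_AVOIDED_CROSSING_TABLE = {
    "name": "avoided_crossing_2s",
    "masses": [20000.0],  # medium-weight diatomic reduced mass
    "states": [
        # Bound diabat; a narrow packet launched on its inner wall at
        # x0 = 2.6 bohr crosses the repulsive diabat on the outer limb.
        {"form": "morse", "d": 0.03, "a": 1.2, "x0": 3.0, "e0": 0.0},
        # Repulsive diabat, dissociating below the packet energy.
        {"form": "exponential", "amp": 0.0282, "a": 1.6, "x0": 2.6, "e0": 0.002},
    ],
    "couplings": [
        {"i": 0, "j": 1, "form": "constant", "value": 0.0015},
    ],
}


def _make_avoided_crossing_2s() -> DiabaticModel:
    """Two-state predissociation-style avoided crossing (constant coupling).

    A Gaussian packet (sigma = 0.05 bohr) promoted onto the bound diabat's
    inner wall rolls through the crossing at ~3.6 bohr and splits between
    the bound and the dissociative channel.
    """
    model = _model_from_table(_AVOIDED_CROSSING_TABLE)
    model.meta = {
        "initial": {"x0": 2.6, "p0": 0.0, "sigma_x": 0.05, "state": 0,
                    "basis": "diabatic"},
        "grid": {"x_min": 1.4, "x_max": 9.0, "n_points": 1024},
        "t_final_fs": 50.0,
        "dt_fs": 0.1,
    }
    return model


#: Reduced mass of an I-Br pair (126.90447 and 78.9183 amu), electron masses.
IBR_REDUCED_MASS = (126.90447 * 78.9183) / (126.90447 + 78.9183) * AMU_TO_ME

_IBR_TABLE = {
    "name": "ibr_surrogate_3s",
    "masses": [IBR_REDUCED_MASS],
    "states": [
        # Bound ground state; curvature chosen so the ground-state bond-length
        # spread is ~7e-2 bohr for this reduced mass (omega ~ 1.18e-3 a.u.).
        {"form": "morse", "d": 0.06, "a": 1.0162, "x0": 4.666, "e0": 0.0},
        # Bound excited diabat with a shallower, displaced well; a packet
        # promoted at the ground-state minimum starts on its inner wall with
        # enough energy to traverse the outer-limb crossing.
        {"form": "morse", "d": 0.03, "a": 1.0, "x0": 5.3, "e0": 0.070},
        # Repulsive diabat crossing state 1 on its outer limb (~6.0 bohr,
        # well outside the Franck-Condon region) and dissociating to the
        # same asymptotic region.
        {"form": "exponential", "amp": 0.219, "a": 1.6, "x0": 3.9, "e0": 0.070},
    ],
    "couplings": [
        {"i": 1, "j": 2, "form": "constant", "value": 0.0020},
    ],
}


def _make_ibr_surrogate_3s() -> DiabaticModel:
    model = _model_from_table(_IBR_TABLE)
    model.meta = {
        "initial": {"state": 1, "basis": "diabatic"},
        "grid": {"x_min": 3.5, "x_max": 11.0, "n_points": 1024},
        "t_final_fs": 140.0,
        "dt_fs": 0.1,
    }
    return model


def _make_tully3_sloped() -> DiabaticModel:
    """Extended-coupling sloped-crossing model (mass 2000 a.u.)."""
    a_, b_, c_ = 6e-4, 0.10, 0.90

    def V(r):
        x = np.asarray(r, dtype=float)[..., 0]
        out = np.empty(x.shape + (2, 2))
        out[..., 0, 0] = a_
        out[..., 1, 1] = -a_
        v12 = np.where(x < 0, b_ * np.exp(c_ * x), b_ * (2.0 - np.exp(-c_ * x)))
        out[..., 0, 1] = out[..., 1, 0] = v12
        return out

    def dV(r):
        x = np.asarray(r, dtype=float)[..., 0]
        out = np.zeros(x.shape + (2, 2, 1))
        dv12 = b_ * c_ * np.exp(-c_ * np.abs(x))
        out[..., 0, 1, 0] = out[..., 1, 0, 0] = dv12
        return out

    meta = {
        "initial": {"x0": -12.0, "p0": 12.0, "sigma_x": 1.0, "state": 0,
                    "basis": "diabatic"},
        "grid": {"x_min": -40.0, "x_max": 40.0, "n_points": 2048},
        "t_final_fs": 120.0,
        "dt_fs": 0.1,
    }
    return DiabaticModel("tully3_sloped", 2, 1, np.array([2000.0]), V, dV, meta=meta)


def _make_lvc_nd(n_modes: int = 3) -> DiabaticModel:
    """Two-state linear vibronic coupling model in mass-weighted coordinates.

    V(q) = [sum_a w_a q_a^2 / 2] I + diag(E) + kappa-terms + lambda coupling.
    Masses are unity (coordinates are already mass-weighted).
    """
    omegas = np.array([0.004, 0.006, 0.009])[:n_modes]
    e0 = np.array([0.0, 0.09])
    kappa = np.array([[0.000, 0.000, 0.0], [-0.012, 0.008, 0.0]])[:, :n_modes]
    lam = np.array([0.0, 0.0, 0.004])[:n_modes]

    def V(r):
        q = np.asarray(r, dtype=float)
        harm = 0.5 * np.sum(omegas ** 2 * q * q, axis=-1)
        out = np.zeros(q.shape[:-1] + (2, 2))
        for s in range(2):
            out[..., s, s] = harm + e0[s] + q @ kappa[s]
        out[..., 0, 1] = out[..., 1, 0] = q @ lam
        return out

    def dV(r):
        q = np.asarray(r, dtype=float)
        dharm = omegas ** 2 * q  # (..., d)
        out = np.zeros(q.shape[:-1] + (2, 2, n_modes))
        for s in range(2):
            out[..., s, s, :] = dharm + kappa[s]
        out[..., 0, 1, :] = out[..., 1, 0, :] = lam
        return out

    modes = NormalModeSpec(frequencies=omegas,
                           mode_vectors=np.eye(n_modes),
                           masses=np.ones(n_modes))
    meta = {
        "initial": {"state": 1, "basis": "adiabatic"},
        "t_final_fs": 30.0,
        # sloped/peaked intersection passages need the finer nuclear step
        "dt_fs": 0.1,
    }
    return DiabaticModel("lvc_nd", 2, n_modes, np.ones(n_modes), V, dV,
                         normal_modes=modes, meta=meta)


PRESETS: dict[str, Callable[[], DiabaticModel]] = {
    "avoided_crossing_2s": _make_avoided_crossing_2s,
    "ibr_surrogate_3s": _make_ibr_surrogate_3s,
    "tully3_sloped": _make_tully3_sloped,
    "lvc_nd": _make_lvc_nd,
}


def build_model(spec: str | Mapping) -> DiabaticModel:
    """Build a model from a preset name or a parameter table.

    Parameter tables describe 1-D models: ``masses``, a ``states`` list of
    diagonal terms (``harmonic``, ``morse``, ``exponential``, ``constant``)
    and a ``couplings`` list (``constant`` or ``gaussian``).  Couplings are
    stored symmetrically; specifying both (i,j) and (j,i) with different
    values is rejected.
    """
    if isinstance(spec, str):
        try:
            return PRESETS[spec]()
        except KeyError:
            raise ValueError(
                f"unknown preset {spec!r}; available: {sorted(PRESETS)}"
            ) from None
    return _model_from_table(spec)
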