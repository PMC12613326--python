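"""Exact 1-D multi-state quantum dynamics on an equidistant grid.

The wave function is stored in the diabatic representation as complex
amplitudes per state on a common grid and propagated with the symmetric
(Strang) split-operator scheme

    exp(-i V dt/2) . FFT^-1 . exp(-i T dt) . FFT . exp(-i V dt/2),

where the potential half-steps diagonalize the (time-independent) diabatic
matrix pointwise.  Bound single-surface eigenstates are obtained from a
sinc-DVR (Fourier-grid) Hamiltonian.  Observables are analyzed either in the
diabatic basis or in the adiabatic basis via the pointwise transformation,
with x-continuous eigenvector gauge so that off-diagonal density-matrix
elements (coherences) are well defined.

The oracle is strictly one-dimensional; it serves as the reference for the
trajectory-ensemble methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .models import DiabaticModel, adiabatize_batch

__all__ = [
    "GridSpec",
    "GridWavefunction",
    "UnboundPotentialError",
    "fourier_grid_ground_state",
    "split_operator_propagate",
    "grid_observables",
]


class UnboundPotentialError(RuntimeError):
    """Raised when a bound eigenstate is requested on an unbound potential."""


@dataclass(frozen=True)
class GridSpec:
    x_min: float
    x_max: float
    n_points: int = 1024

    def points(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_points)


@dataclass
class GridWavefunction:
    """Complex amplitudes per diabatic state on an equidistant grid."""

    x: np.ndarray
    psi: np.ndarray  # (n_states, n_points) complex
    time: float = 0.0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.psi = np.asarray(self.psi, dtype=complex)
        dx = np.diff(self.x)
        if not np.allclose(dx, dx[0], rtol=1e-10):
            raise ValueError("grid must be equidistant")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def n_states(self) -> int:
        return self.psi.shape[0]

    def norm(self) -> float:
        return float(np.sum(np.abs(self.psi) ** 2) * self.dx)

    def populations(self) -> np.ndarray:
        """Diabatic populations (norm per state)."""
        return np.sum(np.abs(self.psi) ** 2, axis=1) * self.dx


def _sinc_dvr_kinetic(n: int, dx: float, mass: float) -> np.ndarray:
    """Sinc-DVR kinetic-energy matrix (spectral accuracy on the grid)."""
    i = np.arange(n)
    diff = i[:, None] - i[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(diff == 0, np.pi ** 2 / 3.0, 2.0 * (-1.0) ** diff / diff ** 2)
    return t / (2.0 * mass * dx * dx)


def fourier_grid_ground_state(model: DiabaticModel, state: int, grid: GridSpec,
                              edge_tol: float = 1e-8) -> tuple[GridWavefunction, float]:
    """Lowest eigenpair of the single-surface Hamiltonian on ``grid``.

    The returned wave function is real, positive and unit-norm (trapezoid on
    the equidistant grid reduces to sum * dx).  Raises
    :class:`UnboundPotentialError` when the requested diabatic surface has no
    interior minimum, and ``ValueError`` when the grid is too small (edge
    amplitude above ``edge_tol``).
    """
    if model.n_dof != 1:
        raise ValueError("grid oracle requires a 1-D model")
    x = grid.points()
    dx = x[1] - x[0]
    v = model.V(x[:, None])[:, state, state]
    interior = v[1:-1]
    if min(v[0], v[-1]) <= interior.min():
        raise UnboundPotentialError(
            f"diabatic surface {state} has its minimum on the grid edge; "
            "potential appears unbound"
        )
    ham = _sinc_dvr_kinetic(x.size, dx, model.reduced_mass)
    ham[np.diag_indices_from(ham)] += v
    energies, vecs = np.linalg.eigh(ham)
    psi0 = vecs[:, 0] / np.sqrt(dx)
    # fix global sign, wave function of the ground state is nodeless
    if psi0[np.argmax(np.abs(psi0))] < 0:
        psi0 = -psi0
    edge = max(abs(psi0[0]), abs(psi0[-1]))
    if edge > edge_tol:
        raise ValueError(
            f"grid too small: ground-state edge amplitude {edge:.2e} > {edge_tol:g}"
        )
    full = np.zeros((model.n_states, x.size), dtype=complex)
    full[state] = psi0
    return GridWavefunction(x=x, psi=full, time=0.0), float(energies[0])


def split_operator_propagate(psi: GridWavefunction, model: DiabaticModel,
                             dt: float, n_steps: int, store_every: int = 1,
                             edge_warn: float = 1e-6) -> list[GridWavefunction]:
    """Propagate ``psi`` for ``n_steps`` steps of ``dt`` (atomic time units).

    Returns the stored snapshots (including the initial one).  The grid has
    hard walls; a warning is emitted when the edge amplitude exceeds
    ``edge_warn`` (wrap-around contamination).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if model.n_dof != 1:
        raise ValueError("grid oracle requires a 1-D model")
    x, dx = psi.x, psi.dx
    n = x.size
    mass = model.reduced_mass

    evals, evecs = adiabatize_batch(model.V(x[:, None]))  # (n, s), (n, s, s)
    phase_half = np.exp(-0.5j * dt * evals)  # (n, s)
    # U_half[k] = W diag(e^{-i E dt/2}) W^T at grid point k
    u_half = np.einsum("kis,ks,kjs->kij", evecs, phase_half, evecs)

    k = 2.0 * np.pi * np.fft.fftfreq(n, d=dx)
    kin_phase = np.exp(-1j * dt * k * k / (2.0 * mass))

    out = [replace(psi, psi=psi.psi.copy())]
    cur = psi.psi.copy()  # (s, n)
    warned = False
    for step in range(1, n_steps + 1):
        cur = np.einsum("kij,jk->ik", u_half, cur)
        cur = np.fft.ifft(np.fft.fft(cur, axis=1) * kin_phase, axis=1)
        cur = np.einsum("kij,jk->ik", u_half, cur)
        if not warned:
            edge = max(np.max(np.abs(cur[:, 0])), np.max(np.abs(cur[:, -1])))
            if edge > edge_warn:
                warnings.warn(
                    f"wave-packet amplitude {edge:.2e} at the grid edge at "
                    f"t={psi.time + step * dt:.1f} a.u.; hard-wall artifacts likely",
                    RuntimeWarning, stacklevel=2)
                warned = True
        if step % store_every == 0 or step == n_steps:
            out.append(GridWavefunction(x=x, psi=cur.copy(),
                                        time=psi.time + step * dt))
    return out


def save_series_hdf5(series: list[GridWavefunction], path) -> None:
    """Store wave-function snapshots (grid, times, complex amplitudes)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = 1
        f.create_dataset("x", data=series[0].x)
        f.create_dataset("t", data=np.array([s.time for s in series]))
        f.create_dataset("psi", data=np.stack([s.psi for s in series]))


def load_series_hdf5(path) -> list[GridWavefunction]:
    import h5py

    with h5py.File(path, "r") as f:
        x = f["x"][:]
        times = f["t"][:]
        psi = f["psi"][:]
    return [GridWavefunction(x=x, psi=p, time=t) for p, t in zip(psi, times)]


def _continuous_gauge(evecs: np.ndarray) -> np.ndarray:
    """Enforce x-continuity of pointwise eigenvector columns (sign flips)."""
    out = evecs.copy()
    for k in range(1, out.shape[0]):
        sign = np.where(np.sum(out[k] * out[k - 1], axis=0) < 0, -1.0, 1.0)
        out[k] *= sign[None, :]
    return out


def grid_observables(series: list[GridWavefunction], model: DiabaticModel) -> dict:
    """Populations, renormalized overlaps and coherences for a snapshot series.

    Returns a dict of time series: diabatic and adiabatic populations, the
    full adiabatic density matrix rho_ij(t) = int chi_i chi_j* dx (which
    equals c_i c_j* S_ij* with renormalized nuclear overlaps), the overlap
    magnitudes |S_ij|, and expectation values of the model operators
    (convention: full electronic wave function).  For a state pair with a
    zero-population member the renormalized overlap is reported as 0.
    """
    if not series:
        raise ValueError("empty series")
    x = series[0].x
    for snap in series:
        if snap.x.shape != x.shape or not np.allclose(snap.x, x):
            raise ValueError("snapshots must share a common grid")
    dx = series[0].dx
    n_states = series[0].n_states

    _, evecs = adiabatize_batch(model.V(x[:, None]))
    evecs = _continuous_gauge(evecs)

    times = np.array([s.time for s in series])
    pop_diab = np.empty((len(series), n_states))
    rho_ad = np.empty((len(series), n_states, n_states), dtype=complex)
    rho_diab = np.empty_like(rho_ad)
    overlaps = np.zeros((len(series), n_states, n_states))
    ops = {name: np.empty(len(series), dtype=complex)
           for name in (model.operators or {})}

    for ti, snap in enumerate(series):
        psi_d = snap.psi  # (s, n)
        pop_diab[ti] = np.sum(np.abs(psi_d) ** 2, axis=1) * dx
        rho_diab[ti] = np.einsum("ik,jk->ij", psi_d, psi_d.conj()) * dx
        psi_a = np.einsum("kji,jk->ik", evecs, psi_d)  # (s, n) adiabatic
        rho_ad[ti] = np.einsum("ik,jk->ij", psi_a, psi_a.conj()) * dx
        pops_a = np.real(np.diag(rho_ad[ti]))
        denom = np.sqrt(np.outer(pops_a, pops_a))
        with np.errstate(divide="ignore", invalid="ignore"):
            s_ij = np.where(denom > 0, np.abs(rho_ad[ti]) / denom, 0.0)
        overlaps[ti] = s_ij
        for name, op in (model.operators or {}).items():
            o = op(x[:, None])  # (n, s, s)
            ops[name][ti] = np.einsum("ik,kij,jk->", psi_d.conj(), o, psi_d) * dx

    return {
        "t": times,
        "pop_diabatic": pop_diab,
        "pop_adiabatic": np.real(np.einsum("tii->ti", rho_ad)),
        "rho_adiabatic": rho_ad,
        "rho_diabatic": rho_diab,
        "overlap_magnitude": overlaps,
        "operators": ops,
    }
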