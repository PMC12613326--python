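"""Ensemble aggregation: filtering, balancing, averaged density matrices.

An ensemble of N independent trajectories is internally consistent when,
for every adiabatic state j, the trajectory-averaged quantum population
rho_jj(t) = <|c_j(t)|^2> agrees with the fraction Pi_j(t) of trajectories
whose active surface is j.  This module computes both, together with the
full averaged density matrix (coherences included), 95% confidence
intervals, observable expectation values evaluated from the full electronic
wave function, and the energy-conservation filtering plus stochastic
balancing of the initial active-state fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import IntegratorConfig, RawEnsemble, propagate_ensemble
from .models import DiabaticModel
from .units import HARTREE_TO_EV
from .wigner import InitialEnsemble

__all__ = [
    "EnsembleResult",
    "run_ensemble",
    "filter_and_balance",
    "ensemble_averages",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class EnsembleResult:
    """Averaged time series over a (balanced) trajectory ensemble."""

    t: np.ndarray  # (T,) atomic time
    rho: np.ndarray  # (T, n, n) complex averaged density matrix
    rho_ci: np.ndarray  # (T, n, n) 95% CI half-width of |element| components
    fractions: np.ndarray  # (T, n) fraction of active trajectories Pi_j
    consistency_gap: np.ndarray  # (T,) max_j |rho_jj - Pi_j|
    n_run: int
    n_valid: int
    n_balanced: int
    observables: dict[str, np.ndarray] = field(default_factory=dict)
    e_tot_initial: np.ndarray | None = None  # (N,) t=0 total energies
    meta: dict = field(default_factory=dict)

    @property
    def populations(self) -> np.ndarray:
        return np.real(np.einsum("tii->ti", self.rho))

    def to_frame(self) -> pd.DataFrame:
        n = self.rho.shape[1]
        data = {"t": self.t}
        for j in range(n):
            data[f"rho_{j}{j}"] = np.real(self.rho[:, j, j])
            data[f"ci_rho_{j}{j}"] = self.rho_ci[:, j, j]
            data[f"pi_{j}"] = self.fractions[:, j]
        for i in range(n):
            for j in range(i + 1, n):
                data[f"re_rho_{i}{j}"] = np.real(self.rho[:, i, j])
                data[f"im_rho_{i}{j}"] = np.imag(self.rho[:, i, j])
                data[f"ci_rho_{i}{j}"] = self.rho_ci[:, i, j]
        data["consistency_gap"] = self.consistency_gap
        for name, series in self.observables.items():
            data[f"obs_{name}"] = np.real(series)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = 1
            f.create_dataset("t", data=self.t)
            f.create_dataset("rho", data=self.rho)
            f.create_dataset("rho_ci", data=self.rho_ci)
            f.create_dataset("fractions", data=self.fractions)
            f.create_dataset("consistency_gap", data=self.consistency_gap)
            for k, v in (("n_run", self.n_run), ("n_valid", self.n_valid),
                         ("n_balanced", self.n_balanced)):
                f.attrs[k] = v
            if self.e_tot_initial is not None:
                f.create_dataset("e_tot_initial", data=self.e_tot_initial)
            for name, series in self.observables.items():
                f.create_dataset(f"observables/{name}", data=series)
            f.attrs["meta"] = json.dumps(self.meta, default=str)


def run_ensemble(model: DiabaticModel, initial: InitialEnsemble,
                 config: IntegratorConfig, n_steps: int, seed: int,
                 initial_basis: str = "diabatic", record_stride: int = 1,
                 **kwargs) -> RawEnsemble:
    """Propagate every sample of ``initial`` as an independent trajectory.

    Trajectory nu draws its RNG stream from ``(seed, nu)``; results are
    therefore independent of batching and execution order.  Diverging
    trajectories are flagged in ``failed`` rather than aborting the run.
    """
    if initial.n_samples < 1:
        raise ValueError("need at least one trajectory")
    return propagate_ensemble(model, initial, config, n_steps, seed,
                              initial_basis=initial_basis,
                              record_stride=record_stride, **kwargs)


def filter_and_balance(raw: RawEnsemble, e_drift_max_ev: float = 1.0,
                       seed: int = 0, tol: float | None = None):
    """Energy-drift filtering and stochastic initial-fraction balancing.

    Trajectories with ``max_t |E_tot(t) - E_tot(0)|`` above the threshold
    (eV) or flagged as failed are excluded.  When several states are
    populated at t = 0, exclusions may hit them unevenly; the state k with
    the largest loss of initial-fraction is identified and trajectories
    started in the other states are removed at random until the t = 0
    fractions of the balanced set match the original ones within ``tol``
    (default: half a trajectory, 1/(2 N)).

    Returns ``(kept_indices, info)``.
    """
    e_d = e_drift_max_ev / HARTREE_TO_EV
    valid = (~raw.failed) & (raw.drift <= e_d)
    if not np.any(valid):
        raise ValueError("all trajectories excluded by the energy-drift filter")
    n = raw.n_traj
    states = np.arange(raw.n_states)
    pi0 = np.array([(raw.init_active == j).mean() for j in states])
    kept = np.nonzero(valid)[0]

    def fractions(indices):
        return np.array([(raw.init_active[indices] == j).mean() for j in states])

    pi_valid = fractions(kept)
    populated = pi0 > 0
    loss = pi0 - pi_valid
    k = int(np.argmax(np.where(populated, loss, -np.inf)))

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x6261)))
    removed = []
    while True:
        cur = fractions(kept)
        tol_eff = tol if tol is not None else 1.0 / (2.0 * kept.size)
        excess = cur - pi0
        excess[k] = -np.inf  # never remove from the max-failure state
        j = int(np.argmax(excess))
        if excess[j] <= tol_eff:
            break
        pool = kept[raw.init_active[kept] == j]
        drop = rng.choice(pool)
        removed.append(int(drop))
        kept = kept[kept != drop]
    info = {
        "n_run": n,
        "n_valid": int(valid.sum()),
        "n_balanced": int(kept.size),
        "max_failure_state": k,
        "initial_fractions": pi0,
        "balanced_fractions": fractions(kept),
        "removed": removed,
    }
    return kept, info


def ensemble_averages(raw: RawEnsemble, indices: np.ndarray | None = None,
                      model: DiabaticModel | None = None,
                      info: dict | None = None) -> EnsembleResult:
    """Averaged density matrix, active fractions and observables.

    rho_ij(t) is the trajectory mean of c_i c_j^*; confidence intervals are
    normal-approximation 95% half-widths of the respective real parts
    (imaginary for i < j stored alongside).  Observable expectations use the
    full electronic wave function: <O>(t) = mean_nu sum_ij c_i^* c_j
    O_ij(R_nu(t)).
    """
    if indices is None:
        indices = np.nonzero(~raw.failed)[0]
    indices = np.asarray(indices)
    if indices.size < 2:
        raise ValueError("need at least two trajectories to average")
    c = raw.coeffs[indices]  # (N, T, n)
    a = raw.active[indices]  # (N, T)
    n, t_len, n_states = c.shape

    outer = np.einsum("nti,ntj->ntij", c, c.conj())
    rho = outer.mean(axis=0)
    se = np.std(np.real(outer), axis=0, ddof=1) / np.sqrt(n)
    se_im = np.std(np.imag(outer), axis=0, ddof=1) / np.sqrt(n)
    rho_ci = Z95 * np.maximum(se, se_im)

    fractions = np.stack([(a == j).mean(axis=0) for j in range(n_states)], axis=1)
    gap = np.max(np.abs(np.real(np.einsum("tii->ti", rho)) - fractions), axis=1)

    observables: dict[str, np.ndarray] = {}
    if model is not None and model.operators and raw.positions is not None:
        r = raw.positions[indices]  # (N, T, d)
        for name, op in model.operators.items():
            o = op(r)  # (N, T, n, n)
            observables[name] = np.einsum("nti,ntij,ntj->t", c.conj(), o, c) / n

    result = EnsembleResult(
        t=raw.t, rho=rho, rho_ci=rho_ci, fractions=fractions,
        consistency_gap=gap,
        n_run=raw.n_traj,
        n_valid=int((~raw.failed).sum()),
        n_balanced=int(indices.size),
        observables=observables,
        e_tot_initial=raw.e_tot[:, 0].copy(),
        meta=dict(info or {}, base_seed=raw.base_seed),
    )
    return result
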