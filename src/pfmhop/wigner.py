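"""Wigner-distribution sampling of initial positions and momenta.

Two routes are provided, both at zero temperature:

* harmonic sampling from a normal-mode decomposition — each mode's
  mass-weighted coordinate is Gaussian with variance 1/(2 omega) and its
  mass-weighted momentum Gaussian with variance omega/2;
* numerical sampling from the exact 1-D ground-state Wigner function
  W(x, p) computed from a grid wave function, by rejection sampling over
  the (x, p) box, disregarding cells with W below a floor (default 1e-10).

Only ground (positive-Wigner) states are supported by the numerical route;
negative cells are excluded.  The module also derives the width parameters
of the decoherence model: the 1-D coordinate standard deviation sigma from a
sampled ensemble, and the common frequency omega as the geometric mean of
the nonzero normal-mode frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridWavefunction
from .models import NormalModeSpec

__all__ = [
    "InitialEnsemble",
    "WidthSpec",
    "harmonic_wigner_sample",
    "grid_wigner_sample",
    "width_parameters",
]


@dataclass
class InitialEnsemble:
    """Sampled phase-space points with optional electronic amplitudes."""

    positions: np.ndarray  # (N, n_dof)
    momenta: np.ndarray  # (N, n_dof)
    coefficients: np.ndarray | None = None  # (N, n_states) complex, unit norm
    seed: int | tuple | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.momenta = np.atleast_2d(np.asarray(self.momenta, dtype=float))
        if self.positions.shape != self.momenta.shape:
            raise ValueError("positions and momenta must have matching shapes")
        if self.coefficients is not None:
            c = np.asarray(self.coefficients, dtype=complex)
            norms = np.sum(np.abs(c) ** 2, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-12):
                raise ValueError("electronic coefficients must be unit-norm")
            self.coefficients = c

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    def with_coefficients(self, amplitudes: np.ndarray) -> "InitialEnsemble":
        """Attach one normalized amplitude vector to every sample."""
        amp = np.asarray(amplitudes, dtype=complex)
        norm = np.linalg.norm(amp)
        if norm == 0:
            raise ValueError("cannot normalize all-zero amplitudes")
        c = np.tile(amp / norm, (self.n_samples, 1))
        return InitialEnsemble(self.positions, self.momenta, c, self.seed)

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for d in range(self.positions.shape[1]):
            data[f"x{d}"] = self.positions[:, d]
            data[f"p{d}"] = self.momenta[:, d]
        if self.coefficients is not None:
            for j in range(self.coefficients.shape[1]):
                data[f"re_c{j}"] = self.coefficients[:, j].real
                data[f"im_c{j}"] = self.coefficients[:, j].imag
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "InitialEnsemble":
        df = pd.read_csv(path)
        xc = sorted(c for c in df.columns if c.startswith("x"))
        pc = sorted(c for c in df.columns if c.startswith("p"))
        cc = sorted(c for c in df.columns if c.startswith("re_c"))
        coeffs = None
        if cc:
            coeffs = np.stack(
                [df[f"re_c{j}"].to_numpy() + 1j * df[f"im_c{j}"].to_numpy()
                 for j in range(len(cc))], axis=1)
        return cls(df[xc].to_numpy(), df[pc].to_numpy(), coeffs)


@dataclass(frozen=True)
class WidthSpec:
    """Width parameter of the decoherence model: sigma+mu (1-D) or omega+N_D."""

    sigma: float | None = None
    mu: float | None = None
    omega: float | None = None
    n_d: int | None = None

    def __post_init__(self):
        for name in ("sigma", "mu", "omega"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be strictly positive")


def harmonic_wigner_sample(modes: NormalModeSpec, n: int, seed,
                           x0: np.ndarray | None = None,
                           p0: np.ndarray | None = None) -> InitialEnsemble:
    """Sample the zero-temperature harmonic Wigner distribution.

    Per mode alpha the mass-weighted coordinate is N(0, 1/(2 omega_a)) and
    the mass-weighted momentum N(0, omega_a/2); samples are transformed back
    to Cartesian coordinates with the mode vectors and masses.  Optional
    Cartesian offsets ``x0``/``p0`` shift the ensemble (displaced packet).
    """
    if modes is None:
        raise ValueError("harmonic sampling requires a NormalModeSpec")
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    om = modes.frequencies
    q = rng.normal(0.0, np.sqrt(1.0 / (2.0 * om)), size=(n, om.size))
    p = rng.normal(0.0, np.sqrt(om / 2.0), size=(n, om.size))
    sqrt_m = np.sqrt(modes.masses)
    positions = (q @ modes.mode_vectors.T) / sqrt_m
    momenta = (p @ modes.mode_vectors.T) * sqrt_m
    if x0 is not None:
        positions = positions + np.asarray(x0, dtype=float)
    if p0 is not None:
        momenta = momenta + np.asarray(p0, dtype=float)
    return InitialEnsemble(positions, momenta, seed=seed)


def wigner_table(psi: GridWavefunction, state: int | None = None,
                 n_p: int = 512) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wigner function W(x, p) of a 1-D wave function on its grid.

    W(x,p) = (1/pi) int dy psi*(x+y) psi(x-y) e^{2ipy}.  Returns
    ``(x, p, W)`` with ``W`` of shape ``(len(x), len(p))``.
    """
    if state is None:
        pops = psi.populations()
        state = int(np.argmax(pops))
    f = psi.psi[state]
    x, dx = psi.x, psi.dx
    n = x.size
    j = np.arange(-(n // 2), n // 2 + 1)  # y = j*dx offsets
    k = np.arange(n)
    kp = k[:, None] + j[None, :]
    km = k[:, None] - j[None, :]
    valid = (kp >= 0) & (kp < n) & (km >= 0) & (km < n)
    corr = np.zeros((n, j.size), dtype=complex)
    corr[valid] = np.conj(f[kp[valid]]) * f[km[valid]]
    # momentum grid from the spectral width of the state
    spec = np.abs(np.fft.fft(f)) ** 2
    freqs = 2.0 * np.pi * np.fft.fftfreq(n, d=dx)
    p_sd = np.sqrt(np.sum(spec * freqs ** 2) / np.sum(spec))
    p_max = 6.0 * max(p_sd, 1e-12)
    p = np.linspace(-p_max, p_max, n_p)
    phase = np.exp(2j * np.outer(j * dx, p))  # (n_y, n_p)
    w = np.real(corr @ phase) * dx / np.pi
    return x, p, w


def grid_wigner_sample(psi: GridWavefunction, n: int, seed,
                       floor: float = 1e-10) -> InitialEnsemble:
    """Rejection-sample (x, p) pairs from the numerical Wigner function.

    Cells with ``W <= floor`` (including all negative cells) are excluded;
    intended for ground states, whose Wigner function is non-negative.
    """
    if floor < 0:
        raise ValueError("floor must be non-negative")
    x, p, w = wigner_table(psi)
    w_max = float(w.max())
    if w_max <= floor:
        raise ValueError("no Wigner cell above the floor; table degenerate "
                         "or floor too large")
    rng = np.random.default_rng(seed)
    dx = x[1] - x[0]
    dp = p[1] - p[0]
    xs = np.empty(n)
    ps = np.empty(n)
    filled = 0
    while filled < n:
        m = max(4 * (n - filled), 1024)
        cand_x = rng.uniform(x[0], x[-1], m)
        cand_p = rng.uniform(p[0], p[-1], m)
        ix = np.clip(np.round((cand_x - x[0]) / dx).astype(int), 0, x.size - 1)
        ip = np.clip(np.round((cand_p - p[0]) / dp).astype(int), 0, p.size - 1)
        vals = w[ix, ip]
        accept = (vals > floor) & (rng.uniform(0.0, w_max, m) < vals)
        take = min(int(accept.sum()), n - filled)
        xs[filled:filled + take] = cand_x[accept][:take]
        ps[filled:filled + take] = cand_p[accept][:take]
        filled += take
    return InitialEnsemble(xs[:, None], ps[:, None], seed=seed)


def width_parameters(source: NormalModeSpec | InitialEnsemble) -> WidthSpec:
    """Width parameters of the decoherence model.

    * multi-D: omega = geometric mean of the nonzero normal-mode frequencies
      (conserves the volume of the variance ellipse), with N_D the mode count;
    * 1-D ensemble: sigma = sample standard deviation of the bond coordinate.
    """
    if isinstance(source, NormalModeSpec):
        om = source.frequencies
        if np.any(om <= 0):
            raise ValueError("zero/negative frequencies must be removed first")
        return WidthSpec(omega=float(np.exp(np.mean(np.log(om)))), n_d=om.size)
    if isinstance(source, InitialEnsemble):
        if source.positions.shape[1] != 1:
            raise ValueError("sigma extraction requires a 1-D ensemble")
        sigma = float(np.std(source.positions[:, 0], ddof=1))
        return WidthSpec(sigma=sigma)
    raise TypeError("expected NormalModeSpec or InitialEnsemble")
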