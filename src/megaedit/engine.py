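"""Density-matrix spin dynamics in the rotating frame.

Hilbert-space propagation in the Zeeman product basis.  The free-evolution
Hamiltonian keeps the full isotropic coupling term (strong coupling is not
approximated away), shaped pulses are propagated piecewise-constant with the
free Hamiltonian included in every step, and relaxation is applied only
during acquisition as a Lorentzian linewidth (no relaxation during RF).

Conventions
-----------
* The thermal-equilibrium state is the high-temperature deviation density
  matrix ``rho = sum_i Iz_i``.
* Detection operator is ``sum_i I+_i``; a spin with positive rotating-frame
  offset ``nu`` (downfield of the carrier) evolves as ``exp(+i 2 pi nu t)``
  and lands at its own ppm value on the spectral axis.
* FID samples are scaled by ``2^(2-N)`` so that an N-proton singlet after an
  ideal 90-degree pulse has first-sample magnitude N (proton-count scaling:
  the 2-proton reference singlet reads 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .pulses import ShapedPulse
from .spin_systems import FieldParams, SpinSystem, offsets_hz

__all__ = [
    "SpinState",
    "AcqConfig",
    "FID",
    "spin_operators",
    "equilibrium",
    "hamiltonian",
    "evolve",
    "apply_pulse",
    "apply_ideal_pulse",
    "acquire_fid",
]

_SX = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
_SY = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
_SZ = np.array([[0.5, 0], [0, -0.5]], dtype=complex)


@lru_cache(maxsize=16)
def spin_operators(n_spins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-spin (Ix, Iy, Iz) operator stacks of shape (n, 2^n, 2^n)."""
    dim = 2 ** n_spins
    ix = np.empty((n_spins, dim, dim), dtype=complex)
    iy = np.empty_like(ix)
    iz = np.empty_like(ix)
    for i in range(n_spins):
        ops = [np.eye(2, dtype=complex)] * n_spins
        for single, out in ((_SX, ix), (_SY, iy), (_SZ, iz)):
            ops[i] = single
            acc = ops[0]
            for o in ops[1:]:
                acc = np.kron(acc, o)
            out[i] = acc
        ops[i] = np.eye(2, dtype=complex)
    for arr in (ix, iy, iz):
        arr.setflags(write=False)
    return ix, iy, iz


@dataclass
class SpinState:
    """Density matrix of an N-proton system in the Zeeman product basis."""

    rho: np.ndarray
    n_spins: int

    def __post_init__(self) -> None:
        dim = 2 ** self.n_spins
        rho = np.asarray(self.rho, dtype=complex)
        if rho.shape != (dim, dim):
            raise ValueError(f"rho must be {dim}x{dim} for {self.n_spins} spins")
        if not np.allclose(rho, rho.conj().T, atol=1e-10):
            raise ValueError("rho must be Hermitian")
        self.rho = rho

    def expect(self, op: np.ndarray) -> complex:
        return complex(np.trace(self.rho @ op))


def equilibrium(system: SpinSystem) -> SpinState:
    """Thermal equilibrium deviation density matrix sum_i Iz_i."""
    _, _, iz = spin_operators(system.n_spins)
    return SpinState(iz.sum(axis=0), system.n_spins)


@dataclass(frozen=True)
class AcqConfig:
    """Acquisition parameters: dwell = 1/spectral width, sample count, linewidth."""

    n_points: int = 2048
    spectral_width_hz: float = 4000.0
    linewidth_hz: float = 2.0

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if self.spectral_width_hz <= 0:
            raise ValueError("spectral width must be positive")
        if self.linewidth_hz < 0:
            raise ValueError("linewidth must be non-negative")

    @property
    def dwell(self) -> float:
        return 1.0 / self.spectral_width_hz


@dataclass(frozen=True)
class FID:
    """Complex time-domain signal plus provenance metadata."""

    samples: np.ndarray
    dwell: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=complex)
        if not np.all(np.isfinite(s)):
            raise ValueError("FID contains non-finite samples")
        object.__setattr__(self, "samples", s)

    def __add__(self, other: "FID") -> "FID":
        self._check(other)
        return FID(self.samples + other.samples, self.dwell, dict(self.meta))

    def __sub__(self, other: "FID") -> "FID":
        self._check(other)
        return FID(self.samples - other.samples, self.dwell, dict(self.meta))

    def __mul__(self, k: float) -> "FID":
        return FID(self.samples * k, self.dwell, dict(self.meta))

    __rmul__ = __mul__

    def _check(self, other: "FID") -> None:
        if len(self.samples) != len(other.samples) or self.dwell != other.dwell:
            raise ValueError("FIDs must share length and dwell")

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dwell


def hamiltonian(system: SpinSystem, fld: FieldParams) -> np.ndarray:
    """Free-evolution Hamiltonian in rad/s.

    H = sum_i 2 pi nu_i Iz_i + sum_{i<j} 2 pi J_ij (Ix_i Ix_j + Iy_i Iy_j +
    Iz_i Iz_j); the full scalar product keeps strong-coupling effects.
    """
    n = system.n_spins
    ix, iy, iz = spin_operators(n)
    nu = offsets_hz(system, fld)
    h = np.zeros((2 ** n, 2 ** n), dtype=complex)
    for i in range(n):
        h += 2.0 * np.pi * nu[i] * iz[i]
    for i in range(n):
        for j in range(i + 1, n):
            jij = system.j[i, j]
            if jij != 0.0:
                h += 2.0 * np.pi * jij * (ix[i] @ ix[j] + iy[i] @ iy[j] + iz[i] @ iz[j])
    return h


def _propagator(h: np.ndarray, t: float) -> np.ndarray:
    """exp(-i H t) via eigendecomposition of the Hermitian H."""
    w, v = np.linalg.eigh(h)
    return (v * np.exp(-1j * w * t)) @ v.conj().T


def evolve(state: SpinState, h: np.ndarray, t: float) -> SpinState:
    """Free evolution rho -> U rho U+ with U = exp(-i H t)."""
    if t < 0:
        raise ValueError("evolution time must be non-negative")
    if t == 0:
        return SpinState(state.rho.copy(), state.n_spins)
    u = _propagator(h, t)
    return SpinState(u @ state.rho @ u.conj().T, state.n_spins)


def _select_spins(system: SpinSystem, selector) -> np.ndarray:
    """Boolean mask of addressed spins; selector = None (all) or (lo, hi) ppm."""
    if selector is None:
        return np.ones(system.n_spins, dtype=bool)
    lo, hi = selector
    mask = np.array([(lo <= s <= hi) for s in system.shifts])
    if not mask.any():
        raise ValueError(f"ppm window {selector} selects no spins of {system.name}")
    return mask


def apply_ideal_pulse(state: SpinState, system: SpinSystem, angle: float,
                      phase: float = 0.0, ppm_window=None,
                      missing_ok: bool = False) -> SpinState:
    """Instantaneous rotation of the selected spins by ``angle`` (radians)
    about the axis at azimuth ``phase`` in the transverse plane.

    An empty ppm window raises unless ``missing_ok`` is set (then the state
    is returned unchanged — a frequency-selective pulse addressing no spins
    of this system).
    """
    if ppm_window is not None and missing_ok:
        lo, hi = ppm_window
        if not any(lo <= s <= hi for s in system.shifts):
            return SpinState(state.rho.copy(), state.n_spins)
    mask = _select_spins(system, ppm_window)
    ix, iy, _ = spin_operators(system.n_spins)
    gen = np.tensordot(mask.astype(float),
                       np.cos(phase) * ix + np.sin(phase) * iy, axes=1)
    u = _propagator(gen, angle)
    return SpinState(u @ state.rho @ u.conj().T, state.n_spins)


def shaped_pulse_propagator(system: SpinSystem, fld: FieldParams,
                            pulse: ShapedPulse) -> np.ndarray:
    """Total propagator of a shaped pulse, free evolution included.

    The pulse carrier offset is handled as a per-step phase ramp in the
    transmitter frame (exact for piecewise-constant waveforms); the ramp is
    referenced to the pulse center so the nominal phase applies there.
    """
    h_free = hamiltonian(system, fld)
    ix, iy, _ = spin_operators(system.n_spins)
    fx, fy = ix.sum(axis=0), iy.sum(axis=0)
    dt = pulse.dt
    n = pulse.n_steps
    t_mid = (np.arange(n) + 0.5) * dt - pulse.duration / 2.0
    phases = pulse.phase + 2.0 * np.pi * pulse.offset_hz * t_mid
    u_total = np.eye(h_free.shape[0], dtype=complex)
    for a, ph in zip(pulse.amp, phases):
        h = h_free + 2.0 * np.pi * a * (np.cos(ph) * fx + np.sin(ph) * fy)
        u_total = _propagator(h, dt) @ u_total
    return u_total


def apply_pulse(state: SpinState, system: SpinSystem, fld: FieldParams,
                pulse: ShapedPulse) -> SpinState:
    """Apply a shaped pulse (piecewise-constant propagation, free evolution
    running throughout the pulse duration)."""
    u = shaped_pulse_propagator(system, fld, pulse)
    return SpinState(u @ state.rho @ u.conj().T, state.n_spins)


def acquire_fid(state: SpinState, h: np.ndarray, acq: AcqConfig,
                meta: dict | None = None) -> FID:
    """Detect sum_i I+_i during free evolution under ``h``.

    samples[k] = 2^(2-N) * Tr(rho(t_k) sum I+) * exp(-pi * linewidth * t_k)
    with t_k = k * dwell.  Evaluated in the eigenbasis of ``h`` so the whole
    FID costs one diagonalization.
    """
    n = state.n_spins
    ix, iy, _ = spin_operators(n)
    det = (ix + 1j * iy).sum(axis=0)
    w, v = np.linalg.eigh(h)
    rho_e = v.conj().T @ state.rho @ v
    det_e = v.conj().T @ det @ v
    # Tr(U rho U+ det) = sum_ab rho_ab det_ba exp(-i (w_a - w_b) t)
    prod = rho_e * det_e.T                      # element (a, b): rho_ab * det_ba
    dw = w[:, None] - w[None, :]
    t = np.arange(acq.n_points) * acq.dwell
    # flatten nonzero contributions
    flat = prod.ravel()
    keep = np.abs(flat) > 1e-14
    amps = flat[keep]
    freqs = dw.ravel()[keep]
    signal = (amps[None, :] * np.exp(-1j * freqs[None, :] * t[:, None])).sum(axis=1)
    signal *= 2.0 ** (2 - n) * np.exp(-np.pi * acq.linewidth_hz * t)
    return FID(signal, acq.dwell, meta or {})
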