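"""Coupled-spin systems and field parameters.

The simulator works in the rotating frame of the transmitter.  Chemical
shifts are stored in ppm; :func:`offsets_hz` converts them to rotating-frame
offsets using the proton Larmor frequency and the transmitter carrier, with
the convention that a proton *downfield* of the carrier (larger ppm) has a
*positive* offset and therefore appears at a larger ppm value on the final
spectral axis.

Spin-system constants (chemical shifts and J-couplings for GABA and for
lysine, the standard simulation surrogate of the J-coupled macromolecular
resonances around 1.7/3.0 ppm) are bundled as a versioned JSON data file;
the file, not code constants, is the source of truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

GAMMA_BAR_MHZ_PER_T = 42.577  # proton gyromagnetic ratio / 2pi

__all__ = [
    "FieldParams",
    "SpinSystem",
    "make_spin_system",
    "offsets_hz",
    "load_constants",
]


@dataclass(frozen=True)
class FieldParams:
    """Static-field / transmitter configuration.

    Parameters
    ----------
    b0 : float
        Field strength in tesla.
    f0 : float
        Proton Larmor frequency in MHz.  Must be consistent with ``b0``
        within 1% of gamma/2pi = 42.577 MHz/T.
    ref_ppm : float
        Chemical shift assigned to zero frequency offset of the shift scale
        (water referencing convention marker; informational).
    carrier_ppm : float
        Transmitter center in ppm.  Everything in the rotating frame is
        measured relative to this.
    """

    b0: float = 7.0
    f0: float = 297.2
    ref_ppm: float = 4.65
    carrier_ppm: float = 2.4

    def __post_init__(self) -> None:
        if self.b0 <= 0 or self.f0 <= 0:
            raise ValueError("b0 and f0 must be positive")
        expected = GAMMA_BAR_MHZ_PER_T * self.b0
        if abs(self.f0 - expected) > 0.01 * expected:
            raise ValueError(
                f"f0={self.f0} MHz inconsistent with b0={self.b0} T "
                f"(expected ~{expected:.1f} MHz)"
            )


@dataclass(frozen=True)
class SpinSystem:
    """A set of coupled protons: shifts in ppm plus a symmetric J matrix in Hz."""

    name: str
    shifts: tuple[float, ...]
    j: np.ndarray
    groups: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        j = np.asarray(self.j, dtype=float)
        n = len(self.shifts)
        if j.shape != (n, n):
            raise ValueError(f"J matrix shape {j.shape} does not match {n} protons")
        if n > 10:
            raise ValueError("at most 10 protons supported (Hilbert dimension 1024)")
        if not np.allclose(j, j.T, atol=0.0):
            raise ValueError("J matrix must be symmetric")
        if np.any(np.diag(j) != 0.0):
            raise ValueError("J matrix diagonal must be exactly zero")
        j.setflags(write=False)
        object.__setattr__(self, "j", j)
        object.__setattr__(self, "shifts", tuple(float(s) for s in self.shifts))
        if self.groups is None:
            object.__setattr__(self, "groups", tuple(f"H{i + 1}" for i in range(n)))
        else:
            object.__setattr__(self, "groups", tuple(self.groups))
            if len(self.groups) != n:
                raise ValueError("group labels must match proton count")

    @property
    def n_spins(self) -> int:
        return len(self.shifts)

    def decoupled_from(self, target_ppm: float, tol_ppm: float = 0.05) -> "SpinSystem":
        """Return a copy with all couplings *to* protons near ``target_ppm`` zeroed.

        Used to build the editing-efficiency reference: zeroing the couplings
        to the 1.89-ppm protons of GABA turns the 3.01-ppm pair into a fully
        refocused pseudo-singlet.
        """
        sel = [i for i, s in enumerate(self.shifts) if abs(s - target_ppm) <= tol_ppm]
        if not sel:
            raise ValueError(f"no protons within {tol_ppm} ppm of {target_ppm}")
        j = np.array(self.j, dtype=float)
        for i in sel:
            for k in range(self.n_spins):
                if k not in sel:
                    j[i, k] = 0.0
                    j[k, i] = 0.0
        return SpinSystem(f"{self.name}_decoupled@{target_ppm:g}", self.shifts, j, self.groups)


def load_constants() -> dict:
    """Load the bundled spin-system constant file (shifts/J for GABA, Lys)."""
    with resources.files("megaedit.data").joinpath("spin_systems.json").open() as fh:
        return json.load(fh)


def make_spin_system(name: str) -> SpinSystem:
    """Build a :class:`SpinSystem` from the bundled constants.

    Accepted names: ``"gaba"``, ``"lys"`` (full 9-proton lysine),
    ``"lys_fragment"`` (the 4-proton delta/epsilon-CH2 subsystem, the fast
    default for offset sweeps) and singlet specs ``"singlet:<ppm>:<n>"``
    (``n`` uncoupled protons at the given shift, e.g. ``"singlet:3.03:2"``
    as a creatine-methylene stand-in).
    """
    name = name.strip().lower()
    if name.startswith("singlet:"):
        parts = name.split(":")
        if len(parts) != 3:
            raise ValueError("singlet spec must be 'singlet:<ppm>:<n_protons>'")
        ppm, n = float(parts[1]), int(parts[2])
        if n < 1 or n > 10:
            raise ValueError("singlet proton count must be in 1..10")
        return SpinSystem(name, (ppm,) * n, np.zeros((n, n)),
                          tuple(f"singlet {ppm:g} ppm" for _ in range(n)))

    data = load_constants()
    if name in data["systems"]:
        entry = data["systems"][name]
        return SpinSystem(name, tuple(entry["shifts_ppm"]),
                          np.array(entry["j_hz"], dtype=float),
                          tuple(entry["group_labels"]))
    if name in data["fragments"]:
        frag = data["fragments"][name]
        parent = data["systems"][frag["parent"]]
        idx = frag["proton_indices"]
        shifts = tuple(parent["shifts_ppm"][i] for i in idx)
        j = np.array(parent["j_hz"], dtype=float)[np.ix_(idx, idx)]
        labels = tuple(parent["group_labels"][i] for i in idx)
        return SpinSystem(name, shifts, j, labels)

    available = sorted(data["systems"]) + sorted(data["fragments"]) + ["singlet:<ppm>:<n>"]
    raise ValueError(f"unknown spin system {name!r}; available: {', '.join(available)}")


def offsets_hz(system: SpinSystem, fld: FieldParams) -> np.ndarray:
    """Rotating-frame offset of each proton in Hz: (shift - carrier) * f0."""
    return (np.asarray(system.shifts) - fld.carrier_ppm) * fld.f0
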