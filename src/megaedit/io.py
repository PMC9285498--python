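"""Plain-text and HDF5 export/import helpers.

FIDs and spectra go to CSV (with a JSON metadata sidecar embedded as a
header comment) or a jMRUI-style plain-text block; synthetic raw datasets
round-trip through HDF5.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .analysis import Spectrum
from .engine import FID

__all__ = [
    "write_fid_csv",
    "read_fid_csv",
    "write_spectrum_csv",
    "write_jmrui_txt",
    "save_raw_h5",
    "load_raw_h5",
]


def write_fid_csv(fid: FID, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# {json.dumps({'dwell_s': fid.dwell, **fid.meta})}\n")
        w = csv.writer(fh)
        w.writerow(["time_s", "real", "imag"])
        for t, s in zip(fid.time, fid.samples):
            w.writerow([f"{t:.9g}", f"{s.real:.10g}", f"{s.imag:.10g}"])


def read_fid_csv(path: str | Path) -> FID:
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = json.loads(first[1:].strip())
            data = np.loadtxt(fh, delimiter=",", skiprows=1)
        else:
            data = np.loadtxt(path, delimiter=",", skiprows=1)
    dwell = meta.pop("dwell_s", None)
    if dwell is None:
        dwell = float(data[1, 0] - data[0, 0])
    return FID(data[:, 1] + 1j * data[:, 2], float(dwell), meta)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# {json.dumps(spectrum.meta)}\n")
        w = csv.writer(fh)
        w.writerow(["ppm", "real", "imag"])
        for p, re, im in zip(spectrum.ppm, spectrum.real, spectrum.imag):
            w.writerow([f"{p:.7g}", f"{re:.10g}", f"{im:.10g}"])


def write_jmrui_txt(fid: FID, path: str | Path, f0_mhz: float = 297.2) -> None:
    """Minimal jMRUI-style ASCII export (header plus sig/FFT columns)."""
    path = Path(path)
    n = len(fid.samples)
    spec = np.fft.fftshift(np.fft.fft(fid.samples))
    lines = [
        "jMRUI Data Textfile", "",
        f"PointsInDataset: {n}",
        "DatasetsInFile: 1",
        f"SamplingInterval: {fid.dwell * 1e3:.6f}",
        "ZeroOrderPhase: 0",
        "BeginTime: 0",
        f"TransmitterFrequency: {f0_mhz * 1e6:.1f}",
        "MagneticField: 7.0",
        "TypeOfNucleus: 1H", "",
        "sig(real)\tsig(imag)\tfft(real)\tfft(imag)",
    ]
    for s, f in zip(fid.samples, spec):
        lines.append(f"{s.real:.6E}\t{s.imag:.6E}\t{f.real:.6E}\t{f.imag:.6E}")
    path.write_text("\n".join(lines) + "\n")


def save_raw_h5(raw, path: str | Path) -> None:
    """Write a RawDataset (blocks, water reference, dwell) to HDF5."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["dwell_s"] = raw.dwell
        h5.attrs["coils"] = raw.coils
        h5.create_dataset("water_ref", data=raw.water_ref)
        for b, blk in enumerate(raw.blocks):
            grp = h5.create_group(f"block{b:03d}")
            for (inv, edit), arr in blk.items():
                grp.create_dataset(f"{inv}__{edit}", data=arr)


def load_raw_h5(path: str | Path):
    """Read a RawDataset written by :func:`save_raw_h5` (truth is not
    persisted: on-disk datasets behave like measured data)."""
    import h5py

    from .processing import RawDataset

    with h5py.File(path, "r") as h5:
        water = h5["water_ref"][()]
        blocks = []
        for name in sorted(k for k in h5 if k.startswith("block")):
            grp = h5[name]
            blk = {}
            for key in grp:
                inv, edit = key.split("__")
                blk[(inv, edit)] = grp[key][()]
            blocks.append(blk)
        return RawDataset(blocks=blocks, water_ref=water,
                          dwell=float(h5.attrs["dwell_s"]),
                          coils=int(h5.attrs["coils"]), truth={})
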