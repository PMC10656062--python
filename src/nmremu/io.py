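"""Plain-text readers and writers for spin systems, FIDs, spectra and
schedules.

All tabular files are comma-separated with a single header line stating the
column names and units; frequencies are in Hz, times in seconds and grid
indices 0-based.  Readers validate their invariants and report the offending
line or entry on failure.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Union

import numpy as np
import yaml

from .nus import NUSSchedule, Peak
from .signals import FIDTrace, Spectrum
from .spin_system import Isotope, ISOTOPE_GAMMA_RATIOS, SpinSystem, isotope

__all__ = [
    "read_spin_system",
    "write_spin_system",
    "read_fid",
    "write_fid",
    "read_spectrum",
    "write_spectrum",
    "read_schedule",
    "write_schedule",
    "read_fid_points",
    "write_fid_points",
    "write_peaks",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A malformed input file, with the offending location in the message."""


def read_spin_system(path: PathLike) -> SpinSystem:
    """Load a spin system from a YAML config.

    Keys: ``sites`` (list of isotope labels), ``J_hz`` (NxN list),
    ``shifts_hz`` (optional), ``coords_angstrom`` (optional),
    ``orientation_quaternion`` (optional).
    """
    path = Path(path)
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise FormatError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: expected a mapping at top level")
    try:
        labels = doc["sites"]
        j = doc["J_hz"]
    except KeyError as exc:
        raise FormatError(f"{path}: missing required key {exc}") from None
    sites = []
    for i, lab in enumerate(labels):
        if lab not in ISOTOPE_GAMMA_RATIOS:
            raise FormatError(f"{path}: sites[{i}]: unknown isotope {lab!r}")
        sites.append(isotope(lab))
    try:
        return SpinSystem(tuple(sites), np.asarray(j, dtype=float),
                          shifts_hz=doc.get("shifts_hz"),
                          coords=doc.get("coords_angstrom"),
                          orientation=doc.get("orientation_quaternion"))
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_spin_system(system: SpinSystem, path: PathLike) -> None:
    doc = {
        "sites": [s.label for s in system.sites],
        "J_hz": system.j_hz.tolist(),
    }
    if np.any(system.shifts_hz):
        doc["shifts_hz"] = system.shifts_hz.tolist()
    if system.coords is not None:
        doc["coords_angstrom"] = system.coords.tolist()
    if system.orientation is not None:
        doc["orientation_quaternion"] = system.orientation.tolist()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _read_two_column(path: PathLike, expected_header: str) -> np.ndarray:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    if lines[0].strip().replace(" ", "") != expected_header:
        raise FormatError(f"{path}:1: expected header {expected_header!r}, "
                          f"got {lines[0]!r}")
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}:{ln}: expected two comma-separated values")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise FormatError(f"{path}:{ln}: non-numeric entry {line!r}") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.array(rows)


def read_fid(path: PathLike) -> FIDTrace:
    data = _read_two_column(path, "time_s,value")
    try:
        return FIDTrace(data[:, 0], data[:, 1], meta={"provenance": "file"})
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fid(fid: FIDTrace, path: PathLike) -> None:
    np.savetxt(path, np.column_stack([fid.times, fid.values]), delimiter=",",
               header="time_s,value", comments="", fmt="%.12g")


def read_spectrum(path: PathLike) -> Spectrum:
    data = _read_two_column(path, "freq_hz,intensity")
    freqs = data[:, 0]
    if len(freqs) < 2:
        raise FormatError(f"{path}: spectrum needs at least two rows")
    try:
        return Spectrum(freqs, data[:, 1], grid_spacing=float(freqs[1] - freqs[0]))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_spectrum(spectrum: Spectrum, path: PathLike) -> None:
    np.savetxt(path, np.column_stack([spectrum.freqs, spectrum.intensities]),
               delimiter=",", header="freq_hz,intensity", comments="", fmt="%.12g")


def read_schedule(path: PathLike, n_grid: int, seed: int = -1,
                  weighting: str = "sine") -> NUSSchedule:
    """Read a schedule file: one 0-based index per line, sorted."""
    path = Path(path)
    indices = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            indices.append(int(line))
        except ValueError:
            raise FormatError(f"{path}:{ln}: expected an integer index, got {line!r}") \
                from None
    try:
        return NUSSchedule(np.array(indices, dtype=int), n_grid=n_grid, seed=seed,
                           weighting=weighting)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_schedule(schedule: NUSSchedule, path: PathLike) -> None:
    Path(path).write_text("\n".join(str(i) for i in schedule.indices) + "\n")


def read_fid_points(path: PathLike) -> np.ndarray:
    """Read `index,value` pairs; returns a (n, 2) array sorted by index."""
    data = _read_two_column(path, "index,value")
    idx = data[:, 0]
    if np.any(idx != np.round(idx)):
        raise FormatError(f"{path}: indices must be integers")
    order = np.argsort(idx)
    return data[order]


def write_fid_points(indices: np.ndarray, values: np.ndarray, path: PathLike) -> None:
    np.savetxt(path, np.column_stack([indices, values]), delimiter=",",
               header="index,value", comments="", fmt=["%d", "%.12g"])


def write_peaks(peaks: List[Peak], uncertainties: List[float], path: PathLike) -> None:
    rows = [(p.center, p.hwhm, p.amplitude, u) for p, u in zip(peaks, uncertainties)]
    np.savetxt(path, np.array(rows), delimiter=",",
               header="center_hz,hwhm_hz,amplitude,uncertainty_hz", comments="",
               fmt="%.12g")
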