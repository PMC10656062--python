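"""Time- and frequency-domain signal containers.

``FIDTrace`` holds a free-induction decay sampled on a time grid;
``Spectrum`` holds its (real-part) Fourier transform on a uniform frequency
grid.  Both are plain dataclasses with light validation; processing lives in
:mod:`nmremu.exact` and :mod:`nmremu.nus`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["FIDTrace", "Spectrum", "TransitionLine"]


@dataclass
class FIDTrace:
    """A free induction decay: real signal values on an increasing time grid.

    ``meta`` records provenance (``exact`` | ``emulated`` | ``nus-subsampled``
    | ``zero-filled``), the normalization flag and, where applicable, the raw
    value of the FID at t=0 before normalization.
    """

    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FID values must be finite")

    @property
    def n_points(self) -> int:
        return len(self.times)

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        if len(self.times) < 2:
            return True
        dt = np.diff(self.times)
        return bool(np.all(np.abs(dt - dt[0]) <= rtol * dt[0]))


@dataclass
class Spectrum:
    """Real-part spectrum on a uniform frequency grid (Hz).

    ``complex_values`` optionally keeps the full complex transform (used by
    energy checks); ``intensities`` is its real part.
    """

    freqs: np.ndarray
    intensities: np.ndarray
    grid_spacing: float
    complex_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.freqs.shape != self.intensities.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and intensities must be 1-D arrays of equal length")
        if len(self.freqs) > 1:
            df = np.diff(self.freqs)
            if not np.allclose(df, df[0], rtol=1e-9, atol=0):
                raise ValueError("frequency grid must be uniform")


@dataclass(frozen=True)
class TransitionLine:
    """A single spectral line: frequency (Hz) and nonnegative amplitude."""

    freq: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("line amplitude must be nonnegative")
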