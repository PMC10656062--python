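"""Noiseless reference dynamics: FIDs, transition tables and spectra.

The measured FID of a one-dimensional NMR experiment is

    FID(t) = Tr[ U(t)^dag M U(t) M ],    U(t) = exp(-i H t),

with M the gamma-weighted total z magnetization.  A single
eigendecomposition of H yields the whole trace as a sum of cosines at the
level-difference frequencies, and the same eigen-pairs give the stick
spectrum (transition table).  The equivalent basis-state form evolves each
positive-magnetization computational state and sums expectation values
weighted by the state's magnetization; the two agree exactly after
normalization (their raw values differ by a factor of two through the
global spin-flip symmetry).
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .signals import FIDTrace, Spectrum, TransitionLine
from .spin_system import (
    OperatorMatrix,
    SpinSystem,
    magnetization_weights,
    positive_magnetization_states,
)

__all__ = [
    "fid_trace_formula",
    "fid_basis_sum",
    "transition_table",
    "apply_dephasing",
    "fid_to_spectrum",
    "default_time_grid",
]

#: Default acquisition grid: 4096 points over 6 s.
DEFAULT_N_POINTS = 4096
DEFAULT_T_MAX = 6.0


def default_time_grid(n_points: int = DEFAULT_N_POINTS, t_max: float = DEFAULT_T_MAX) -> np.ndarray:
    """Uniform grid t_k = k * t_max / n_points, k = 0 .. n_points-1."""
    return np.arange(n_points) * (t_max / n_points)


def _check_pair(h: OperatorMatrix, o: OperatorMatrix) -> None:
    if h.dim != o.dim:
        raise ValueError(f"dimension mismatch: H is {h.dim}, observable is {o.dim}")


def _line_data(h: OperatorMatrix, o: OperatorMatrix):
    """Eigendecompose H and return (frequency_hz, amplitude) for all pairs."""
    energies, vecs = np.linalg.eigh(h.data)
    m = vecs.conj().T @ o.data @ vecs
    amp = np.abs(m) ** 2
    freq = (energies[:, None] - energies[None, :]) / (2 * np.pi)
    return freq.ravel(), amp.ravel()


def fid_trace_formula(h: OperatorMatrix, o: OperatorMatrix, times: np.ndarray,
                      normalize: bool = True) -> FIDTrace:
    """FID from the trace formula via one eigendecomposition of H.

    FID(t) = sum_{a,b} |<a|O|b>|^2 cos((E_a - E_b) t); the output is real by
    construction.  With ``normalize`` the values are scaled so FID(0) = 1 and
    the raw t=0 value Tr[O^2] is kept in ``meta["raw_t0"]``.
    """
    _check_pair(h, o)
    times = np.asarray(times, dtype=float)
    freq, amp = _line_data(h, o)
    keep = amp > 1e-16 * amp.max()
    omega = 2 * np.pi * freq[keep]
    amp = amp[keep]
    values = np.cos(np.outer(times, omega)) @ amp
    raw_t0 = float(amp.sum())  # equals Tr[O^2]
    meta = {"provenance": "exact", "normalized": normalize, "raw_t0": raw_t0}
    if normalize:
        values = values / raw_t0
    return FIDTrace(times, values, meta)


def fid_basis_sum(system: SpinSystem, h: OperatorMatrix, times: np.ndarray,
                  normalize: bool = True) -> FIDTrace:
    """FID as the weighted sum over positive-magnetization basis states.

    FID(t) = sum_{m_n > 0} m_n <n(t)| M |n(t)> with |n(t)> = U(t)|n>.  After
    normalization to FID(0)=1 this equals :func:`fid_trace_formula`; the raw
    values are exactly half the raw trace because the magnetization spectrum
    is symmetric under the global spin flip.
    """
    if h.dim != 2**system.n_sites:
        raise ValueError("Hamiltonian dimension does not match the system")
    times = np.asarray(times, dtype=float)
    weights = magnetization_weights(system)
    states = positive_magnetization_states(system)
    energies, vecs = np.linalg.eigh(h.data)
    values = np.zeros(len(times))
    phases = np.exp(-1j * np.outer(times, energies))  # (T, dim)
    for idx, m_n in states:
        coeff = vecs.conj()[idx, :]  # <a|n>
        psi_t = (phases * coeff[None, :]) @ vecs.T  # (T, dim) amplitudes in basis
        values += m_n * ((np.abs(psi_t) ** 2) @ weights)
    raw_t0 = float(sum(m**2 for _, m in states))
    meta = {
        "provenance": "exact",
        "normalized": normalize,
        "raw_t0": raw_t0,
        "n_initial_states": len(states),
    }
    if normalize:
        values = values / raw_t0
    return FIDTrace(times, values, meta)


def transition_table(h: OperatorMatrix, o: OperatorMatrix,
                     min_amplitude: float = 1e-9,
                     degeneracy_tol_hz: float = 1e-9) -> List[TransitionLine]:
    """Positive-frequency stick spectrum from eigen-pairs of H.

    Lines sit at f = (E_a - E_b)/(2 pi) > 0 with amplitude |<a|O|b>|^2;
    amplitudes of pairs degenerate to within ``degeneracy_tol_hz`` are summed
    into one line, lines weaker than ``min_amplitude`` are dropped, and the
    result is sorted by frequency.
    """
    _check_pair(h, o)
    freq, amp = _line_data(h, o)
    pos = freq > degeneracy_tol_hz
    freq, amp = freq[pos], amp[pos]
    if len(freq) == 0:
        return []
    order = np.argsort(freq)
    freq, amp = freq[order], amp[order]
    lines: List[TransitionLine] = []
    start = 0
    breaks = np.nonzero(np.diff(freq) > degeneracy_tol_hz)[0]
    for end in list(breaks + 1) + [len(freq)]:
        a = amp[start:end].sum()
        if a >= min_amplitude:
            f = float(np.average(freq[start:end], weights=np.maximum(amp[start:end], 1e-300)))
            lines.append(TransitionLine(f, float(a)))
        start = end
    return lines


def apply_dephasing(fid: FIDTrace, t2: float) -> FIDTrace:
    """Multiply the FID by the phenomenological envelope exp(-t/T2).

    ``t2 = numpy.inf`` is the identity.  The spectrum of a dephased single
    line is a Lorentzian of half width at half maximum 1/(2 pi T2) Hz.
    """
    if not t2 > 0:
        raise ValueError(f"T2 must be positive, got {t2}")
    values = fid.values * np.exp(-fid.times / t2)
    meta = dict(fid.meta)
    meta["t2"] = float(t2)
    return FIDTrace(fid.times, values, meta)


def fid_to_spectrum(fid: FIDTrace, remove_dc: bool = True,
                    zero_fill_factor: int = 1) -> Spectrum:
    """Real part of the discrete Fourier transform of a dense uniform FID.

    The frequency grid spacing is 1/(t_max * zero_fill_factor) where
    t_max = n * dt.  With ``remove_dc`` the time-average is subtracted first,
    suppressing the conserved-magnetization peak at 0 Hz.  Nonuniform traces
    must be zero-filled to the dense grid first (see :mod:`nmremu.nus`).
    """
    if not fid.is_uniform():
        raise ValueError("fid_to_spectrum requires a uniformly gridded FID")
    if zero_fill_factor < 1:
        raise ValueError("zero_fill_factor must be >= 1")
    n = fid.n_points
    if n < 2:
        raise ValueError("need at least two points to transform")
    dt = fid.times[1] - fid.times[0]
    x = fid.values - fid.values.mean() if remove_dc else fid.values
    n_fft = n * zero_fill_factor
    spec = np.fft.rfft(x, n=n_fft)
    freqs = np.fft.rfftfreq(n_fft, d=dt)
    return Spectrum(freqs, spec.real, grid_spacing=float(freqs[1]), complex_values=spec)
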