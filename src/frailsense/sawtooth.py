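"""Hysteresis-gated sawtooth-cycle segmentation.

Both exercise accelerometry and the respiratory expansion signal are
quasi-triangular ("sawtooth-like") waveforms; a repetition of an exercise
and a breath are the same geometric object: a rise to a peak followed by a
fall to a trough.  This module implements the shared primitive: band-pass
conditioning, alternating-extrema detection with an amplitude hysteresis
(so sub-threshold wiggles never open a cycle), extremum refinement on the
unfiltered signal (so cycle timing is not biased by the filter), and
assembly into trough→peak→trough cycles.

The hysteresis for accelerometry is derived from the movement-activity
energy threshold: a triangle wave of peak-to-trough amplitude A has
variance A²/12, so the amplitude floor is ``sqrt(12 · threshold)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class SawtoothCycle:
    """One rise/fall cycle of a sawtooth-like waveform."""

    start_time: float
    peak_time: float
    end_time: float
    amplitude: float      # peak-to-trough, signal units
    rise_duration: float
    fall_duration: float
    dominant_axis: str = ""

    def __post_init__(self) -> None:
        if not (self.start_time < self.peak_time < self.end_time):
            raise ValueError("cycle extrema must be strictly ordered")
        if self.amplitude <= 0:
            raise ValueError("cycle amplitude must be positive")

    @property
    def period(self) -> float:
        return self.end_time - self.start_time


def movement_hysteresis(movement_energy_threshold: float) -> float:
    """Peak-to-trough amplitude floor equivalent to a variance threshold."""
    return float(np.sqrt(12.0 * movement_energy_threshold))


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def alternating_extrema(x: np.ndarray, hysteresis: float) -> list[tuple[int, str]]:
    """Indices of alternating minima/maxima separated by ≥ ``hysteresis``.

    Classic reversal-tracking algorithm: a maximum is committed once the
    signal has dropped by the hysteresis below the running maximum, and
    vice versa, which guarantees strict min/max alternation and rejects
    excursions smaller than the hysteresis.
    """
    n = len(x)
    if n == 0:
        return []
    ext: list[tuple[int, str]] = []
    mn = mx = x[0]
    mni = mxi = 0
    mode = 0  # 0 unknown, +1 hunting a maximum, -1 hunting a minimum
    for i in range(1, n):
        v = x[i]
        if v > mx:
            mx, mxi = v, i
        if v < mn:
            mn, mni = v, i
        if mode >= 0 and v < mx - hysteresis:
            ext.append((mxi, "max"))
            mode = -1
            mn, mni = v, i
        elif mode <= 0 and v > mn + hysteresis:
            ext.append((mni, "min"))
            mode = +1
            mx, mxi = v, i
    # end-of-stream flush, so the closing trough of the final cycle is not
    # silently dropped at the recording boundary: a pending minimum that
    # follows a committed maximum is genuine (the max's commit already
    # established the full-hysteresis fall); a pending maximum is only
    # committed once the signal has dropped half a hysteresis below it
    last = ext[-1][0] if ext else 0
    if mode == -1 and mni > last:
        ext.append((mni, "min"))
    elif mode == +1 and mxi > last and mx - x[-1] >= 0.5 * hysteresis:
        ext.append((mxi, "max"))
        j = mxi + int(np.argmin(x[mxi:]))
        if j > mxi:
            ext.append((j, "min"))
    return ext


def _refine(idx: int, raw: np.ndarray, kind: str, radius: int) -> int:
    """Snap an extremum found on the filtered trace to the raw signal."""
    lo = max(0, idx - radius)
    hi = min(len(raw), idx + radius + 1)
    seg = raw[lo:hi]
    off = int(np.argmax(seg)) if kind == "max" else int(np.argmin(seg))
    return lo + off


def segment_cycles(
    raw: np.ndarray,
    fs: float,
    band: tuple[float, float],
    hysteresis: float,
    min_period: float = 0.0,
    refine: bool = True,
    dominant_axis: str = "",
) -> list[SawtoothCycle]:
    """Segment a 1-D waveform into trough→peak→trough cycles.

    ``band`` conditions the signal (Hz); ``hysteresis`` is the amplitude
    floor in signal units; cycles shorter than ``min_period`` seconds are
    discarded as noise-induced micro-cycles.
    """
    raw = np.asarray(raw, dtype=float)
    if len(raw) < 8:
        return []
    filt = bandpass(raw, fs, band[0], band[1])
    ext = alternating_extrema(filt, hysteresis)
    if len(ext) < 3:
        return []
    if refine:
        # refinement radius: a fraction of the local extremum spacing, so a
        # noiseless waveform recovers grid-exact extrema positions
        idxs = [i for i, _ in ext]
        gaps = np.diff(idxs)
        radius = max(2, int(round(0.3 * float(np.min(gaps)))))
        ext = [(_refine(i, raw, k, radius), k) for i, k in ext]
    cycles: list[SawtoothCycle] = []
    for (i0, k0), (i1, k1), (i2, k2) in zip(ext, ext[1:], ext[2:]):
        if (k0, k1, k2) != ("min", "max", "min"):
            continue
        if not (i0 < i1 < i2):
            continue
        period = (i2 - i0) / fs
        if period < min_period:
            continue
        amp = float(filt[ext_index_nearest(filt, i1, "max")] -
                    0.5 * (filt[i0] + filt[i2]))
        # fall back to raw amplitude when refinement moved off the filtered peak
        if amp <= 0:
            amp = float(raw[i1] - 0.5 * (raw[i0] + raw[i2]))
        if amp <= 0:
            continue
        cycles.append(
            SawtoothCycle(
                start_time=i0 / fs,
                peak_time=i1 / fs,
                end_time=i2 / fs,
                amplitude=amp,
                rise_duration=(i1 - i0) / fs,
                fall_duration=(i2 - i1) / fs,
                dominant_axis=dominant_axis,
            )
        )
    return cycles


def ext_index_nearest(x: np.ndarray, idx: int, kind: str, radius: int = 3) -> int:
    lo = max(0, idx - radius)
    hi = min(len(x), idx + radius + 1)
    seg = x[lo:hi]
    off = int(np.argmax(seg)) if kind == "max" else int(np.argmin(seg))
    return lo + off
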