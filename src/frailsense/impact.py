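"""Stage-1 impact detection (wearable-device side).

The on-body device watches the 40 Hz triaxial stream for high-energy
transients.  The energy statistic is the centred moving variance of the
acceleration magnitude over a 0.5 s window (21 samples); its units,
m²/s⁴, match the fall-energy threshold of the personalization table.
When the energy exceeds the threshold at a local maximum, the device
emits the excerpt spanning two seconds before to two seconds after the
impact sample (161 samples) for stage-2 classification, and transfers it
over a 20-byte-block framing codec emulating the BLE GATT payload size.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .config import DetectorConfig
from .errors import FramingError, InsufficientSignal
from .streams import AccelStream

#: Energy window: 0.5 s at 40 Hz, odd so the window is centred.
ENERGY_WINDOW_SAMPLES = 21

#: Excerpt half-width, seconds.
WINDOW_HALF_S = 2.0

#: Minimum separation between two reported impacts, seconds.
REFRACTORY_S = 4.0

#: Codec full scale: ±16 g mapped onto int16.
_FULL_SCALE = 16.0 * 9.81
_SCALE = _FULL_SCALE / 32767.0

_BLOCK = 20
_HEADER_FMT = "<2sBBIHHddd4x"  # magic, version, flags, index, n, fs, scale, t_imp, energy
_HEADER_LEN = struct.calcsize(_HEADER_FMT)
assert _HEADER_LEN == 40


@dataclass
class ImpactWindow:
    """A 2 s pre / 2 s post acceleration excerpt around a candidate impact."""

    impact_index: int            # sample index in the source stream
    impact_time: float           # s
    samples: np.ndarray          # (m, 3) excerpt
    peak_energy: float           # m²/s⁴ at the impact sample
    fs: float = 40.0
    t0: float = 0.0              # time of the first excerpt sample
    truncated: bool = False
    offset: int = field(default=0)  # impact position within the excerpt

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return self.samples.shape[0]


def signal_energy(stream: AccelStream, window_len: int = ENERGY_WINDOW_SAMPLES) -> np.ndarray:
    """Centred moving variance of ‖a‖ per sample, m²/s⁴.

    The window shrinks at the stream edges.  Variance removes the DC
    component, so the series is invariant under adding a constant vector
    to every sample.
    """
    if len(stream) == 0:
        raise InsufficientSignal("cannot compute energy of an empty stream")
    if window_len < 2 or window_len % 2 == 0:
        raise ValueError("window_len must be odd and >= 3")
    return moving_variance(stream.magnitude(), window_len)


def moving_variance(x: np.ndarray, window_len: int) -> np.ndarray:
    """Centred moving variance of a 1-D series, window shrinking at edges."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    half = window_len // 2
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    cnt = (hi - lo).astype(float)
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    var = s2 / cnt - (s1 / cnt) ** 2
    return np.maximum(var, 0.0)


def detect_impacts(
    stream: AccelStream,
    config: DetectorConfig | None = None,
    window_len: int = ENERGY_WINDOW_SAMPLES,
    refractory_s: float = REFRACTORY_S,
) -> list[ImpactWindow]:
    """Find candidate impacts and cut their 2 s pre/post excerpts.

    One window per local maximum of the energy series above the
    fall-energy threshold; maxima closer than the refractory period are
    merged keeping the higher-energy one.  Streams shorter than one
    energy window yield no impacts.
    """
    config = config or DetectorConfig()
    if len(stream) < window_len:
        return []
    energy = signal_energy(stream, window_len)
    thr = config.fall_energy_threshold
    n = len(energy)
    # strict local maxima over the exceedance set (plateaus: keep first sample)
    cand = [
        i for i in range(n)
        if energy[i] > thr
        and (i == 0 or energy[i] > energy[i - 1])
        and (i == n - 1 or energy[i] >= energy[i + 1])
    ]
    # refractory merge, highest energy wins
    kept: list[int] = []
    gap = int(round(refractory_s * stream.fs))
    for i in sorted(cand, key=lambda i: (-energy[i], i)):
        if all(abs(i - j) >= gap for j in kept):
            kept.append(i)
    kept.sort()

    half = int(round(WINDOW_HALF_S * stream.fs))
    windows = []
    for i in kept:
        lo = max(0, i - half)
        hi = min(len(stream), i + half + 1)
        windows.append(
            ImpactWindow(
                impact_index=i,
                impact_time=float(stream.t0 + i / stream.fs),
                samples=stream.a[lo:hi],
                peak_energy=float(energy[i]),
                fs=stream.fs,
                t0=float(stream.t0 + lo / stream.fs),
                truncated=(hi - lo) != 2 * half + 1,
                offset=i - lo,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# 20-byte transfer framing codec
# ---------------------------------------------------------------------------

def pack_frames(window: ImpactWindow) -> list[bytes]:
    """Serialize an excerpt into consecutive 20-byte blocks.

    Layout: a 40-byte header (magic, version, flags, impact index, sample
    count, sampling rate, fixed-point scale, impact time, peak energy)
    followed by int16 little-endian samples, 3 axes per sample, at ±16 g
    full scale; the tail is zero-padded to a whole block.
    """
    n = len(window)
    raw = np.clip(np.round(window.samples / _SCALE), -32768, 32767).astype("<i2")
    header = struct.pack(
        _HEADER_FMT,
        b"IW",
        1,
        1 if window.truncated else 0,
        int(window.impact_index),
        n,
        int(round(window.fs)),
        _SCALE,
        float(window.impact_time),
        float(window.peak_energy),
    )
    payload = header + raw.tobytes()
    if len(payload) % _BLOCK:
        payload += b"\x00" * (_BLOCK - len(payload) % _BLOCK)
    return [payload[i:i + _BLOCK] for i in range(0, len(payload), _BLOCK)]


def unpack_frames(blocks: list[bytes]) -> ImpactWindow:
    """Reassemble an :class:`ImpactWindow` from 20-byte blocks.

    Samples are reproduced to the codec resolution (one int16 quantum at
    ±16 g, about 0.005 m/s²).
    """
    for b in blocks:
        if len(b) != _BLOCK:
            raise FramingError(f"block of {len(b)} bytes; expected {_BLOCK}")
    payload = b"".join(blocks)
    if len(payload) < _HEADER_LEN:
        raise FramingError("missing header blocks")
    magic, version, flags, idx, n, fs, scale, t_imp, energy = struct.unpack(
        _HEADER_FMT, payload[:_HEADER_LEN]
    )
    if magic != b"IW" or version != 1:
        raise FramingError("bad header magic/version")
    need = n * 6
    body = payload[_HEADER_LEN:_HEADER_LEN + need]
    if len(body) < need:
        raise FramingError("payload shorter than the declared sample count")
    raw = np.frombuffer(body, dtype="<i2").reshape(n, 3)
    samples = raw.astype(float) * scale
    half = int(round(WINDOW_HALF_S * fs))
    offset = min(idx, half)
    return ImpactWindow(
        impact_index=idx,
        impact_time=t_imp,
        samples=samples,
        peak_energy=energy,
        fs=float(fs),
        t0=t_imp - offset / fs,
        truncated=bool(flags & 1),
        offset=offset,
    )


def expected_block_count(n_samples: int) -> int:
    """Number of 20-byte blocks for an excerpt of ``n_samples``."""
    return int(np.ceil((n_samples * 6 + _HEADER_LEN) / _BLOCK))
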