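"""Key position traces and basic signal conditioning.

A :class:`KeyTrace` holds the vertical position of one piano key sampled on a
(nominally) uniform 1 kHz grid. Convention: 0 mm at rest, positive downward,
full key travel ~10 mm. Velocity is therefore positive while the key descends
and negative while it ascends; feature code reports magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt, lfilter

from .errors import InsufficientDataError, NonUniformSamplingError

#: sanity band for plausible key positions, mm (spec'd key travel is ~10 mm)
POSITION_BAND_MM = (-0.5, 15.0)

#: tolerated deviation of any sampling interval from the median, as a fraction
#: of the median interval, before a grid counts as non-uniform
UNIFORMITY_RTOL = 0.1


@dataclass
class KeyTrace:
    """Uniformly sampled vertical position of one key.

    Parameters
    ----------
    key_id : int
        MIDI-style key number (any subset of 1..88 is valid input).
    t : ndarray
        Sample times in ms, strictly increasing.
    x : ndarray
        Position in mm, downward positive, 0 at rest.
    v : ndarray, optional
        Velocity in mm/s; populated by :func:`differentiate`.
    depth_range_mm : float
        Calibrated full key travel, used for segmentation thresholds.
    """

    key_id: int
    t: np.ndarray
    x: np.ndarray
    v: np.ndarray | None = None
    depth_range_mm: float = 10.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.shape != self.x.shape:
            raise ValueError("t and x must have the same length")
        if self.v is not None:
            self.v = np.asarray(self.v, dtype=float)
            if self.v.shape != self.x.shape:
                raise ValueError("v must match x in length")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt_ms(self) -> float:
        """Median sampling interval in ms."""
        return float(np.median(np.diff(self.t)))

    @property
    def fs_hz(self) -> float:
        return 1000.0 / self.dt_ms

    def is_uniform(self, rtol: float = UNIFORMITY_RTOL) -> bool:
        dt = np.diff(self.t)
        if dt.size == 0:
            return True
        med = np.median(dt)
        return bool(np.all(np.abs(dt - med) <= rtol * med))

    def with_(self, **kw) -> "KeyTrace":
        """Copy with replaced fields (arrays are not copied)."""
        return replace(self, **kw)

    def shifted(self, dt_ms: float) -> "KeyTrace":
        """Time-shift the whole trace by ``dt_ms``."""
        return self.with_(t=self.t + dt_ms)


def lowpass(trace: KeyTrace, cutoff_hz: float = 20.0, order: int = 2,
            zero_phase: bool = True) -> KeyTrace:
    """Butterworth low-pass the position signal.

    Defaults follow the standard preprocessing for key-position data: a
    second-order Butterworth with 20 Hz cutoff. By default the filter is
    applied forward-backward (zero phase) so event *timing* is unbiased
    across keys — at the cost of doubling the effective magnitude order.
    Note that a 20 Hz cutoff noticeably attenuates the peak velocity of very
    fast strokes (descents of ~50 ms); see the methods note.

    Raises
    ------
    NonUniformSamplingError
        If the grid is not uniform within jitter tolerance.
    InsufficientDataError
        If the trace is shorter than ~3x the filter warm-up.
    """
    if not trace.is_uniform():
        raise NonUniformSamplingError(
            f"key {trace.key_id}: non-uniform sampling grid; resample before filtering")
    nyq = trace.fs_hz / 2.0
    b, a = butter(order, cutoff_hz / nyq)
    warmup = 3 * max(len(a), len(b))
    if trace.n <= 3 * warmup:
        raise InsufficientDataError(
            f"trace of {trace.n} samples too short for order-{order} filtering")
    if zero_phase:
        xf = filtfilt(b, a, trace.x)
    else:
        xf = lfilter(b, a, trace.x)
    return trace.with_(x=xf, v=None)


def differentiate(trace: KeyTrace) -> KeyTrace:
    """Populate velocity (mm/s) by central differences.

    Central differences on the interior, one-sided at the two edges
    (``np.gradient``); exact for locally quadratic position signals.
    """
    if trace.n < 3:
        raise InsufficientDataError("need at least 3 samples to differentiate")
    v = np.gradient(trace.x, trace.t) * 1000.0  # mm/ms -> mm/s
    return trace.with_(v=v)
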