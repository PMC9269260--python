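"""Independent reference implementations used only by the test suite.

These deliberately re-derive results with the dumbest possible code
(per-sample scans, closed forms) so they share no code path with the
library's vectorized implementations.
"""

from __future__ import annotations

import numpy as np

VEL_FLOOR = 2.0  # mm/s, matches the library's refinement floor


def brute_force_segment(t, x, v, depth_range_mm, onset_frac=0.02,
                        bottom_frac=0.95, vel_frac=0.01):
    """Per-sample scan for the keystroke-event definitions.

    Same event *definitions* as ``keykin.segmentation.segment`` (coarse
    position thresholds with 0.5x hysteresis, per-stroke 95% dwell band,
    velocity-refined boundaries) located by linear per-sample scanning.
    Returns a list of dicts with sample indices.
    """
    n = len(x)
    thr = onset_frac * depth_range_mm
    off_thr = 0.5 * thr
    events = []
    prev_offset = -1
    i = 0
    while i < n:
        # next coarse crossing
        while i < n and x[i] < thr:
            i += 1
        if i == n:
            break
        start = i
        while i < n and x[i] >= off_thr:
            i += 1
        end = i  # region is [start, end)

        max_depth = 0.0
        vmax = 0.0
        for j in range(start, end):
            max_depth = max(max_depth, x[j])
            vmax = max(vmax, abs(v[j]))
        if max_depth < 2.0 * thr:
            continue
        vtol = max(vel_frac * vmax, VEL_FLOOR)
        band = bottom_frac * max_depth

        bottom = None
        for j in range(start, end):
            if x[j] >= band and v[j] <= vtol:
                bottom = j
                break
        release = None
        for j in range(end - 1, start - 1, -1):
            if x[j] >= band and v[j] >= -vtol:
                release = j
                break
        if bottom is None or release is None:
            continue

        truncated = start == 0 or end == n
        j = start
        while j - 1 > prev_offset and v[j - 1] > vtol:
            j -= 1
        if j - 1 > prev_offset:
            onset = j - 1
        else:
            onset, truncated = max(j - 1, 0), True
        j = end - 1
        while j + 1 < n and v[j + 1] < -vtol:
            j += 1
        if j + 1 < n:
            offset = j + 1
        else:
            offset, truncated = n - 1, True

        if not (onset < bottom <= release < offset):
            continue
        events.append({"onset": onset, "bottom": bottom, "release": release,
                       "offset": offset, "truncated": truncated})
        prev_offset = offset
    return events


def closed_form_ridge(X, y, alpha):
    """Ridge solution for the elastic-net objective at l1_ratio = 0:

        min_b 1/(2n) ||y - c - Xb||^2 + (alpha/2) ||b||^2

    with free intercept c, i.e. b = (X'X/n + alpha I)^-1 X'y_c/n on
    column-centered data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    b = np.linalg.solve(Xc.T @ Xc / n + alpha * np.eye(p), Xc.T @ yc / n)
    intercept = y.mean() - X.mean(axis=0) @ b
    return b, intercept
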