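import numpy as np
import pytest

from keykin.simulate import AnalyticStroke, StrokeSpec
from keykin.trace import differentiate


@pytest.fixture
def canonical_stroke() -> AnalyticStroke:
    """The reference keystroke: min-jerk 10 mm / 50 ms descent, 100 ms dwell,
    50 ms ascent. Closed-form peak velocity 1.875 * 10 / 0.050 = 375 mm/s."""
    return AnalyticStroke(StrokeSpec(descent_ms=50, dwell_ms=100, ascent_ms=50,
                                     depth_mm=10.0, onset_ms=0.0))


@pytest.fixture
def canonical_trace(canonical_stroke):
    """The canonical stroke sampled at 1 kHz with velocity from the pipeline
    differentiator (central differences), as measured data would be."""
    tr = canonical_stroke.sample(fs_hz=1000.0, pad_ms=50.0)
    return differentiate(tr.with_(v=None))


def match_strokes(true_events, measured_events, tol_ms=20.0):
    """Pair measured strokes to ground-truth strokes by onset proximity."""
    pairs = []
    for te in true_events:
        best = min(measured_events,
                   key=lambda me: abs(me.onset_ms - te.onset_ms), default=None)
        if best is not None and abs(best.onset_ms - te.onset_ms) <= tol_ms:
            pairs.append((te, best))
    return pairs
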