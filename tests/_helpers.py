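"""Test utilities shared across test modules."""

from __future__ import annotations

import numpy as np

from apdecomp.ahp_extraction import NormalizedAP
from apdecomp.config import AnalysisConfig
from apdecomp.core import Trace
from apdecomp.event_detection import detect_eofr, detect_onset


def best_shift_corr(a: np.ndarray, b: np.ndarray, max_shift: int = 30
                    ) -> float:
    """Max Pearson correlation of two vectors over integer relative shifts."""
    best = -1.0
    for s in range(-max_shift, max_shift + 1):
        n = min(len(a) - max(s, 0), len(b) + min(s, 0))
        if n < 10:
            continue
        x = a[max(s, 0):max(s, 0) + n]
        y = b[max(-s, 0):max(-s, 0) + n]
        best = max(best, float(np.corrcoef(x, y)[0, 1]))
    return best


def normalized_ap_from_segment(seg: np.ndarray, dt: float, rmp: float,
                               ap_id: str, noise_sd: float,
                               config: AnalysisConfig | None = None
                               ) -> NormalizedAP:
    """Build a NormalizedAP from a composed AP segment (rmp included)."""
    config = config or AnalysisConfig()
    trace = Trace(samples=np.asarray(seg, dtype=float), dt=dt)
    peak = int(np.argmax(trace.samples))
    onset = detect_onset(trace, rmp, config.onset_threshold_mV, peak)
    eofr, _ = detect_eofr(trace, peak, rmp, config)
    amplitude = float(trace.samples[peak]) - rmp
    v = (trace.samples[onset:] - rmp) / amplitude
    return NormalizedAP(ap_id=ap_id, v=v, peak=peak - onset,
                        eofr=eofr - onset, sigma=noise_sd / amplitude)
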