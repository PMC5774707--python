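"""Slow-AHP isolation: G1 - G0 subtraction and energy classification.

G0 APs contain only the junction potential and the native AP; G1 APs
additionally express one slow AHP (the two slow-AHP species are assumed
mutually exclusive within one AP).  Subtracting the best-matching G0 AP
from a G1 AP therefore estimates the slow-AHP component.

Matching runs across all available cells on amplitude-normalized,
peak-aligned AP vectors; the match is scored by the Euclidean distance over
the fixed window from the G1 AP's onset to its end of first repolarization
(the distance deliberately ignores the tail, which carries the AHP).  A
match is accepted when the window residual energy is comparable to the
noise energy expected for two normalized noisy signals of that length.

Accepted residual tails split into two populations by the midpoint energy
threshold  E_th = (E_max + E_min) / 2 : below it slow AHPs (sAHP, ~200 ms),
at or above it very slow AHPs (vsAHP, ~300 ms, deeper).  Ensemble means of
each category, aligned at the G1 peak (the slow AHP starts at the native-AP
peak) and normalized to unit trough, give the H1 and H2 templates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from apdecomp.config import AnalysisConfig
from apdecomp.core import (
    APAnnotation,
    AlignmentError,
    DegenerateInputError,
    MatchError,
    Trace,
    normalize_template,
    ragged_mean,
)

#: integer shifts tried around exact peak alignment (detected peak indices
#: jitter by a sample or two under baseline noise)
PEAK_SHIFT_RANGE = 3


@dataclass
class NormalizedAP:
    """Amplitude-normalized AP vector with peak-relative landmarks.

    ``v`` spans [onset, EoS) minus RMP, divided by the amplitude, so the
    baseline is ~0 and the peak ~1.  ``sigma`` is the baseline noise SD in
    the same normalized units.
    """

    ap_id: str
    v: np.ndarray
    peak: int          # index of the peak within v
    eofr: int          # index of EoFR within v
    sigma: float

    @classmethod
    def from_annotation(cls, trace: Trace, ap: APAnnotation,
                        noise_sd: float, tail_pad: int = 0) -> "NormalizedAP":
        """``tail_pad`` extends the window past EoS by up to the quiet-run
        length (that stretch is event-free by the EoS definition), so slow
        AHPs whose shallow recovery ends inside the noise band keep their
        full time course."""
        end = min(ap.eos_idx + max(0, tail_pad), len(trace))
        seg = trace.samples[ap.onset_idx:end] - ap.rmp
        return cls(ap_id=ap.id, v=seg / ap.amplitude,
                   peak=ap.peak_idx - ap.onset_idx,
                   eofr=ap.eofr_idx - ap.onset_idx,
                   sigma=noise_sd / ap.amplitude)


@dataclass
class AhpResidual:
    """G1 - G0 residual for one matched pair."""

    g1_id: str
    g0_id: str
    residual: np.ndarray          # full-overlap residual, G1 index space
    tail_start: int               # index of the G1 peak within residual
    eofr: int                     # index of the G1 EoFR within residual
    energy: float                 # sum of squared post-EoFR samples
    D: float                      # match distance over the fixed window
    accepted: bool
    category: Literal["sahp", "vsahp", "reject"] = "reject"

    def __post_init__(self) -> None:
        if self.energy < 0:
            raise MatchError("residual energy must be non-negative")

    @property
    def tail(self) -> np.ndarray:
        """The AHP estimate: residual from the G1 peak onward."""
        return self.residual[self.tail_start:]


def ap_ap_distance(vg1: np.ndarray, vg0: np.ndarray,
                   window: tuple[int, int]) -> float:
    """Euclidean distance between two aligned AP vectors over a fixed window.

    Both vectors must already live in a common index space (normalized and
    peak-aligned); the window is the G1 AP's [onset, EoFR) span.
    """
    lo, hi = window
    if lo < 0 or hi > min(len(vg1), len(vg0)) or hi <= lo:
        raise AlignmentError(f"window {window} exceeds the aligned overlap")
    return float(np.linalg.norm(np.asarray(vg1[lo:hi], dtype=float)
                                - np.asarray(vg0[lo:hi], dtype=float)))


def _aligned_g0(g1: NormalizedAP, g0: NormalizedAP, shift: int
                ) -> np.ndarray | None:
    """G0 vector resampled onto g1's index space, peaks aligned plus shift.

    Returns None when the G0 AP does not cover g1's matching window.
    Positions past the G0 end-of-signal are baseline (zero) extended.
    """
    offset = g0.peak - g1.peak + shift  # g0 index = g1 index + offset
    if offset < 0:
        # G0 onset falls inside g1's window: no data for the early foot
        return None
    out = np.zeros(len(g1.v))
    src = g0.v[offset:offset + len(g1.v)]
    out[:len(src)] = src
    return out


def best_matching_g0(g1: NormalizedAP, g0_pool: list[NormalizedAP]
                     ) -> tuple[NormalizedAP, float, int]:
    """Arg-min of the windowed distance over the G0 pool.

    Peak alignment is refined over +/-``PEAK_SHIFT_RANGE`` integer shifts
    (detected peaks jitter under noise; sub-sample interpolation is not
    used).  Ties go to the first candidate in input order.
    """
    if not g0_pool:
        raise MatchError("empty G0 pool")
    window = (0, g1.eofr)
    best: tuple[NormalizedAP, float, int] | None = None
    for g0 in g0_pool:
        for shift in range(-PEAK_SHIFT_RANGE, PEAK_SHIFT_RANGE + 1):
            aligned = _aligned_g0(g1, g0, shift)
            if aligned is None:
                continue
            try:
                D = ap_ap_distance(g1.v, aligned, window)
            except AlignmentError:
                continue
            if best is None or D < best[1]:
                best = (g0, D, shift)
    if best is None:
        raise MatchError(f"no G0 AP covers the matching window of {g1.ap_id}")
    return best


def extract_residual(g1: NormalizedAP, g0: NormalizedAP, shift: int = 0,
                     D: float | None = None,
                     config: AnalysisConfig | None = None) -> AhpResidual:
    """Subtract the matched G0 AP from the G1 AP and assess the match.

    The pair is accepted when the residual energy over the matching window
    (onset to EoFR) is at most ``energy_factor`` times the expected noise
    energy for two independent normalized noisy signals,
    ``L * (sigma_g1^2 + sigma_g0^2)``.  The residual tail (post-peak) is the
    AHP estimate; ``energy`` is the sum of squared post-EoFR samples.
    """
    config = config or AnalysisConfig()
    aligned = _aligned_g0(g1, g0, shift)
    if aligned is None:
        raise AlignmentError(
            f"G0 {g0.ap_id} does not cover the window of G1 {g1.ap_id}")
    residual = g1.v - aligned
    window = (0, g1.eofr)
    if D is None:
        D = ap_ap_distance(g1.v, aligned, window)
    window_energy = float(np.sum(residual[:g1.eofr] ** 2))
    expected = g1.eofr * (g1.sigma ** 2 + g0.sigma ** 2)
    accepted = window_energy <= config.energy_factor * expected
    energy = float(np.sum(residual[g1.eofr:] ** 2))
    return AhpResidual(g1_id=g1.ap_id, g0_id=g0.ap_id, residual=residual,
                       tail_start=g1.peak, eofr=g1.eofr, energy=energy,
                       D=float(D), accepted=accepted)


def energy_threshold(residuals: list[AhpResidual]) -> float:
    """Midpoint threshold E_th = (E_max + E_min)/2 over accepted residuals."""
    energies = [r.energy for r in residuals if r.accepted]
    if len(energies) < 2:
        raise MatchError("need at least two accepted residuals")
    e_min, e_max = min(energies), max(energies)
    if e_min == e_max:
        raise DegenerateInputError(
            "all residual energies identical; no threshold exists")
    return 0.5 * (e_min + e_max)


def classify_residual(residual: AhpResidual, e_th: float) -> str:
    """sAHP strictly below the energy threshold, vsAHP at or above it."""
    if not residual.accepted:
        return "reject"
    return "sahp" if residual.energy < e_th else "vsahp"


def classify_pool(residuals: list[AhpResidual]) -> float:
    """Assign categories in place over the accepted pool; returns E_th."""
    e_th = energy_threshold(residuals)
    for r in residuals:
        r.category = classify_residual(r, e_th)
    return e_th


def build_ahp_prototypes(residuals: list[AhpResidual]
                         ) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Per-category ensemble means of the residual tails, unit-trough.

    Tails are aligned at their start (the G1 peak — consistent with the
    synthesis convention that the slow AHPs start at the nAP peak) and
    averaged with a ragged mean (each index averages the tails reaching
    it).  An empty category yields None — the model then degrades to three
    components.
    """
    out: list[np.ndarray | None] = []
    for category in ("sahp", "vsahp"):
        tails = [r.tail for r in residuals if r.category == category]
        if not tails:
            out.append(None)
            continue
        out.append(normalize_template(ragged_mean(tails), "trough_negative"))
    return out[0], out[1]
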