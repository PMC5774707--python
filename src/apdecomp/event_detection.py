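"""Event detection, landmarking, classification and standard features.

Detection works on a moving-average-smoothed copy of the trace: a candidate
event is a sustained excursion above RMP + threshold (single noise samples
above threshold are rejected by the minimum-duration rule), and excursions
separated by a short gap are merged, because the fast AHP of an AP can dip
the trace below threshold mid-event.

Landmarks follow the standard terminology:

* onset — first sample above RMP + threshold, searched forward from the
  last at-or-below-RMP sample preceding the peak;
* EoF (end of foot) — valley of the rising-phase slope profile between its
  two peaks (the junction-potential foot and the spike upstroke);
* peak — global maximum of the event;
* EoFR (end of first repolarization) — where the repolarization slope has
  collapsed or the trace first re-crosses RMP, whichever is earlier;
* EoS (end of signal) — start of the first sustained quiet run back inside
  the RMP noise band.

Type A APs show a double-peaked rising-phase slope profile (convex foot fed
by a junction potential) and reach their peak within 50 ms of onset; Type B
(pacemaking) APs ride a ~100 ms ramp foot.  Type A APs split into G0 (no
slow AHP) and G1 (slow AHP with time course >= 100 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from apdecomp.config import AnalysisConfig
from apdecomp.core import (
    APAnnotation,
    APGroup,
    APKind,
    DegenerateInputError,
    DetectionError,
    SejpAnnotation,
    Trace,
)

# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Baseline noise level and the derived hard onset threshold.

    For a pool of recordings the onset threshold is the maximum baseline
    noise SD across recordings, rounded up to the next integer millivolt
    (a noise SD of ~0.9 mV yields the fixed RMP + 1 mV rule).
    """

    sigma_n: float
    onset_threshold: float

    def __post_init__(self) -> None:
        if self.onset_threshold < self.sigma_n:
            raise DetectionError(
                "onset threshold must not be below the noise SD")

    @classmethod
    def from_sigmas(cls, sigmas: list[float]) -> "NoiseModel":
        if not sigmas:
            raise DetectionError("need at least one noise estimate")
        smax = float(max(sigmas))
        return cls(sigma_n=smax, onset_threshold=float(math.ceil(smax)))


# ---------------------------------------------------------------------------
# Elementary estimators
# ---------------------------------------------------------------------------

def estimate_rmp(trace: Trace, window: tuple[int, int]) -> float:
    """Mean membrane potential over an event-free half-open index window."""
    lo, hi = window
    if hi <= lo or lo < 0 or hi > len(trace):
        raise DegenerateInputError(f"empty or out-of-range window {window}")
    return float(np.mean(trace.samples[lo:hi]))


def estimate_noise_sd(trace: Trace, window: tuple[int, int],
                      min_samples: int = 50) -> float:
    """Sample SD of an event-free baseline window (>= 50 samples)."""
    lo, hi = window
    if hi - lo < min_samples:
        raise DegenerateInputError(
            f"noise window needs >= {min_samples} samples, got {hi - lo}")
    return float(np.std(trace.samples[lo:hi], ddof=1))


def smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with reflected ends (length preserved)."""
    if window <= 1:
        return np.asarray(x, dtype=float)
    if window % 2 == 0:
        raise DegenerateInputError("smoothing window must be odd")
    half = window // 2
    padded = np.pad(np.asarray(x, dtype=float), half, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def detect_onset(trace: Trace, rmp: float, threshold: float,
                 peak_idx: int | None = None) -> int:
    """First sample strictly above ``rmp + threshold`` before the peak.

    The search window starts at the last sample at or below ``rmp``
    preceding the event peak, so an earlier unrelated excursion cannot
    capture the onset.
    """
    if threshold <= 0:
        raise DetectionError("onset threshold must be positive")
    v = trace.samples
    if peak_idx is None:
        peak_idx = int(np.argmax(v))
    at_or_below = np.flatnonzero(v[:peak_idx + 1] <= rmp)
    start = int(at_or_below[-1]) if at_or_below.size else 0
    above = np.flatnonzero(v[start:peak_idx + 1] > rmp + threshold)
    if above.size == 0:
        raise DetectionError("no threshold crossing before the peak")
    return start + int(above[0])


def slope_profile(trace: Trace, window: tuple[int, int],
                  smoothing_window: int = 1) -> np.ndarray:
    """First difference of the (optionally smoothed) trace, in mV/ms.

    Length is ``window length - 1``; element ``k`` is the slope between
    samples ``k`` and ``k + 1`` of the window.
    """
    lo, hi = window
    if hi - lo < 3:
        raise DegenerateInputError("slope window needs >= 3 samples")
    seg = smooth(trace.samples[lo:hi], smoothing_window)
    return np.diff(seg) / trace.dt


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def _rising_slope_peaks(profile: np.ndarray, config: AnalysisConfig
                        ) -> tuple[list[int], np.ndarray]:
    """Indices of admissible local maxima of the rising-phase slope profile.

    Boundary maxima are admissible (the junction-potential slope peaks at
    the very start of the rise), hence the -inf padding.  A maximum counts
    only if it exceeds ``double_peak_minor_frac`` of the global maximum.
    """
    padded = np.concatenate(([-np.inf], profile, [-np.inf]))
    peaks, _ = find_peaks(padded)
    peaks = peaks - 1
    floor = config.double_peak_minor_frac * float(np.max(profile))
    return [int(p) for p in peaks if profile[p] >= floor], profile


def has_double_peaked_slope(profile: np.ndarray,
                            config: AnalysisConfig) -> bool:
    """Two admissible slope maxima separated by a sufficiently deep valley."""
    try:
        i, j = _double_peak_pair(profile, config)
    except DetectionError:
        return False
    return True


def _double_peak_pair(profile: np.ndarray, config: AnalysisConfig
                      ) -> tuple[int, int]:
    peaks, profile = _rising_slope_peaks(profile, config)
    if len(peaks) < 2:
        raise DetectionError("single-peaked rising slope profile")
    # the two largest admissible maxima, in time order
    by_height = sorted(peaks, key=lambda p: profile[p], reverse=True)
    candidates = []
    for k in range(1, len(by_height)):
        i, j = sorted((by_height[0], by_height[k]))
        if j - i < 2:
            continue
        valley = float(np.min(profile[i + 1:j]))
        minor = min(profile[i], profile[j])
        if valley < config.double_peak_valley_frac * minor:
            candidates.append((i, j))
    if not candidates:
        raise DetectionError("no valley between rising-phase slope maxima")
    return candidates[0]


def detect_eof(trace: Trace, ap_onset: int, ap_peak: int,
               config: AnalysisConfig) -> int:
    """End of foot: slope-profile valley between the two rising-phase peaks.

    Raises :class:`DetectionError` when the rising phase has a single-peaked
    slope profile (the caller then treats the event as not Type A).
    """
    profile = slope_profile(trace, (ap_onset, ap_peak + 1),
                            config.smoothing_window)
    i, j = _double_peak_pair(profile, config)
    valley = i + 1 + int(np.argmin(profile[i + 1:j]))
    # profile[k] is the slope between window samples k and k+1: the valley
    # instant is the sample after the minimal slope step
    return ap_onset + valley + 1


def detect_eofr(trace: Trace, ap_peak: int, rmp: float,
                config: AnalysisConfig) -> tuple[int, bool]:
    """End of first repolarization (start of the AP tail).

    First index after the peak where the repolarization slope magnitude
    falls below ``eofr_slope_frac`` of its maximum, or where the voltage
    first re-crosses RMP, whichever is earlier.  Returns ``(index,
    truncated)``; ``truncated`` is set when the trace ends first.
    """
    v = trace.samples
    if ap_peak >= len(v) - 2:
        return len(v) - 1, True
    # repolarization completes within tens of ms; a capped segment keeps the
    # scan local to the event
    seg_end = min(len(v), ap_peak + int(round(500.0 / trace.dt)))
    profile = slope_profile(trace, (ap_peak, seg_end), config.smoothing_window)
    repol = -profile  # positive while falling
    max_repol = float(np.max(repol))
    if max_repol <= 0:
        return len(v) - 1, True
    # start checking once the fall is under way, else the zero slope at the
    # (smoothed) peak itself triggers immediately
    started = np.flatnonzero(repol >= 0.5 * max_repol)
    k0 = int(started[0]) if started.size else 0
    flat = np.flatnonzero(repol[k0:] < config.eofr_slope_frac * max_repol)
    idx_flat = ap_peak + k0 + int(flat[0]) if flat.size else None
    below = np.flatnonzero(v[ap_peak:seg_end] <= rmp)
    idx_rmp = ap_peak + int(below[0]) if below.size else None
    candidates = [i for i in (idx_flat, idx_rmp) if i is not None]
    if not candidates:
        return len(v) - 1, True
    return min(candidates), False


def detect_eos(trace: Trace, eofr_idx: int, rmp: float,
               onset_threshold: float, config: AnalysisConfig
               ) -> tuple[int, bool]:
    """End of signal: start of the first sustained quiet run after EoFR.

    Quiet means the smoothed trace stays within ``onset_threshold`` of RMP
    for at least ``eos_quiet_ms``.  Returns ``(index, truncated)``; when the
    criterion is never met the trace-end index is returned with the
    truncated flag set.
    """
    v = smooth(trace.samples[eofr_idx:], config.smoothing_window)
    need = max(1, int(round(config.eos_quiet_ms / trace.dt)))
    quiet = np.abs(v - rmp) < onset_threshold
    start = _first_run(quiet, need)
    if start is None:
        if quiet.size and quiet[-1]:
            # quiet tail shorter than the required run: trace ended too soon
            run_start = quiet.size - 1
            while run_start > 0 and quiet[run_start - 1]:
                run_start -= 1
            return eofr_idx + run_start, True
        return len(trace) - 1, True
    return eofr_idx + start, False


def _first_run(mask: np.ndarray, length: int) -> int | None:
    """Start of the first run of ``length`` consecutive True values."""
    if mask.size < length:
        return None
    if length == 1:
        hits = np.flatnonzero(mask)
        return int(hits[0]) if hits.size else None
    csum = np.cumsum(np.concatenate(([0], mask.astype(int))))
    runs = csum[length:] - csum[:-length]
    hits = np.flatnonzero(runs == length)
    return int(hits[0]) if hits.size else None


def measure_ahp_duration(trace: Trace, eofr_idx: int, eos_idx: int,
                         rmp: float, config: AnalysisConfig) -> float:
    """Duration (ms) of the slow afterhyperpolarization, 0 if none.

    The AHP is the sustained hyperpolarized excursion after EoFR: the
    smoothed trace must stay below ``rmp - onset_threshold/2`` for at least
    ``ahp_min_excursion_ms`` (noise dips do not count).  The duration runs
    from the start of the first such excursion to the end of signal.
    """
    if eos_idx <= eofr_idx:
        return 0.0
    v = smooth(trace.samples[eofr_idx:eos_idx], config.smoothing_window)
    below = v < rmp - 0.5 * config.onset_threshold_mV
    need = max(1, int(round(config.ahp_min_excursion_ms / trace.dt)))
    start = _first_run(below, need)
    if start is None:
        return 0.0
    return (eos_idx - (eofr_idx + start)) * trace.dt


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

#: Type A APs reach their peak within this many ms of onset; Type B APs
#: ride a ~100 ms ramp foot
TYPE_A_MAX_RISE_MS = 50.0


def classify_ap(trace: Trace, onset_idx: int, peak_idx: int,
                config: AnalysisConfig) -> APKind:
    """Type A iff the rising-phase slope profile is double-peaked and the
    onset-to-peak time is under 50 ms; Type B otherwise."""
    rise_ms = (peak_idx - onset_idx) * trace.dt
    if rise_ms >= TYPE_A_MAX_RISE_MS:
        return APKind.TYPE_B
    profile = slope_profile(trace, (onset_idx, peak_idx + 1),
                            config.smoothing_window)
    if has_double_peaked_slope(profile, config):
        return APKind.TYPE_A
    return APKind.TYPE_B


def assign_group(ap: APAnnotation) -> APGroup:
    """G1 iff the slow-AHP time course is >= 100 ms; Type A only."""
    if ap.kind is not APKind.TYPE_A:
        raise DetectionError("G0/G1 groups are undefined for Type B APs")
    return APGroup.G1 if ap.ahp_duration >= 100.0 else APGroup.G0


# ---------------------------------------------------------------------------
# Scalar features
# ---------------------------------------------------------------------------

def _crossing_time(x: np.ndarray, dt: float, level: float, start: int,
                   stop: int, rising: bool) -> float | None:
    """Linearly interpolated time of the first level crossing in [start, stop)."""
    step = 1 if stop >= start else -1
    rng = range(start, stop, step)
    for k in rng:
        if k + 1 >= x.size or k < 0:
            continue
        a, b = x[k], x[k + 1]
        hit = (a < level <= b) if rising else (a >= level > b)
        if hit:
            frac = 0.0 if b == a else (level - a) / (b - a)
            return (k + frac) * dt
    return None


def compute_features(trace: Trace, onset_idx: int, peak_idx: int,
                     eos_idx: int, rmp: float) -> dict[str, float]:
    """Standard scalar features of one event.

    amplitude = peak - RMP; half_width = time spent above RMP + amplitude/2
    (rising to falling crossing); ap_duration = onset-to-EoS time;
    rise_time = 10-90% rise span; fall_time = 90-10% decay span.  A feature
    whose level is not crossed on one limb is NaN.  Features are measured on
    the raw trace (crossing times are linearly interpolated); smoothing
    would clip the sharp spike peak and bias amplitude and half-width.
    """
    v = trace.samples
    peak_v = float(v[peak_idx])
    amplitude = peak_v - rmp
    out = {"amplitude": amplitude}
    end = min(eos_idx + 1, v.size - 1)

    half = rmp + amplitude / 2.0
    t_up = _crossing_time(v, trace.dt, half, onset_idx, peak_idx + 1, True)
    t_down = _crossing_time(v, trace.dt, half, peak_idx, end, False)
    out["half_width"] = (t_down - t_up) if (t_up is not None and
                                            t_down is not None) else float("nan")
    out["ap_duration"] = (eos_idx - onset_idx) * trace.dt

    lo_level = rmp + 0.1 * amplitude
    hi_level = rmp + 0.9 * amplitude
    t10 = _crossing_time(v, trace.dt, lo_level, onset_idx - 1, peak_idx + 1, True)
    t90 = _crossing_time(v, trace.dt, hi_level, onset_idx - 1, peak_idx + 1, True)
    out["rise_time"] = (t90 - t10) if (t10 is not None and
                                       t90 is not None) else float("nan")
    f90 = _crossing_time(v, trace.dt, hi_level, peak_idx, end, False)
    f10 = _crossing_time(v, trace.dt, lo_level, peak_idx, end, False)
    out["fall_time"] = (f10 - f90) if (f10 is not None and
                                       f90 is not None) else float("nan")
    return out


# ---------------------------------------------------------------------------
# Full-trace event detection
# ---------------------------------------------------------------------------

def estimate_baseline(trace: Trace, config: AnalysisConfig
                      ) -> tuple[float, float]:
    """Robust (RMP, noise SD) estimate from the event-free parts of a trace.

    The RMP is the median of the whole trace (events are sparse); the noise
    SD is the sample SD over samples whose smoothed value lies within the
    onset band, which excludes event bodies.
    """
    v = trace.samples
    rmp = float(np.median(v))
    sm = smooth(v, config.smoothing_window)
    quiet = np.abs(sm - rmp) < config.onset_threshold_mV
    if quiet.sum() < 50:
        raise DegenerateInputError("not enough quiet baseline to estimate noise")
    return rmp, float(np.std(v[quiet], ddof=1))


def _event_regions(trace: Trace, rmp: float, config: AnalysisConfig
                   ) -> list[tuple[int, int]]:
    """Sustained above-threshold regions of the smoothed trace, merged."""
    sm = smooth(trace.samples, config.smoothing_window)
    above = sm > rmp + config.onset_threshold_mV
    min_len = max(1, int(round(config.min_event_ms / trace.dt)))
    gap = int(round(config.merge_gap_ms / trace.dt))
    regions: list[tuple[int, int]] = []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[above[edges + 1]] + 1) if edges.size else []
    stops = list(edges[~above[edges + 1]] + 1) if edges.size else []
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(above.size)
    for lo, hi in zip(starts, stops):
        if regions and lo - regions[-1][1] < gap:
            regions[-1] = (regions[-1][0], hi)
        else:
            regions.append((lo, hi))
    return [(lo, hi) for lo, hi in regions if hi - lo >= min_len]


@dataclass
class DetectionResult:
    """Everything detected on one trace."""

    aps: list[APAnnotation] = field(default_factory=list)
    sejps: list[SejpAnnotation] = field(default_factory=list)
    rmp: float = float("nan")
    noise_sd: float = float("nan")
    rejected: int = 0

    @property
    def events(self) -> list:
        return sorted(self.aps + self.sejps, key=lambda e: e.onset_idx)


def detect_events(trace: Trace, config: AnalysisConfig | None = None,
                  id_prefix: str = "ev",
                  rmp: float | None = None) -> DetectionResult:
    """Detect and landmark every event in a trace.

    Events with peak amplitude >= ``ap_amplitude_min_mV`` above RMP are
    treated as APs (landmarked, classified Type A/B, grouped G0/G1);
    smaller ones as sEJPs.  Events whose landmarking fails — truncated at a
    trace edge, no threshold crossing — are counted in ``rejected``.
    """
    config = config or AnalysisConfig()
    if rmp is None:
        rmp, noise_sd = estimate_baseline(trace, config)
    else:
        _, noise_sd = estimate_baseline(trace, config)
    result = DetectionResult(rmp=rmp, noise_sd=noise_sd)
    thr = config.onset_threshold_mV
    n_ap = n_sejp = 0
    for lo, hi in _event_regions(trace, rmp, config):
        try:
            ev = _landmark_region(trace, lo, hi, rmp, config,
                                  id_prefix, n_ap, n_sejp)
        except (DetectionError, DegenerateInputError):
            result.rejected += 1
            continue
        if ev is None:
            result.rejected += 1
        elif isinstance(ev, APAnnotation):
            result.aps.append(ev)
            n_ap += 1
        else:
            result.sejps.append(ev)
            n_sejp += 1
    return result


def _landmark_region(trace: Trace, lo: int, hi: int, rmp: float,
                     config: AnalysisConfig, prefix: str,
                     n_ap: int, n_sejp: int
                     ) -> APAnnotation | SejpAnnotation | None:
    v = trace.samples
    peak = lo + int(np.argmax(v[lo:hi]))
    onset = detect_onset(trace, rmp, config.onset_threshold_mV, peak)
    amplitude = float(v[peak]) - rmp
    if amplitude < config.ap_amplitude_min_mV:
        # junction potential: onset, peak, end (return into the noise band)
        end, truncated = detect_eos(trace, peak, rmp,
                                    config.onset_threshold_mV, config)
        if truncated:
            return None
        feats = compute_features(trace, onset, peak, end, rmp)
        return SejpAnnotation(
            id=f"{prefix}-sejp{n_sejp}", onset_idx=onset, peak_idx=peak,
            end_idx=end, rmp=rmp, amplitude=feats["amplitude"],
            rise_time=feats["rise_time"], fall_time=feats["fall_time"])

    kind = classify_ap(trace, onset, peak, config)
    if kind is APKind.TYPE_A:
        eof = detect_eof(trace, onset, peak, config)
    else:
        eof = onset
    eofr, trunc1 = detect_eofr(trace, peak, rmp, config)
    eos, trunc2 = detect_eos(trace, eofr, rmp, config.onset_threshold_mV,
                             config)
    truncated = trunc1 or trunc2
    feats = compute_features(trace, onset, peak, eos, rmp)
    ahp_ms = measure_ahp_duration(trace, eofr, eos, rmp, config)
    ap = APAnnotation(
        id=f"{prefix}-ap{n_ap}", kind=kind, onset_idx=onset, eof_idx=eof,
        peak_idx=peak, eofr_idx=eofr, eos_idx=eos, rmp=rmp,
        amplitude=feats["amplitude"], half_width=feats["half_width"],
        ap_duration=feats["ap_duration"], ahp_duration=ahp_ms,
        truncated=truncated)
    if kind is APKind.TYPE_A:
        ap.group = assign_group(ap)
    return ap


# ---------------------------------------------------------------------------
# Training-cell selection
# ---------------------------------------------------------------------------

def select_training_cells(cells: list, config: AnalysisConfig | None = None
                          ) -> list:
    """Keep the cells suitable for template training.

    A cell qualifies with (i) at least 5 minutes of recording, (ii) at
    least 5 Type A APs and (iii) at least 5 sEJPs with amplitude strictly
    above 5 mV (all limits configurable).  ``cells`` are objects with
    ``trace``, ``aps`` and ``sejps`` attributes.
    """
    config = config or AnalysisConfig()
    keep = []
    for cell in cells:
        duration_min = cell.trace.duration_ms / 60000.0
        n_type_a = sum(1 for ap in cell.aps if ap.kind is APKind.TYPE_A)
        n_big_sejps = sum(
            1 for s in cell.sejps
            if s.amplitude > config.min_train_sejp_amp_mV)
        if (duration_min >= config.min_train_duration_min
                and n_type_a >= config.min_train_aps
                and n_big_sejps >= config.min_train_sejps):
            keep.append(cell)
    return keep
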