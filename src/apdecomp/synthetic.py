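"""Synthetic recordings with the statistical structure the analysis assumes.

No recordings ship with the method, so the generator emulates the regime the
analysis was designed for: sEJPs with amplitude ~9 +/- 3.5 mV and a rise
time within the observed spread (the default shape rises in ~9.5 ms and
decays fast enough that the ADP does not mask the slow AHPs), Type A APs
with amplitude ~52 +/- 7.6 mV and half-width ~9.7 ms, convex feet produced
by an underlying suprathreshold sEJP, and two slow-AHP populations with
~200 ms and ~300 ms time courses, all riding on a resting membrane
potential near -43 mV with Gaussian baseline noise.

Every Type A AP is composed through the same forward model the analysis
inverts: ``Y = a*S(n-nd) + b*A(n) + c*H1(n) + d*H2(n)`` plus RMP and noise,
and the generator records the full ground truth of every event.

Shape families (double exponential for the sEJP, exponential-foot spike for
the nAP, raised cosine for the slow AHPs) are chosen for closed-form
landmarks so tests have analytic oracles; they are conventions of this
package, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np

from apdecomp.core import ApdecompError, ConfigError, TemplateSet, Trace
from apdecomp.synthesis import component_matrix


# ---------------------------------------------------------------------------
# Shape families
# ---------------------------------------------------------------------------

def sejp_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Analytic peak time of the double-exponential sEJP shape (ms)."""
    return (math.log(decay_tau) - math.log(rise_tau)) / (
        1.0 / rise_tau - 1.0 / decay_tau)


def gen_sejp_shape(amplitude: float, rise_tau: float, decay_tau: float,
                   dt: float, cutoff_frac: float = 0.02) -> np.ndarray:
    """Double-exponential junction-potential shape, scaled so peak = amplitude.

    ``v(t) = k * (exp(-t/decay_tau) - exp(-t/rise_tau))``; the vector starts
    at 0 and is truncated once the decaying tail falls below
    ``cutoff_frac * amplitude``.
    """
    if not (0 < rise_tau < decay_tau):
        raise ConfigError("need 0 < rise_tau < decay_tau")
    t_peak = sejp_peak_time(rise_tau, decay_tau)
    raw_peak = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    # past the peak the normalized shape is bounded by
    # exp(-t/decay_tau)/raw_peak; solve that bound for the cutoff
    t_end = max(2 * t_peak,
                decay_tau * math.log(1.0 / (cutoff_frac * raw_peak)))
    t = np.arange(0.0, t_end + dt, dt)
    raw = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    v = amplitude * raw / raw.max()
    past_peak = t > t_peak
    below = past_peak & (v < cutoff_frac * abs(amplitude))
    if below.any():
        v = v[: int(np.argmax(below)) + 1]
    return v


def gen_nap_shape(amplitude: float, upstroke_ms: float, repol_ms: float,
                  fast_ahp_mV: float, dt: float, *,
                  foot_sharpness: float = 16.0,
                  recovery_tau_ms: float = 35.0,
                  cutoff_mV: float = 0.05) -> np.ndarray:
    """Native-AP shape: concave accelerating foot, spike, fast AHP, recovery.

    The rising phase is ``amplitude * (exp(alpha*t) - 1)/(exp(alpha*Tu) - 1)``
    with ``alpha = foot_sharpness / upstroke_ms`` — slope strictly increasing,
    so its slope profile is single-peaked.  Repolarization is a raised-cosine
    fall from the peak to ``-fast_ahp_mV`` over ``repol_ms``, followed by a
    strictly monotone exponential recovery toward 0.
    """
    if min(amplitude, upstroke_ms, repol_ms, fast_ahp_mV) <= 0:
        raise ConfigError("nAP shape parameters must be positive")
    alpha = foot_sharpness / upstroke_ms
    t_up = np.arange(0.0, upstroke_ms, dt)
    rise = amplitude * np.expm1(alpha * t_up) / np.expm1(alpha * upstroke_ms)
    t_rep = np.arange(0.0, repol_ms, dt)
    fall = amplitude - (amplitude + fast_ahp_mV) * 0.5 * (
        1.0 - np.cos(np.pi * t_rep / repol_ms))
    n_rec = int(math.ceil(recovery_tau_ms
                          * math.log(fast_ahp_mV / cutoff_mV) / dt)) + 1
    t_rec = dt * np.arange(n_rec)
    recovery = -fast_ahp_mV * np.exp(-t_rec / recovery_tau_ms)
    return np.concatenate([rise, np.array([amplitude]), fall[1:], recovery])


def gen_ahp_shape(duration: float, trough_mV: float, dt: float) -> np.ndarray:
    """Negative-going raised cosine: zero at both ends, minimum at mid-course.

    ``v(t) = -trough * (1 - cos(2*pi*t/duration)) / 2`` on ``[0, duration]``.
    """
    if duration <= 100.0:
        raise ConfigError("slow AHP duration must exceed 100 ms")
    t = np.arange(0.0, duration + dt / 2, dt)
    return -trough_mV * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / duration))


def gen_typeb_shape(amplitude: float, ramp_ms: float, dt: float, *,
                    ramp_frac: float = 0.25, upstroke_ms: float = 6.0,
                    repol_ms: float = 18.0, fast_ahp_mV: float = 4.0
                    ) -> np.ndarray:
    """Pacemaking-type AP: ~100 ms linear ramp foot, then a spike.

    Used as the Type B counterpart in classification tests; the ramp foot
    has a flat slope profile, so the rising phase shows a single slope peak
    and the onset-to-peak time is dominated by the ramp.
    """
    ramp_amp = ramp_frac * amplitude
    n_ramp = int(round(ramp_ms / dt))
    ramp = ramp_amp * np.arange(n_ramp) / n_ramp
    spike = gen_nap_shape(amplitude - ramp_amp, upstroke_ms, repol_ms,
                          fast_ahp_mV, dt, foot_sharpness=8.0)
    return np.concatenate([ramp, ramp_amp + spike])


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Study conditions for synthetic cohorts.

    Event statistics follow the regime of long sharp-electrode recordings
    from mouse detrusor: sEJP amplitudes N(9.23, 3.56) mV, Type A AP
    amplitudes N(52.49, 7.60) mV, slow AHP time courses of ~200 ms (sAHP)
    and ~300 ms (vsAHP), RMP near -43 mV.  ``sahp_trough_frac`` /
    ``vsahp_trough_frac`` set the AHP trough as a fraction of the AP
    amplitude; the vsAHP population is deeper and longer, with the two
    populations well separated (no intermediates are observed in the
    tissue).
    """

    dt: float = 0.5                      # ms; resolves the ~9.7 ms half-width
    rmp: float = -43.0                   # mV
    noise_sd: float = 0.5                # mV baseline Gaussian noise SD
    duration_min: float = 10.0           # recording length, minutes
    sejp_rate: float = 3.0               # subthreshold events / min
    ap_rate: float = 1.2                 # Type A APs / min
    typeb_rate: float = 0.1              # Type B APs / min
    frac_g1: float = 0.42                # fraction of Type A APs with slow AHP
    frac_vsahp_given_g1: float = 0.22    # vsAHP share among G1 APs
    sejp_amplitude_mean: float = 9.23    # mV
    sejp_amplitude_sd: float = 3.56      # mV
    sejp_amplitude_floor: float = 1.0    # physical lower bound, mV
    ap_amplitude_mean: float = 52.49     # mV
    ap_amplitude_sd: float = 7.60        # mV
    ap_amplitude_floor: float = 20.0     # mV
    spike_threshold_mV: float = 12.0     # sEJPs above this trigger an AP
    sejp_rise_tau: float = 14.0          # ms (10-90% rise ~9.5 ms)
    sejp_decay_tau: float = 20.0         # ms (90-10% fall ~57 ms)
    sejp_tau_jitter: float = 0.10        # relative SD of per-event tau draw
    nap_upstroke_ms: float = 24.0
    nap_repol_ms: float = 19.0
    nap_fast_ahp_mV: float = 4.0
    nap_foot_sharpness: float = 24.0
    nap_recovery_tau_ms: float = 35.0
    sahp_duration: float = 200.0         # ms
    vsahp_duration: float = 300.0        # ms
    sahp_trough_frac: float = 0.055      # trough depth / AP amplitude
    sahp_trough_frac_sd: float = 0.007
    vsahp_trough_frac: float = 0.10
    vsahp_trough_frac_sd: float = 0.005
    nd_max_ms: float = 8.0               # max sEJP delay in the forward model
    min_gap_ms: float = 300.0            # quiet time between events
    typeb_ramp_ms: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sejp_rate, self.ap_rate, self.typeb_rate) < 0:
            raise ConfigError("event rates must be non-negative")
        for frac in (self.frac_g1, self.frac_vsahp_given_g1):
            if not (0.0 <= frac <= 1.0):
                raise ConfigError("fractions must lie in [0, 1]")
        if not (100.0 < self.sahp_duration < self.vsahp_duration):
            raise ConfigError(
                "need 100 ms < sahp_duration < vsahp_duration")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")

    def replace(self, **kwargs) -> "GeneratorConfig":
        payload = asdict(self)
        payload.update(kwargs)
        return GeneratorConfig(**payload)


@dataclass
class TrueEvent:
    """Ground truth for one generated event."""

    id: str
    kind: Literal["sejp", "typea", "typeb"]
    start_idx: int                       # first sample of the inserted segment
    peak_idx: int                        # global index of the segment maximum
    end_idx: int                         # one past the last inserted sample
    amplitude: float                     # peak above RMP, mV
    group: Literal["G0", "G1", "NA"] = "NA"
    ahp_kind: Literal["none", "sahp", "vsahp"] = "none"
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    nd: int = 0
    rise_tau: float = float("nan")
    decay_tau: float = float("nan")


@dataclass
class SyntheticCell:
    """One synthetic cell recording plus its ground truth."""

    id: str
    trace: Trace
    truth: list[TrueEvent]
    true_templates: TemplateSet

    def events(self, kind: str) -> list[TrueEvent]:
        return [e for e in self.truth if e.kind == kind]


# ---------------------------------------------------------------------------
# Forward composition
# ---------------------------------------------------------------------------

def true_template_set(config: GeneratorConfig) -> TemplateSet:
    """The generator's ground-truth S, A, H1, H2 templates (normalized)."""
    S = gen_sejp_shape(1.0, config.sejp_rise_tau, config.sejp_decay_tau,
                       config.dt)
    A = gen_nap_shape(1.0, config.nap_upstroke_ms, config.nap_repol_ms,
                      config.nap_fast_ahp_mV / config.ap_amplitude_mean,
                      config.dt,
                      foot_sharpness=config.nap_foot_sharpness,
                      recovery_tau_ms=config.nap_recovery_tau_ms,
                      cutoff_mV=0.001)
    H1 = gen_ahp_shape(config.sahp_duration, 1.0, config.dt)
    H2 = gen_ahp_shape(config.vsahp_duration, 1.0, config.dt)
    return TemplateSet(S=S, A=A, H1=H1, H2=H2, dt=config.dt, h_offset=0)


def compose_ap(templates: TemplateSet, a: float, b: float, c: float,
               d: float, nd: int, rmp: float, noise_sd: float,
               rng: np.random.Generator, n_samples: int | None = None
               ) -> tuple[np.ndarray, dict]:
    """Compose one AP segment through the forward model.

    ``Y = C_nd @ (a, b, c, d) + rmp + N(0, noise_sd)``.  Returns the segment
    and a ground-truth record of the parameters.
    """
    foot_span = int(np.argmax(templates.A))
    if not (0 <= nd <= foot_span):
        raise ConfigError(f"nd={nd} outside [0, A-foot span={foot_span}]")
    if n_samples is None:
        n_samples = _required_length(templates, nd)
    C = component_matrix(templates, nd, n_samples)
    clean = C @ np.array([a, b, c, d])
    y = clean + rmp
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_samples)
    truth = {"a": a, "b": b, "c": c, "d": d, "nd": nd,
             "peak_idx": int(np.argmax(clean)),
             "amplitude": float(clean.max())}
    return y, truth


def _required_length(templates: TemplateSet, nd: int) -> int:
    n = max(len(templates.A), nd + len(templates.S))
    peak = int(np.argmax(templates.A)) + templates.h_offset
    for h in (templates.H1, templates.H2):
        if h is not None:
            n = max(n, peak + len(h))
    return n


# ---------------------------------------------------------------------------
# Recording generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise ApdecompError("truncated normal rejection sampling failed")


def _draw_sejp_taus(config: GeneratorConfig, rng: np.random.Generator
                    ) -> tuple[float, float]:
    jit = 1.0 + config.sejp_tau_jitter * rng.standard_normal()
    jit = min(max(jit, 0.6), 1.4)
    rise = config.sejp_rise_tau * jit
    decay = max(config.sejp_decay_tau * jit, rise * 1.05)
    return rise, decay


def gen_recording(config: GeneratorConfig,
                  rng: np.random.Generator | None = None,
                  cell_id: str = "cell0") -> SyntheticCell:
    """Generate one annotated recording.

    Events arrive as a Poisson stream thinned to keep at least
    ``min_gap_ms`` of quiet time between the end of one event and the onset
    of the next.  Subthreshold sEJP amplitudes are truncated below the spike
    threshold; the sEJP underlying each Type A AP is drawn from the
    suprathreshold tail of the same amplitude distribution, and the nAP gain
    is set so the composite peak matches the drawn AP amplitude.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.dt
    n_total = int(round(config.duration_min * 60000.0 / dt))
    templates = true_template_set(config)
    a_peak = int(np.argmax(templates.A))
    nd_max = min(int(round(config.nd_max_ms / dt)), a_peak)

    samples = np.zeros(n_total)
    total_rate = config.sejp_rate + config.ap_rate + config.typeb_rate
    truth: list[TrueEvent] = []
    if total_rate > 0:
        mean_gap_ms = 60000.0 / total_rate
        if mean_gap_ms < 2.0 * config.min_gap_ms:
            raise ConfigError("event rates too high for the minimum gap")
        probs = np.array([config.sejp_rate, config.ap_rate,
                          config.typeb_rate]) / total_rate
        t_ms = rng.exponential(mean_gap_ms)
        counter = 0
        while True:
            start = int(round(t_ms / dt))
            kind = ("sejp", "typea", "typeb")[rng.choice(3, p=probs)]
            seg, event = _make_event(kind, config, templates, nd_max, rng,
                                     f"{cell_id}-e{counter}")
            if start + seg.size + 1 >= n_total:
                break
            samples[start:start + seg.size] += seg
            event.start_idx = start
            event.peak_idx += start
            event.end_idx = start + seg.size
            truth.append(event)
            counter += 1
            t_ms = (start + seg.size) * dt + config.min_gap_ms \
                + rng.exponential(mean_gap_ms)
    samples += config.rmp
    if config.noise_sd > 0:
        samples += rng.normal(0.0, config.noise_sd, size=n_total)
    trace = Trace(samples=samples, dt=dt, t0=0.0)
    return SyntheticCell(id=cell_id, trace=trace, truth=truth,
                         true_templates=templates)


def _make_event(kind: str, config: GeneratorConfig, templates: TemplateSet,
                nd_max: int, rng: np.random.Generator, event_id: str
                ) -> tuple[np.ndarray, TrueEvent]:
    dt = config.dt
    if kind == "sejp":
        amp = _truncated_normal(rng, config.sejp_amplitude_mean,
                                config.sejp_amplitude_sd,
                                lo=config.sejp_amplitude_floor,
                                hi=config.spike_threshold_mV)
        rise, decay = _draw_sejp_taus(config, rng)
        seg = gen_sejp_shape(amp, rise, decay, dt)
        return seg, TrueEvent(id=event_id, kind="sejp", start_idx=0,
                              peak_idx=int(np.argmax(seg)), end_idx=0,
                              amplitude=amp, rise_tau=rise, decay_tau=decay)
    if kind == "typeb":
        amp = _truncated_normal(rng, config.ap_amplitude_mean,
                                config.ap_amplitude_sd,
                                lo=config.ap_amplitude_floor)
        seg = gen_typeb_shape(amp, config.typeb_ramp_ms, dt)
        return seg, TrueEvent(id=event_id, kind="typeb", start_idx=0,
                              peak_idx=int(np.argmax(seg)), end_idx=0,
                              amplitude=amp)
    # Type A: suprathreshold sEJP plus nAP, optional slow AHP
    a = _truncated_normal(rng, config.sejp_amplitude_mean,
                          config.sejp_amplitude_sd,
                          lo=config.spike_threshold_mV)
    amp = _truncated_normal(rng, config.ap_amplitude_mean,
                            config.ap_amplitude_sd,
                            lo=config.ap_amplitude_floor)
    nd = int(rng.integers(0, nd_max + 1))
    a_peak = int(np.argmax(templates.A))
    s_at_peak = 0.0
    if 0 <= a_peak - nd < len(templates.S):
        s_at_peak = float(templates.S[a_peak - nd])
    b = max(amp - a * s_at_peak, 1.0)
    c = d = 0.0
    group = "G0"
    ahp_kind = "none"
    if rng.random() < config.frac_g1:
        group = "G1"
        if rng.random() < config.frac_vsahp_given_g1:
            ahp_kind = "vsahp"
            d = amp * _truncated_normal(rng, config.vsahp_trough_frac,
                                        config.vsahp_trough_frac_sd, lo=0.01)
        else:
            ahp_kind = "sahp"
            c = amp * _truncated_normal(rng, config.sahp_trough_frac,
                                        config.sahp_trough_frac_sd, lo=0.01)
    seg, comp_truth = compose_ap(templates, a, b, c, d, nd, rmp=0.0,
                                 noise_sd=0.0, rng=rng)
    return seg, TrueEvent(id=event_id, kind="typea", start_idx=0,
                          peak_idx=comp_truth["peak_idx"], end_idx=0,
                          amplitude=comp_truth["amplitude"], group=group,
                          ahp_kind=ahp_kind, a=a, b=b, c=c, d=d, nd=nd)


def gen_cohort(n_cells: int, config: GeneratorConfig,
               seed: int | None = None) -> list[SyntheticCell]:
    """Generate ``n_cells`` independent recordings under one config."""
    root = np.random.default_rng(config.seed if seed is None else seed)
    cells = []
    for i in range(n_cells):
        child = np.random.default_rng(root.integers(0, 2**31 - 1))
        cells.append(gen_recording(config, rng=child, cell_id=f"cell{i}"))
    return cells
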