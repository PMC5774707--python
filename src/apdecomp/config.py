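"""Analysis configuration with documented defaults and YAML round-trip.

Every constant the method leaves open — onset threshold, slope smoothing,
double-peak criteria, quiet-run length, multiplier grid, residual-energy
acceptance, threshold-pool purity — lives here so a run is fully described
by its config plus seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from apdecomp.core import ConfigError

CONFIG_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    """Tunable constants of the detection/matching/fitting pipeline.

    Attributes
    ----------
    onset_threshold_mV : float
        Hard onset threshold above RMP.  Default 1.0 mV: baseline noise SD
        in sharp-electrode recordings runs up to ~0.9 mV and is rounded up
        to a fixed 1 mV rule.
    min_event_ms : float
        Minimum time the smoothed trace must stay above threshold for a
        crossing to count as an event (rejects single-sample noise spikes).
    merge_gap_ms : float
        Crossings separated by less than this are merged into one event
        (an AP's fast AHP can dip the trace below threshold mid-event).
    smoothing_window : int
        Moving-average window (samples) applied before differencing when
        computing slope profiles.  Raw derivatives of noisy traces have no
        readable double peak.
    double_peak_minor_frac : float
        A rising-phase slope maximum counts as a real peak if it exceeds
        this fraction of the global rising-slope maximum.  The junction
        potential's slope peak is an order of magnitude below the spike's,
        so this is small.
    double_peak_valley_frac : float
        The valley between the two slope peaks must fall below this
        fraction of the smaller peak.
    eofr_slope_frac : float
        End of first repolarization: first post-peak index where the
        repolarization slope magnitude drops below this fraction of the
        peak repolarization slope (or the RMP re-crossing if earlier).
    eos_quiet_ms : float
        End of signal: start of the first run of at least this many ms with
        |V - RMP| below the onset threshold.
    ahp_min_excursion_ms : float
        A post-EoFR hyperpolarized excursion must last at least this long
        to count toward the AHP duration (guards against noise dips).
    n_multipliers : int
        Size of the sEJP multiplier grid on the open interval (1, 1.5).
    multiplier_lo, multiplier_hi : float
        Bounds of the multiplier interval (open; the grid is inset by half
        a step at both ends).
    v2f_min_mV : float
        Foot samples smaller than this in the second half reject the pair
        (the relative-error distance term is undefined near zero).
    foot_accept_sigma : float
        Accept an AP-sEJP pair when the residual foot mean |value| is below
        this multiple of the baseline noise SD.
    min_pairs_per_cell : int
        A cell contributes to the sEJP/nAP prototypes only with at least
        this many accepted AP-sEJP pairs.
    energy_factor : float
        A G1-G0 match is accepted when the residual energy in the matching
        window is at most this multiple of the expected noise energy.
    n_matching : int
        Number of nearest neighbours used for the specific RMSE threshold.
    purity_factor : float
        Drop an AP from threshold estimation when the RMSE spread of its
        nearest-neighbour set exceeds this multiple of the median spread
        (automatic replacement for visual curation of mixed-class sets).
    min_train_duration_min, min_train_aps, min_train_sejps,
    min_train_sejp_amp_mV : training-cell selection rule (at least 5 min,
        at least 5 Type A APs, at least 5 sEJPs with amplitude > 5 mV).
    nonnegative_ahp : bool
        Constrain c, d >= 0 in the synthesis fit.  Off by default; the
        least-squares solution is unconstrained.
    """

    onset_threshold_mV: float = 1.0
    min_event_ms: float = 10.0
    merge_gap_ms: float = 100.0
    smoothing_window: int = 15
    double_peak_minor_frac: float = 0.008
    double_peak_valley_frac: float = 0.8
    max_foot_ms: float = 50.0
    eofr_slope_frac: float = 0.10
    eos_quiet_ms: float = 50.0
    ahp_min_excursion_ms: float = 20.0
    ap_amplitude_min_mV: float = 20.0
    n_multipliers: int = 1000
    multiplier_lo: float = 1.0
    multiplier_hi: float = 1.5
    v2f_min_mV: float = 0.1
    foot_accept_sigma: float = 3.0
    min_pairs_per_cell: int = 4
    energy_factor: float = 2.0
    n_matching: int = 10
    purity_factor: float = 5.0
    min_train_duration_min: float = 5.0
    min_train_aps: int = 5
    min_train_sejps: int = 5
    min_train_sejp_amp_mV: float = 5.0
    nonnegative_ahp: bool = False

    def __post_init__(self) -> None:
        if self.onset_threshold_mV <= 0:
            raise ConfigError("onset_threshold_mV must be positive")
        if not (self.multiplier_lo < self.multiplier_hi):
            raise ConfigError("multiplier interval is empty")
        if self.n_multipliers < 2:
            raise ConfigError("n_multipliers must be >= 2")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigError("smoothing_window must be a positive odd integer")

    def to_yaml(self, path: str | Path) -> None:
        payload = {"schema_version": CONFIG_SCHEMA_VERSION, **asdict(self)}
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.pop("schema_version", None)
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        return cls(**payload)
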