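"""Domain types, file I/O and alignment primitives shared by all stages.

Conventions used throughout the package:

* voltages are in mV, times in ms; traces are uniformly sampled;
* sample indexing is 0-based and windows are half-open ``[start, end)``;
* template vectors are dimensionless: baseline (first sample) at zero and
  either peak = +1 (sEJP, nAP) or trough = -1 (sAHP, vsAHP);
* alignment between vectors is integer-shift only, no sub-sample
  interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ApdecompError(Exception):
    """Base class for all apdecomp errors."""


class TraceFormatError(ApdecompError):
    """Malformed trace file (non-uniform sampling, bad columns, ...)."""


class TraceParseError(ApdecompError):
    """Non-numeric or otherwise unparseable row in a trace file."""


class DegenerateInputError(ApdecompError):
    """Input carries no usable signal (constant vector, empty window, ...)."""


class AlignmentError(ApdecompError):
    """Integer-shift alignment produced an empty overlap."""


class DetectionError(ApdecompError):
    """Event or landmark detection failed."""


class LandmarkError(ApdecompError):
    """Landmark indices violate their ordering contract."""


class MatchError(ApdecompError):
    """Template matching produced no valid candidate."""


class FitError(ApdecompError):
    """Least-squares synthesis failed (rank deficiency, bad window, ...)."""


class ConfigError(ApdecompError):
    """Invalid or incomplete configuration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class APKind(str, Enum):
    TYPE_A = "TypeA"
    TYPE_B = "TypeB"


class APGroup(str, Enum):
    G0 = "G0"
    G1 = "G1"
    NA = "NA"


@dataclass
class Trace:
    """A uniformly sampled membrane-potential time series.

    Parameters
    ----------
    samples : ndarray
        Membrane potential in mV.
    dt : float
        Sampling interval in ms.
    t0 : float
        Time of the first sample in ms.
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise TraceFormatError(f"dt must be positive, got {self.dt}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise TraceFormatError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise TraceFormatError("trace contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return self.dt * (self.samples.size - 1)


@dataclass
class SejpAnnotation:
    """A detected spontaneous excitatory junction potential."""

    id: str
    onset_idx: int
    peak_idx: int
    end_idx: int
    rmp: float
    amplitude: float
    rise_time: float = float("nan")
    fall_time: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.onset_idx < self.peak_idx <= self.end_idx):
            raise LandmarkError(
                f"sEJP landmarks out of order: onset={self.onset_idx} "
                f"peak={self.peak_idx} end={self.end_idx}"
            )
        if self.amplitude <= 0:
            raise LandmarkError("sEJP amplitude must be positive")


@dataclass
class APAnnotation:
    """A detected spontaneous action potential with its landmarks.

    Landmarks follow the standard terminology: onset, end of foot (EoF),
    peak, end of first repolarization (EoFR) and end of signal (EoS).
    ``group`` is only meaningful for Type A APs: G1 APs express a slow AHP
    (time course >= 100 ms), G0 APs do not.
    """

    id: str
    kind: APKind
    onset_idx: int
    eof_idx: int
    peak_idx: int
    eofr_idx: int
    eos_idx: int
    rmp: float
    amplitude: float
    group: APGroup = APGroup.NA
    half_width: float = float("nan")
    ap_duration: float = float("nan")
    ahp_duration: float = 0.0
    truncated: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.kind, str):
            self.kind = APKind(self.kind)
        if isinstance(self.group, str):
            self.group = APGroup(self.group)
        ok = (self.onset_idx <= self.eof_idx <= self.peak_idx
              <= self.eofr_idx <= self.eos_idx)
        if not ok:
            raise LandmarkError(
                f"AP landmarks out of order: {self.onset_idx}, {self.eof_idx},"
                f" {self.peak_idx}, {self.eofr_idx}, {self.eos_idx}"
            )
        if self.amplitude <= 0:
            raise LandmarkError("AP amplitude must be positive")
        if self.group is not APGroup.NA and self.kind is not APKind.TYPE_A:
            raise LandmarkError("G0/G1 groups are defined only for Type A APs")


@dataclass
class TemplateSet:
    """The four normalized component prototypes and their alignment.

    ``S`` (sEJP) and ``A`` (nAP) are unit-peak, ``H1`` (sAHP) and ``H2``
    (vsAHP) are unit-trough (most negative value = -1); every template is
    baseline-zeroed at its first sample.  ``h_offset`` is the sample offset
    of the H1/H2 start relative to the peak of ``A``; the default 0 places
    the slow-AHP components exactly at the nAP peak.
    """

    S: np.ndarray
    A: np.ndarray
    H1: np.ndarray | None
    H2: np.ndarray | None
    dt: float
    h_offset: int = 0

    _FILES = {
        "S": "sejp_template.txt",
        "A": "nap_template.txt",
        "H1": "sahp_template.txt",
        "H2": "vsahp_template.txt",
    }
    _MODES = {"S": "peak_positive", "A": "peak_positive",
              "H1": "trough_negative", "H2": "trough_negative"}

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.H1 is not None:
            self.H1 = np.asarray(self.H1, dtype=float)
        if self.H2 is not None:
            self.H2 = np.asarray(self.H2, dtype=float)
        if self.dt <= 0:
            raise ConfigError("template dt must be positive")

    @property
    def a_peak_idx(self) -> int:
        return int(np.argmax(self.A))

    def components(self) -> dict[str, np.ndarray | None]:
        return {"S": self.S, "A": self.A, "H1": self.H1, "H2": self.H2}

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, vec in self.components().items():
            if vec is None:
                continue
            header = {"dt_ms": self.dt, "mode": self._MODES[name]}
            if name in ("H1", "H2"):
                header["h_offset"] = self.h_offset
            save_template(out_dir / self._FILES[name], vec, **header)

    @classmethod
    def load(cls, in_dir: str | Path) -> "TemplateSet":
        in_dir = Path(in_dir)
        vecs: dict[str, np.ndarray | None] = {}
        dt = None
        h_offset = 0
        for name, fname in cls._FILES.items():
            path = in_dir / fname
            if not path.exists():
                if name in ("H1", "H2"):
                    vecs[name] = None
                    continue
                raise TraceFormatError(f"missing template file {path}")
            vec, meta = load_template(path)
            vecs[name] = vec
            dt = float(meta.get("dt_ms", dt if dt is not None else 0.5))
            if name in ("H1", "H2") and "h_offset" in meta:
                h_offset = int(float(meta["h_offset"]))
        return cls(S=vecs["S"], A=vecs["A"], H1=vecs["H1"], H2=vecs["H2"],
                   dt=float(dt), h_offset=h_offset)


@dataclass
class Decomposition:
    """The fitted parameters of the four-component synthesis of one AP.

    ``a, b`` are in mV (S, A are unit-peak); ``c, d`` are in mV (H1, H2 are
    unit-trough); ``nd`` is the sEJP delay in samples, constrained to the
    interval [onset, peak] of the fitted AP.
    """

    ap_id: str
    a: float
    b: float
    c: float
    d: float
    nd: int
    rmse: float
    threshold_used: float = float("nan")
    condition_number: float = float("nan")
    n1: int = 0
    n2: int = 0

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise FitError("rmse must be non-negative")
        if not (self.n1 <= self.nd <= self.n2):
            raise FitError(
                f"nd={self.nd} outside delay interval [{self.n1}, {self.n2}]")

    @property
    def good_fit(self) -> bool:
        return bool(self.rmse < self.threshold_used)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d])


@dataclass
class RmseThresholds:
    """Per-AP specific RMSE thresholds and the universal threshold T (mV).

    The universal threshold is defined as the mean of the specific ones;
    it is used for APs that do not belong to the training pool.
    """

    specific: dict[str, float]
    universal_T: float

    def __post_init__(self) -> None:
        if self.specific:
            if any(v <= 0 for v in self.specific.values()):
                raise ConfigError("specific thresholds must be positive")
            mean = float(np.mean(list(self.specific.values())))
            if not np.isclose(mean, self.universal_T, rtol=1e-9, atol=1e-12):
                raise ConfigError(
                    "universal_T must equal the mean of specific thresholds")

    def threshold_for(self, ap_id: str) -> float:
        """Specific threshold when available, universal T otherwise."""
        return self.specific.get(ap_id, self.universal_T)


# ---------------------------------------------------------------------------
# Trace I/O (CSV: time_ms, voltage_mV)
# ---------------------------------------------------------------------------

TRACE_HEADER = ("time_ms", "voltage_mV")
_DT_RTOL = 1e-6


def read_trace(path: str | Path) -> Trace:
    """Read a two-column CSV trace (time in ms, voltage in mV).

    The time column must be uniformly sampled to within a relative
    tolerance of 1e-6; ``dt`` is inferred from it.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001 - normalize to package error
        raise TraceParseError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise TraceFormatError(f"{path}: expected two columns, got {df.shape[1]}")
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    v = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(t) | ~np.isfinite(v))
    if bad.size:
        # +2: 1-based line numbering plus the header line
        raise TraceParseError(f"{path}: non-numeric row at line {bad[0] + 2}")
    if t.size < 2:
        raise TraceFormatError(f"{path}: trace needs at least 2 rows")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or np.any(np.abs(steps - dt) > _DT_RTOL * max(abs(dt), 1.0)):
        raise TraceFormatError(f"{path}: non-uniform sampling")
    return Trace(samples=v, dt=dt, t0=float(t[0]))


def write_trace(path: str | Path, trace: Trace) -> None:
    """Write a trace as CSV with header ``time_ms,voltage_mV``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(",".join(TRACE_HEADER) + "\n")
        for k, v in enumerate(trace.samples):
            fh.write(f"{trace.t0 + k * trace.dt:.17g},{v:.17g}\n")


# ---------------------------------------------------------------------------
# Template I/O (plain text, one sample per line, '#' metadata headers)
# ---------------------------------------------------------------------------

def save_template(path: str | Path, vector: np.ndarray, **meta: object) -> None:
    """Save a template vector: '#' header lines with metadata, one sample/line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key} = {value}\n")
        for v in np.asarray(vector, dtype=float):
            fh.write(f"{v:.17g}\n")


def load_template(path: str | Path) -> tuple[np.ndarray, dict[str, str]]:
    """Load a template vector and its '#'-header metadata."""
    meta: dict[str, str] = {}
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise TraceParseError(
                    f"{path}: non-numeric template line {lineno}") from exc
    return np.array(values), meta


# ---------------------------------------------------------------------------
# Annotation I/O (JSON array of event objects)
# ---------------------------------------------------------------------------

def _event_to_dict(event) -> dict:
    out = {}
    for f in fields(event):
        val = getattr(event, f.name)
        if isinstance(val, Enum):
            val = val.value
        elif isinstance(val, (np.integer,)):
            val = int(val)
        elif isinstance(val, (np.floating,)):
            val = float(val)
        out[f.name] = val
    out["event_type"] = "ap" if isinstance(event, APAnnotation) else "sejp"
    return out


def write_annotations(path: str | Path,
                      events: list[APAnnotation | SejpAnnotation],
                      extra: Mapping[str, object] | None = None) -> None:
    """Write events to a JSON file mirroring the annotation types."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload: dict[str, object] = {"events": [_event_to_dict(e) for e in events]}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_annotations(path: str | Path
                     ) -> list[APAnnotation | SejpAnnotation]:
    """Read events written by :func:`write_annotations`."""
    with open(path) as fh:
        payload = json.load(fh)
    events: list[APAnnotation | SejpAnnotation] = []
    for obj in payload["events"]:
        obj = dict(obj)
        etype = obj.pop("event_type")
        cls = APAnnotation if etype == "ap" else SejpAnnotation
        allowed = {f.name for f in fields(cls)}
        events.append(cls(**{k: v for k, v in obj.items() if k in allowed}))
    return events


# ---------------------------------------------------------------------------
# Normalization and alignment primitives
# ---------------------------------------------------------------------------

def normalize_template(v: np.ndarray, mode: str) -> np.ndarray:
    """Baseline-zero and unit-scale a component vector.

    The baseline reference is the first sample (templates are extracted
    starting at onset, where the signal equals baseline).  ``peak_positive``
    scales so max = 1; ``trough_negative`` so min = -1.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise DegenerateInputError("vector too short to normalize")
    w = v - v[0]
    if mode == "peak_positive":
        ext = float(np.max(w))
    elif mode == "trough_negative":
        ext = float(np.min(w))
    else:
        raise ConfigError(f"unknown normalization mode {mode!r}")
    if ext == 0.0:
        raise DegenerateInputError(
            f"vector has no {mode} extremum relative to its baseline")
    return w / abs(ext)


def ragged_mean(vectors: list[np.ndarray],
                length_percentile: float = 75.0) -> np.ndarray:
    """Mean of start-aligned vectors of unequal length.

    The output length is the given percentile of the input lengths; each
    index averages the vectors that reach it.  Signals here converge to
    baseline, so vectors that end early (their event finished sooner) simply
    stop contributing — truncating everything to the shortest vector would
    let a single early-ending event clip the ensemble.
    """
    if not vectors:
        raise DegenerateInputError("no vectors to average")
    lengths = [len(v) for v in vectors]
    n = max(2, int(np.percentile(lengths, length_percentile)))
    total = np.zeros(n)
    count = np.zeros(n)
    for v in vectors:
        k = min(len(v), n)
        total[:k] += np.asarray(v[:k], dtype=float)
        count[:k] += 1
    return total / np.maximum(count, 1)


def anchored_mean(vectors: list[np.ndarray], anchors: list[int],
                  length_percentile: float = 75.0
                  ) -> tuple[np.ndarray, int]:
    """Ragged mean of vectors aligned at a per-vector anchor index.

    The output is anchored at the median anchor; each index averages the
    vectors that cover it.  Used to average AP vectors at their peak — the
    sharpest landmark — so the steep spike flanks do not smear the ensemble
    the way onset-aligned averaging would.  Returns ``(mean, anchor)``.
    """
    if not vectors or len(vectors) != len(anchors):
        raise DegenerateInputError("vectors and anchors must pair up")
    anchors = [int(a) for a in anchors]
    a_out = int(np.median(anchors))
    tails = [len(v) - a for v, a in zip(vectors, anchors)]
    n = a_out + max(2, int(np.percentile(tails, length_percentile)))
    total = np.zeros(n)
    count = np.zeros(n)
    for v, a in zip(vectors, anchors):
        off = a_out - a
        lo = max(0, off)
        hi = min(n, off + len(v))
        if hi <= lo:
            continue
        total[lo:hi] += np.asarray(v[lo - off:hi - off], dtype=float)
        count[lo:hi] += 1
    return total / np.maximum(count, 1), a_out


def alignment_shift(fixed_anchor: int, moving_anchor: int) -> int:
    """Integer shift that maps ``moving_anchor`` onto ``fixed_anchor``."""
    return int(fixed_anchor) - int(moving_anchor)


def align_by_index(fixed: np.ndarray, moving: np.ndarray,
                   fixed_anchor: int, moving_anchor: int
                   ) -> tuple[np.ndarray, int]:
    """Shift ``moving`` onto the index space of ``fixed`` (integer shift only).

    Returns the aligned vector (same length as ``fixed``) and the applied
    shift.  Positions with no source sample are NaN, never silently zero.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if not (0 <= fixed_anchor < fixed.size):
        raise AlignmentError("fixed anchor out of bounds")
    if not (0 <= moving_anchor < moving.size):
        raise AlignmentError("moving anchor out of bounds")
    shift = alignment_shift(fixed_anchor, moving_anchor)
    aligned = np.full(fixed.size, np.nan)
    dst_lo = max(0, shift)
    dst_hi = min(fixed.size, moving.size + shift)
    if dst_hi <= dst_lo:
        raise AlignmentError("empty overlap after alignment")
    aligned[dst_lo:dst_hi] = moving[dst_lo - shift:dst_hi - shift]
    return aligned, shift
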