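"""sEJP/nAP isolation by differentially weighted foot matching.

A G0 AP is assumed to contain only two components: the junction potential
that triggered it and the native AP.  The junction potential underlying an
AP is approximated by an amplified version (multiplier m in the open
interval (1, 1.5)) of the best-matching subthreshold sEJP recorded in the
same cell.  The match is scored on the AP foot (onset to end-of-foot)
against an equal-length section of the sEJP's rising phase with a
differentially weighted distance:

    d1 = || V1f - m * V1s ||                     (first halves, mV)
    d2 = sum_k ((V2f[k] - m * V2s[k]) / V2f[k])^2  (second halves, relative)
    D  = d1 + d2

The second half carries a reduced weight, so the partially active (spike
contaminated) late foot cannot inflate the multiplier.  d1 is an unsquared
Euclidean norm in mV and d2 a dimensionless sum of squares; their sum mixes
units exactly as the defining equations do and is implemented literally.

Subtracting the amplified best match from the AP (onsets aligned) yields
the native-AP estimate; per-cell means of the shortlisted pairs, then the
cross-cell mean, give the universal sEJP and nAP prototypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from apdecomp.config import AnalysisConfig
from apdecomp.core import (
    APAnnotation,
    DegenerateInputError,
    MatchError,
    SejpAnnotation,
    Trace,
    anchored_mean,
    normalize_template,
    ragged_mean,
)


class CandidateSkip(MatchError):
    """This sEJP candidate cannot be used for this AP (not fatal)."""


@dataclass
class FootMatch:
    """Best multiplier and distance of one AP-sEJP pairing."""

    ap_id: str
    sejp_id: str
    m: float
    D: float
    d1: float
    d2: float
    L: int
    accepted: bool = True

    def __post_init__(self) -> None:
        if self.D < 0 or self.L <= 0:
            raise MatchError("invalid foot match")

    @property
    def Dnorm(self) -> float:
        """Distance normalized by the foot length, for cross-AP shortlists."""
        return self.D / self.L


def foot_vector(trace: Trace, ap: APAnnotation) -> np.ndarray:
    """Baseline-subtracted AP foot: samples [onset, EoF) minus RMP."""
    L = ap.eof_idx - ap.onset_idx
    if L < 4:
        raise DegenerateInputError(
            f"foot of {ap.id} too short to split into halves (L={L})")
    return trace.samples[ap.onset_idx:ap.eof_idx] - ap.rmp


def sejp_segment(trace: Trace, sejp: SejpAnnotation, L: int) -> np.ndarray:
    """Length-L section of the sEJP rising phase, from its onset, minus RMP.

    Raises :class:`CandidateSkip` when the rising phase is shorter than L.
    """
    if sejp.onset_idx + L > sejp.peak_idx + 1:
        raise CandidateSkip(
            f"sEJP {sejp.id} rise shorter than foot length {L}")
    return trace.samples[sejp.onset_idx:sejp.onset_idx + L] - sejp.rmp


def split_halves(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split at floor(L/2) elements from the end; the first half gets the
    extra sample when L is odd."""
    n_first = len(v) - len(v) // 2
    return v[:n_first], v[n_first:]


def weighted_foot_distance(v_f: np.ndarray, v_s: np.ndarray, m: float,
                           v2f_min: float = 0.1
                           ) -> tuple[float, float, float]:
    """The differentially weighted distance (D, d1, d2) at multiplier m.

    Rejects the pair when any element of the second half of ``v_f`` is
    within ``v2f_min`` of zero — the relative-error term is undefined there
    and silent regularization would distort the selection.
    """
    v_f = np.asarray(v_f, dtype=float)
    v_s = np.asarray(v_s, dtype=float)
    if v_f.shape != v_s.shape:
        raise MatchError("foot and sEJP section lengths differ")
    v1f, v2f = split_halves(v_f)
    v1s, v2s = split_halves(v_s)
    if np.any(np.abs(v2f) < v2f_min):
        raise DegenerateInputError(
            "near-zero element in the second half of the AP foot")
    d1 = float(np.linalg.norm(v1f - m * v1s))
    d2 = float(np.sum(((v2f - m * v2s) / v2f) ** 2))
    return d1 + d2, d1, d2


def multiplier_grid(config: AnalysisConfig | None = None) -> np.ndarray:
    """The m grid: n points equally spaced on the open interval (1, 1.5),
    inset by half a grid step at both ends."""
    config = config or AnalysisConfig()
    step = (config.multiplier_hi - config.multiplier_lo) / config.n_multipliers
    return config.multiplier_lo + step / 2 + step * np.arange(
        config.n_multipliers)


def best_multiplier(v_f: np.ndarray, v_s: np.ndarray,
                    config: AnalysisConfig | None = None
                    ) -> tuple[float, float]:
    """Grid point of the multiplier grid minimizing D, and that minimum D.

    Ties go to the smaller m.  Evaluates the full grid (D is piecewise
    quadratic in m but not unimodal across the d1/d2 mix, and the grid is
    cheap).
    """
    config = config or AnalysisConfig()
    v_f = np.asarray(v_f, dtype=float)
    v_s = np.asarray(v_s, dtype=float)
    if v_f.shape != v_s.shape:
        raise MatchError("foot and sEJP section lengths differ")
    v1f, v2f = split_halves(v_f)
    v1s, v2s = split_halves(v_s)
    if np.any(np.abs(v2f) < config.v2f_min_mV):
        raise DegenerateInputError(
            "near-zero element in the second half of the AP foot")
    grid = multiplier_grid(config)
    m_col = grid[:, None]
    d1 = np.linalg.norm(v1f[None, :] - m_col * v1s[None, :], axis=1)
    d2 = np.sum(((v2f[None, :] - m_col * v2s[None, :]) / v2f[None, :]) ** 2,
                axis=1)
    D = d1 + d2
    k = int(np.argmin(D))  # argmin takes the first (smallest m) on ties
    return float(grid[k]), float(D[k])


def best_matching_sejp(trace: Trace, ap: APAnnotation,
                       sejps: list[SejpAnnotation],
                       config: AnalysisConfig | None = None) -> FootMatch:
    """The candidate sEJP (each at its own best multiplier) minimizing D.

    Candidates whose rising phase is shorter than the AP foot, or whose
    pairing is degenerate, are skipped.  Ties go to the first candidate in
    input order.
    """
    config = config or AnalysisConfig()
    v_f = foot_vector(trace, ap)
    best: FootMatch | None = None
    for sejp in sejps:
        try:
            v_s = sejp_segment(trace, sejp, len(v_f))
            m, D = best_multiplier(v_f, v_s, config)
        except (CandidateSkip, DegenerateInputError):
            continue
        _, d1, d2 = weighted_foot_distance(v_f, v_s, m, config.v2f_min_mV)
        if best is None or D < best.D:
            best = FootMatch(ap_id=ap.id, sejp_id=sejp.id, m=m, D=D,
                             d1=d1, d2=d2, L=len(v_f))
    if best is None:
        raise MatchError(f"no valid sEJP candidate for AP {ap.id}")
    return best


def sejp_waveform(trace: Trace, sejp: SejpAnnotation) -> np.ndarray:
    """Full baseline-subtracted sEJP time course [onset, end)."""
    return trace.samples[sejp.onset_idx:sejp.end_idx] - sejp.rmp


def extract_nap(trace: Trace, ap: APAnnotation, sejp: SejpAnnotation,
                m: float) -> np.ndarray:
    """Native-AP estimate: AP segment minus the amplified matched sEJP.

    The full sEJP time course (not just the foot section) is subtracted,
    onset-aligned and zero-extended past its end — the underlying junction
    potential persists through the afterdepolarization, and subtracting
    only the foot would leave the ADP unexplained.  The result spans the
    AP's [onset, EoS) window.
    """
    seg = trace.samples[ap.onset_idx:ap.eos_idx] - ap.rmp
    approx = np.zeros_like(seg)
    wave = m * sejp_waveform(trace, sejp)
    n = min(len(wave), len(seg))
    approx[:n] = wave[:n]
    return seg - approx


def accept_pair(residual_foot: np.ndarray, sigma_n: float,
                config: AnalysisConfig | None = None) -> bool:
    """Automatic replacement for visual match curation: accept the pair when
    the residual foot mean |value| is below ``foot_accept_sigma`` baseline
    noise SDs."""
    config = config or AnalysisConfig()
    return float(np.mean(np.abs(residual_foot))) < (
        config.foot_accept_sigma * sigma_n)


def build_sejp_nap_prototypes(
        cell_pairs: dict[str, list[tuple[np.ndarray, np.ndarray, int]]],
        min_pairs_per_cell: int = 4
        ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Two-level ensemble mean of accepted (sEJP, nAP) pairs.

    ``cell_pairs`` maps cell id to its accepted pair records ``(amplified
    sEJP approximation, nAP estimate, nAP peak index)``, all
    baseline-subtracted and starting at onset.  Cells with fewer than
    ``min_pairs_per_cell`` accepted pairs are excluded.  sEJP vectors are
    averaged onset-aligned; nAP vectors are averaged anchored at their
    peaks — the spike flanks are steep enough that onset-aligned averaging
    would smear them by the onset-detection jitter.  Per-cell means are
    averaged across cells and each prototype is normalized to unit peak.

    Returns ``(S, A, contributing_cell_ids)``.
    """
    s_protos, a_protos, a_peaks, used = [], [], [], []
    for cell_id, pairs in cell_pairs.items():
        if len(pairs) < min_pairs_per_cell:
            continue
        s_protos.append(ragged_mean([s for s, _, _ in pairs]))
        a_mean, a_anchor = anchored_mean([a for _, a, _ in pairs],
                                         [p for _, _, p in pairs])
        a_protos.append(a_mean)
        a_peaks.append(a_anchor)
        used.append(cell_id)
    if not used:
        raise MatchError(
            "no cell has enough accepted AP-sEJP pairs for a prototype")
    S = normalize_template(ragged_mean(s_protos), "peak_positive")
    a_univ, _ = anchored_mean(a_protos, a_peaks)
    A = normalize_template(a_univ, "peak_positive")
    return S, A, used
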