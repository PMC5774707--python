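"""RMSE similarity, threshold estimation and replication efficiency.

The similarity between a recorded AP and its synthesized replica (or
between two recorded APs) is the root mean square error over the first
signal's active window (onset to end of signal), after peak alignment by an
integer sample shift:

    D^2 = (1/n) * sum_k (a[k] - b[k + r])^2 ,   r = peak_b - peak_a

Thresholds come from a training pool: for each AP the 10 smallest RMSE
values against the rest of the pool identify its matching APs (same shape
class, differing only by noise), and the specific threshold tau_i is the
largest of those 10.  The universal threshold T is the mean of all specific
thresholds and serves for APs outside the pool.  A synthesis is a good fit
when its RMSE falls below the applicable threshold; the replication
efficiency of a set is the percentage of good fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from apdecomp.config import AnalysisConfig
from apdecomp.core import (
    AlignmentError,
    Decomposition,
    DegenerateInputError,
    RmseThresholds,
)


@dataclass
class PoolAP:
    """One AP of a threshold-estimation pool.

    ``v`` is the baseline-subtracted active window [onset, EoS); ``peak``
    the peak index within it.
    """

    ap_id: str
    v: np.ndarray
    peak: int


def rmse(a: np.ndarray, b: np.ndarray, peak_a: int, peak_b: int,
         strict: bool = False) -> float:
    """Peak-aligned RMSE over the active window of ``a``.

    ``b`` is shifted by ``r = peak_b - peak_a`` so the peaks coincide; the
    mean runs over all n samples of ``a``'s window.  Samples of ``b``
    outside its own window are taken as baseline (zero) unless ``strict``,
    in which case any out-of-range index raises.  An empty overlap always
    raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    r = int(peak_b) - int(peak_a)
    lo = max(0, -r)
    hi = min(a.size, b.size - r)
    if hi <= lo:
        raise AlignmentError("empty overlap after peak alignment")
    if strict and (lo > 0 or hi < a.size):
        raise AlignmentError("active window out of bounds after peak shift")
    b_full = np.zeros(a.size)
    b_full[lo:hi] = b[lo + r:hi + r]
    return float(np.sqrt(np.mean((a - b_full) ** 2)))


def matching_rmses(i: int, pool: list[PoolAP], n_matching: int
                   ) -> np.ndarray:
    """The ``n_matching`` smallest RMSE values of pool AP i vs the rest."""
    if len(pool) < n_matching + 1:
        raise DegenerateInputError(
            f"threshold pool needs >= {n_matching + 1} APs, got {len(pool)}")
    me = pool[i]
    values = [rmse(me.v, other.v, me.peak, other.peak)
              for j, other in enumerate(pool) if j != i]
    return np.sort(np.asarray(values))[:n_matching]


def specific_threshold(i: int, pool: list[PoolAP],
                       config: AnalysisConfig | None = None) -> float:
    """tau_i: the maximum RMSE among the i-th AP's matching APs."""
    config = config or AnalysisConfig()
    return float(matching_rmses(i, pool, config.n_matching)[-1])


def universal_threshold(specifics: dict[str, float] | list[float]) -> float:
    """T: the mean of all specific thresholds in the pool."""
    values = list(specifics.values()) if isinstance(specifics, dict) \
        else list(specifics)
    if not values:
        raise DegenerateInputError("no specific thresholds")
    return float(np.mean(values))


def estimate_thresholds(pool: list[PoolAP],
                        config: AnalysisConfig | None = None
                        ) -> tuple[RmseThresholds, list[str]]:
    """Specific thresholds for every pool AP, and the universal T.

    APs whose matching set has an anomalously wide RMSE spread (above
    ``purity_factor`` times the median spread) are dropped from threshold
    estimation — the automatic counterpart of visually discarding APs whose
    nearest neighbours mix shape classes.  Returns the thresholds and the
    ids of the dropped APs (they fall back to T).
    """
    config = config or AnalysisConfig()
    nearest = [matching_rmses(i, pool, config.n_matching)
               for i in range(len(pool))]
    spreads = np.array([m[-1] - m[0] for m in nearest])
    median_spread = float(np.median(spreads))
    dropped: list[str] = []
    specific: dict[str, float] = {}
    for ap, m, spread in zip(pool, nearest, spreads):
        if median_spread > 0 and spread > config.purity_factor * median_spread:
            dropped.append(ap.ap_id)
            continue
        specific[ap.ap_id] = float(m[-1])
    if not specific:
        raise DegenerateInputError("every pool AP failed the purity check")
    return RmseThresholds(specific=specific,
                          universal_T=universal_threshold(specific)), dropped


def replication_efficiency(decomps: list[Decomposition],
                           thresholds: RmseThresholds | float) -> float:
    """Percentage of fitted APs whose RMSE is below the applicable threshold.

    With an :class:`RmseThresholds` object each AP uses its specific
    threshold when it belongs to the pool and the universal T otherwise;
    with a plain float every AP uses that value.
    """
    if not decomps:
        raise DegenerateInputError("no decompositions to evaluate")
    good = 0
    for dec in decomps:
        thr = thresholds.threshold_for(dec.ap_id) \
            if isinstance(thresholds, RmseThresholds) else float(thresholds)
        good += dec.rmse < thr
    return 100.0 * good / len(decomps)
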