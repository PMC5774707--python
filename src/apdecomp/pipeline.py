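"""End-to-end orchestration: detect -> templates -> fit -> evaluate.

The stages mirror the analysis workflow: every recording is annotated;
cells meeting the training criteria (duration, Type A AP count, large-sEJP
count) form the training set and the rest the test set; sEJP/nAP prototypes
come from foot matching within training cells and H1/H2 prototypes from
G1-G0 subtraction across them; RMSE thresholds are estimated on the
training AP pool; finally every Type A AP in both sets is synthesized from
the templates and scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from apdecomp import ahp_extraction, foot_matching
from apdecomp.config import AnalysisConfig
from apdecomp.core import (
    APAnnotation,
    APGroup,
    APKind,
    Decomposition,
    DegenerateInputError,
    FitError,
    MatchError,
    RmseThresholds,
    SejpAnnotation,
    TemplateSet,
    Trace,
)
from apdecomp.evaluation import (
    PoolAP,
    estimate_thresholds,
    replication_efficiency,
)
from apdecomp.event_detection import detect_events, select_training_cells
from apdecomp.synthesis import component_matrix, fit_decomposition, synthesize

logger = logging.getLogger("apdecomp")

#: integer shifts of the template anchor tried when fitting a detected AP
#: (detected peak indices jitter by a sample or two under noise)
FIT_SHIFT_RANGE = 2


@dataclass
class AnnotatedCell:
    """One recording with everything detected on it."""

    id: str
    trace: Trace
    aps: list[APAnnotation] = field(default_factory=list)
    sejps: list[SejpAnnotation] = field(default_factory=list)
    rmp: float = float("nan")
    noise_sd: float = float("nan")

    def type_a(self, group: APGroup | None = None,
               include_truncated: bool = False) -> list[APAnnotation]:
        out = [ap for ap in self.aps if ap.kind is APKind.TYPE_A
               and (include_truncated or not ap.truncated)]
        if group is not None:
            out = [ap for ap in out if ap.group is group]
        return out


def annotate_cell(cell_id: str, trace: Trace,
                  config: AnalysisConfig | None = None) -> AnnotatedCell:
    """Detect and landmark all events of one recording."""
    config = config or AnalysisConfig()
    result = detect_events(trace, config, id_prefix=cell_id)
    return AnnotatedCell(id=cell_id, trace=trace, aps=result.aps,
                         sejps=result.sejps, rmp=result.rmp,
                         noise_sd=result.noise_sd)


# ---------------------------------------------------------------------------
# Template extraction
# ---------------------------------------------------------------------------

def match_cell_feet(cell: AnnotatedCell, config: AnalysisConfig
                    ) -> tuple[list[foot_matching.FootMatch],
                               list[tuple[np.ndarray, np.ndarray, int]]]:
    """Foot-match every G0 AP of a cell against the cell's own sEJPs.

    Returns the per-pair match records and, for accepted pairs, the
    (amplified sEJP approximation, nAP estimate, nAP peak index) records
    used for prototype averaging.
    """
    matches: list[foot_matching.FootMatch] = []
    pairs: list[tuple[np.ndarray, np.ndarray, int]] = []
    sejp_by_id = {s.id: s for s in cell.sejps}
    for ap in cell.type_a(APGroup.G0):
        try:
            match = foot_matching.best_matching_sejp(
                cell.trace, ap, cell.sejps, config)
        except MatchError:
            continue
        sejp = sejp_by_id[match.sejp_id]
        nap = foot_matching.extract_nap(cell.trace, ap, sejp, match.m)
        foot_len = ap.eof_idx - ap.onset_idx
        match.accepted = foot_matching.accept_pair(
            nap[:foot_len], cell.noise_sd, config)
        matches.append(match)
        if match.accepted:
            wave = match.m * foot_matching.sejp_waveform(cell.trace, sejp)
            pairs.append((wave, nap, ap.peak_idx - ap.onset_idx))
    return matches, pairs


def extract_templates(cells: list[AnnotatedCell],
                      config: AnalysisConfig | None = None
                      ) -> tuple[TemplateSet, dict]:
    """Build the four component templates from a set of training cells.

    Returns the template set and a report dict with per-stage counts
    (accepted pairs, contributing cells, residual counts, E_th).
    """
    config = config or AnalysisConfig()
    if not cells:
        raise MatchError("no training cells")
    dt = cells[0].trace.dt

    cell_pairs: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    all_matches: list[foot_matching.FootMatch] = []
    for cell in cells:
        matches, pairs = match_cell_feet(cell, config)
        all_matches.extend(matches)
        cell_pairs[cell.id] = pairs
    S, A, used_cells = foot_matching.build_sejp_nap_prototypes(
        cell_pairs, config.min_pairs_per_cell)
    logger.info("sEJP/nAP prototypes from %d cells, %d accepted pairs",
                len(used_cells), sum(len(cell_pairs[c]) for c in used_cells))

    # G1-G0 matching runs across all cells
    tail_pad = int(round(config.eos_quiet_ms / dt))
    g0_pool = [ahp_extraction.NormalizedAP.from_annotation(
        c.trace, ap, c.noise_sd, tail_pad) for c in cells
        for ap in c.type_a(APGroup.G0)]
    g1_aps = [ahp_extraction.NormalizedAP.from_annotation(
        c.trace, ap, c.noise_sd, tail_pad) for c in cells
        for ap in c.type_a(APGroup.G1)]
    residuals: list[ahp_extraction.AhpResidual] = []
    for g1 in g1_aps:
        try:
            g0, D, shift = ahp_extraction.best_matching_g0(g1, g0_pool)
            residuals.append(ahp_extraction.extract_residual(
                g1, g0, shift, D, config))
        except MatchError:
            continue
    accepted = [r for r in residuals if r.accepted]
    e_th = float("nan")
    H1 = H2 = None
    if len(accepted) >= 2:
        try:
            e_th = ahp_extraction.classify_pool(residuals)
            H1, H2 = ahp_extraction.build_ahp_prototypes(residuals)
        except (MatchError, DegenerateInputError):
            pass
    if H1 is None or H2 is None:
        logger.warning("slow-AHP category empty: model degrades to %d "
                       "components", 2 + (H1 is not None) + (H2 is not None))

    templates = TemplateSet(S=S, A=A, H1=H1, H2=H2, dt=dt, h_offset=0)
    report = {
        "n_training_cells": len(cells),
        "n_prototype_cells": len(used_cells),
        "n_foot_pairs": len(all_matches),
        "n_foot_pairs_accepted": sum(m.accepted for m in all_matches),
        "n_g0": len(g0_pool),
        "n_g1": len(g1_aps),
        "n_residuals_accepted": len(accepted),
        "n_sahp": sum(r.category == "sahp" for r in residuals),
        "n_vsahp": sum(r.category == "vsahp" for r in residuals),
        "energy_threshold": e_th,
    }
    return templates, report


# ---------------------------------------------------------------------------
# Fitting detected APs
# ---------------------------------------------------------------------------

def fit_ap(trace: Trace, ap: APAnnotation, templates: TemplateSet,
           config: AnalysisConfig | None = None,
           threshold: float = float("nan")) -> Decomposition:
    """Fit the four-component model to one detected Type A AP.

    The fitting window is anchored so the nAP template's peak row lands on
    the AP's detected peak; the anchor is refined over a few integer shifts
    (detected peaks jitter under noise).  The sEJP delay is scanned over
    [onset, peak] of the AP.  The reported RMSE is computed over the AP's
    active window [onset, EoS) per the similarity definition.
    """
    config = config or AnalysisConfig()
    pa = templates.a_peak_idx
    # peak alignment must never lose to the onset bound: when the AP's
    # onset-to-peak span exceeds the template's pre-peak span, extend the
    # template front with baseline zeros (the nAP foot is negligible there)
    span = ap.peak_idx - ap.onset_idx
    pad = max(0, span - pa + FIT_SHIFT_RANGE)
    if pad:
        templates = TemplateSet(
            S=templates.S, A=np.concatenate([np.zeros(pad), templates.A]),
            H1=templates.H1, H2=templates.H2, dt=templates.dt,
            h_offset=templates.h_offset)
        pa += pad
    best: Decomposition | None = None
    for delta in range(-FIT_SHIFT_RANGE, FIT_SHIFT_RANGE + 1):
        y0 = min(max(ap.peak_idx - pa + delta, 0), ap.onset_idx)
        if ap.eos_idx - y0 < pa + 2:
            continue
        Y = trace.samples[y0:ap.eos_idx] - ap.rmp
        n1 = ap.onset_idx - y0
        n2 = ap.peak_idx - y0
        if n1 < 0 or n1 > n2 or n2 >= Y.size:
            continue
        try:
            dec = fit_decomposition(
                Y, templates, n1, n2, ap_id=ap.id,
                nonnegative_ahp=config.nonnegative_ahp, threshold=threshold)
        except FitError:
            continue
        # score on the active window [onset, EoS)
        C = component_matrix(templates, dec.nd, Y.size)
        resid = Y - synthesize(C, dec.coefficients)
        dec.rmse = float(np.sqrt(np.mean(resid[n1:] ** 2)))
        if best is None or dec.rmse < best.rmse:
            best = dec
    if best is None:
        raise FitError(f"could not fit AP {ap.id}")
    return best


def fit_cells(cells: list[AnnotatedCell], templates: TemplateSet,
              config: AnalysisConfig | None = None,
              thresholds: RmseThresholds | None = None
              ) -> list[Decomposition]:
    """Fit every (non-truncated) Type A AP of the given cells."""
    config = config or AnalysisConfig()
    out = []
    for cell in cells:
        for ap in cell.type_a():
            thr = thresholds.threshold_for(ap.id) if thresholds else float("nan")
            try:
                out.append(fit_ap(cell.trace, ap, templates, config, thr))
            except FitError:
                logger.warning("fit failed for %s", ap.id)
    return out


# ---------------------------------------------------------------------------
# Threshold pool and full pipeline
# ---------------------------------------------------------------------------

def threshold_pool(cells: list[AnnotatedCell]) -> list[PoolAP]:
    """The RMSE-threshold pool: every AP (Type A and Type B) of the cells."""
    pool = []
    for cell in cells:
        for ap in cell.aps:
            if ap.truncated:
                continue
            v = cell.trace.samples[ap.onset_idx:ap.eos_idx] - ap.rmp
            pool.append(PoolAP(ap_id=ap.id, v=v,
                               peak=ap.peak_idx - ap.onset_idx))
    return pool


def run_pipeline(traces: dict[str, Trace],
                 config: AnalysisConfig | None = None,
                 workdir: str | Path | None = None) -> dict:
    """Execute detect -> select -> templates -> fit -> evaluate.

    ``traces`` maps cell ids to recordings.  Returns a report dict with
    per-stage counts, the threshold distribution and the replication
    efficiencies; when ``workdir`` is given, templates and the report are
    also written there.  Stage failures raise with the stage name.
    """
    config = config or AnalysisConfig()
    report: dict = {"stages": {}}

    cells = [annotate_cell(cid, tr, config) for cid, tr in traces.items()]
    report["stages"]["detect"] = {
        "n_cells": len(cells),
        "n_aps": sum(len(c.aps) for c in cells),
        "n_type_a": sum(len(c.type_a(include_truncated=True)) for c in cells),
        "n_sejps": sum(len(c.sejps) for c in cells),
    }

    training = select_training_cells(cells, config)
    test = [c for c in cells if c not in training]
    if not training:
        raise MatchError("stage select_training_cells: no cell qualifies")
    report["stages"]["select"] = {
        "n_training_cells": len(training),
        "n_test_cells": len(test),
    }

    try:
        templates, tmpl_report = extract_templates(training, config)
    except MatchError as exc:
        raise MatchError(f"stage templates: {exc}") from exc
    report["stages"]["templates"] = tmpl_report

    pool = threshold_pool(training)
    thresholds, dropped = estimate_thresholds(pool, config)
    taus = np.array(list(thresholds.specific.values()))
    report["stages"]["thresholds"] = {
        "pool_size": len(pool),
        "n_dropped_purity": len(dropped),
        "tau_min_mV": float(taus.min()),
        "tau_max_mV": float(taus.max()),
        "tau_mean_mV": float(taus.mean()),
        "tau_sd_mV": float(taus.std(ddof=1)) if taus.size > 1 else 0.0,
        "universal_T_mV": thresholds.universal_T,
    }

    fits_train = fit_cells(training, templates, config, thresholds)
    report["efficiency_training_pct"] = replication_efficiency(
        fits_train, thresholds) if fits_train else float("nan")
    fits_test = fit_cells(test, templates, config) if test else []
    for dec in fits_test:
        dec.threshold_used = thresholds.universal_T
    report["efficiency_test_pct"] = replication_efficiency(
        fits_test, thresholds.universal_T) if fits_test else float("nan")
    all_fits = fits_train + fits_test
    report["efficiency_overall_pct"] = replication_efficiency(
        all_fits, thresholds) if all_fits else float("nan")
    report["n_fitted"] = len(all_fits)
    report["median_fit_rmse_mV"] = float(np.median(
        [d.rmse for d in all_fits])) if all_fits else float("nan")

    if workdir is not None:
        workdir = Path(workdir)
        templates.save(workdir / "templates")
        import json
        with open(workdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return report
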