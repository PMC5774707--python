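# apdecomp

Four-component decomposition and synthesis of spontaneous action potentials
(sAPs) recorded intracellularly from detrusor smooth muscle cells (DSMCs)
of the mouse urinary bladder.

## The problem

DSMCs fire spontaneous action potentials with strikingly variable shapes:
convex feet, afterdepolarizations, and slow afterhyperpolarizations of two
distinct time courses.  Under the superposition hypothesis, every
neurogenic ("Type A") sAP is a linear combination of four stereotyped
components:

* **S** — the spontaneous excitatory junction potential (sEJP): the passive
  depolarization from a neurotransmitter vesicle release.  A suprathreshold
  sEJP triggers the spike and keeps riding under it, producing the convex
  foot and the ADP;
* **A** — the native AP (nAP): the response of the voltage-gated machinery
  alone, never observable in isolation;
* **H1** — the slow AHP (sAHP), time course ≥ 100 ms, typically ~200 ms;
* **H2** — the very slow AHP (vsAHP), deeper and longer, ~300 ms.

The model synthesizes an AP `Y` (baseline-subtracted, sampled at interval
`dt`) as

```
Y(n) ≈ a·S(n − n_d) + b·A(n) + c·H1(n) + d·H2(n)
```

where `a, b, c, d` are amplification factors, `n_d` is the sEJP delay in
samples, and H1/H2 start at the peak of A.  For a given delay the
amplifications solve the least-squares problem `X = argmin ‖C·X − Y‖` over
the component matrix `C`; the delay itself is found by exhaustive scan over
the integers in `[n₁, n₂]` (the AP's onset and peak).  A fit is a *good
replication* when the peak-aligned RMSE over the AP's active window
(onset → end of signal) falls below a threshold estimated from a training
pool: each pool AP's specific threshold τᵢ is the largest RMSE among its 10
nearest neighbours, and the universal threshold T is the mean of the τᵢ.

The package implements the full workflow that produces the templates from
raw recordings:

1. **Event detection** — onset (hard threshold RMP + 1 mV), end of foot
   (valley between the double peaks of the rising-phase slope profile),
   peak, end of first repolarization, end of signal; Type A vs Type B
   (ramp-foot, pacemaking) classification; G0 (no slow AHP) vs G1 split.
2. **sEJP/nAP isolation** — each G0 AP's foot is matched against the
   cell's own sEJPs with a differentially weighted distance
   (`D = ‖V1f − m·V1s‖ + Σ((V2f − m·V2s)/V2f)²`, multiplier grid on
   (1, 1.5)); subtracting the amplified best match, onsets aligned, yields
   the nAP estimate; two-level ensemble means give the S and A prototypes.
3. **sAHP/vsAHP isolation** — each G1 AP is matched against the G0 pool
   (normalized, peak-aligned, Euclidean distance over onset → EoFR);
   the subtraction residual's tail is the AHP estimate, and the midpoint
   energy threshold `E_th = (E_max + E_min)/2` splits residuals into the
   sAHP and vsAHP populations that form H1 and H2.

Because no recordings are distributed, the package ships a synthetic-data
generator (`apdecomp.synthetic`) that emulates the tissue's statistics
(sEJP amplitude 9.2 ± 3.6 mV, AP amplitude 52.5 ± 7.6 mV, half-width
~9.7 ms, two slow-AHP populations, RMP ≈ −43 mV, baseline noise up to
~0.9 mV) through the same forward model the analysis inverts, with full
ground-truth annotations.

## Worked example

```python
from apdecomp.config import AnalysisConfig
from apdecomp.pipeline import annotate_cell, extract_templates, fit_ap
from apdecomp.synthetic import GeneratorConfig, gen_cohort

cfg = GeneratorConfig(seed=42, duration_min=6.0, ap_rate=2.0)
cells = gen_cohort(4, cfg)
annotated = [annotate_cell(c.id, c.trace, AnalysisConfig()) for c in cells]
templates, report = extract_templates(annotated, AnalysisConfig())

ann = annotated[0]
for ap in ann.type_a()[:3]:
    dec = fit_ap(ann.trace, ap, templates, AnalysisConfig(), threshold=2.3)
    print(f"{ap.id} ({ap.group.value}): a={dec.a:5.1f}  b={dec.b:5.1f}  "
          f"c={dec.c:5.2f}  d={dec.d:5.2f}  nd={dec.nd * 0.5:4.1f} ms  "
          f"RMSE={dec.rmse:.2f} mV  good_fit={dec.good_fit}")
```

prints

```
cell0-ap0 (G1): a= 18.1  b= 21.3  c=-0.47  d= 4.13  nd= 1.5 ms  RMSE=1.18 mV  good_fit=True
cell0-ap1 (G0): a= 14.5  b= 27.2  c= 0.96  d= 0.92  nd= 3.5 ms  RMSE=1.07 mV  good_fit=True
cell0-ap2 (G0): a= 13.5  b= 43.7  c=-1.50  d=-3.78  nd= 1.0 ms  RMSE=1.25 mV  good_fit=True
```

`a` and `b` are the sEJP and nAP amplitudes in mV (S and A are unit-peak),
`c` and `d` the sAHP and vsAHP trough depths in mV (H1 and H2 are
unit-trough), `nd` the sEJP delay, and the RMSE is measured over the AP's
active window against the synthesized composite.  The fit is unconstrained,
as in the defining equations, so small negative `c`/`d` values can appear
on G0 APs where the slow-AHP columns absorb residual tail mismatch; set
`nonnegative_ahp: true` in the analysis config to forbid that.

### Command line

```
apdecomp simulate --cells 4 --seed 7 --out-dir cohort/
apdecomp detect   --trace cohort/cell0.csv --out events.json
apdecomp templates --trace cohort/cell0.csv --trace cohort/cell1.csv --out-dir templates/
apdecomp fit      --trace cohort/cell0.csv --templates templates/ --out decomps.csv
apdecomp evaluate --decomps decomps.csv --threshold 2.3 --out report.json
apdecomp pipeline --trace cohort/cell0.csv --trace cohort/cell1.csv --workdir run/
```

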