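# placentaq

Quantification pipeline for studies of placental function and
senescence: landmark statistics of dynamic contrast-enhanced MRI
(DCE-MRI) signal-intensity curves, histological positivity counting and
rubric scoring, staining/activity image quantification, expression
fold-change filtering, and the accompanying group statistics — together
with synthetic-data generators that make every stage testable with known
ground truth, no imaging data required.

It is aimed at researchers quantifying placental perfusion phenotypes in
mouse genetic models (e.g. knockouts of the senescence regulators p21,
p53, p16/Cdkn2a) and trophoblast senescence markers in human placental
tissue.

## The statistics at the core

After intravenous injection of a macromolecular contrast agent
(albumin-bound Gd), the mean signal intensity SI(t) of a placental
region of interest is biphasic: enhancement as the labyrinth
syncytiotrophoblasts internalize the agent, a decline, then a late
recovery as the agent is recycled into the maternal circulation. On a
curve sampled at scans k = 1…N (2 min 43 s per scan, 25 scans ≈ 68 min),
the package computes

* **initial enhancement** E = SI(first local maximum) / SI(initial point),
* **recovery** R = SI(second local maximum) / SI(local minimum between
  the two maxima),
* **ROE** (rate of enhancement, min⁻¹):
  ROE_k = ΔSI_k / Δt_k / C_vc, the SI rate scaled to the vena cava
  plateau signal C_vc.

Landmarks are found on a moving-average-smoothed copy of the curve and
snapped back to the raw samples; ratios are always computed from
unsmoothed values. Attenuated senescence programs blunt the recovery
limb, so R separates genotypes.

Histology support includes the percent of syncytiotrophoblasts
containing ≥ 1 DAB-positive nucleus per counting field (aggregated as
mean ± SEM over ≥ 12 fields), a 9-level semi-quantitative Ki67 rubric
(0–4 in 0.5 steps keyed to positive-fraction bins), the trophoblast
fusion index (nuclei-based by default, cell-based by flag), and
Otsu-thresholded area-fraction / mean-intensity quantification of
SA-β-gal and in situ zymography images. Expression analysis applies the
1.8-fold-change filter between late (day 3–5) and early (day 1.5–2)
trophoblast cultures on linear-scale group means. Group comparisons use
the unpaired Student's t-test (pooled variance, one- or two-tailed) and
one-way ANOVA with Tukey's HSD.

## Worked example

Simulate a five-genotype cohort (8 placentas per genotype, seed 7) and
compute per-group landmark statistics:

```python
from placentaq.synthetic import default_presets, simulate_cohort
from placentaq.dce import analyze_cohort

cohort = simulate_cohort(default_presets(), n_per_group=8, seed=7)
result = analyze_cohort([c.curve for c in cohort])
print(result.summary.round(3).to_string(index=False))
```

```
         group  n  mean_initial_enhancement  sem_initial_enhancement  mean_recovery  sem_recovery
     Cdkn1a_KO  8                     1.347                    0.019          1.294         0.017
     Cdkn2a_KO  8                     1.303                    0.006          1.172         0.011
Cdkn2a_p53_DKO  8                     1.256                    0.020          1.105         0.008
            WT  8                     1.403                    0.015          1.311         0.009
        p53_KO  8                     1.343                    0.017          1.196         0.009
```

Wild-type placentas recover most strongly (R ≈ 1.31) while the
Cdkn2a;p53 double knockout, generated with the smallest planted recovery
amplitude, recovers least (R ≈ 1.11) — the ordering the recovery
statistic is designed to resolve. The same workflow is available from
the shell:

```sh
placentaq simulate --n-per-group 8 --seed 7 --out-dir demo
placentaq dynamics demo/curves.csv --out-dir demo
placentaq ki67-score 0.30        # -> 2
placentaq run --seed 7 --out-dir demo_full   # full pipeline + manifest
```

Subcommands: `simulate`, `dynamics`, `syncytia`, `ki67-score`, `fusion`,
`intensity`, `compare`, `fc-filter`, `run`. Exit codes: 0 ok, 2 config
error, 3 data error, 4 pipeline error.

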