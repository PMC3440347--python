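# cytoquant

Absolute surface-receptor quantification from flow cytometry, with a
forward simulator of cytometry events for end-to-end validation.

## What this is for

Systems-biology models of VEGF signaling need absolute receptor
numbers per endothelial cell, but cytometers report fluorescence in
arbitrary units. Quantitative flow cytometry closes that gap: cells
are labeled with PE-conjugated antibodies under saturating conditions
(≈1 PE per antibody, 1 antibody per receptor), and beads carrying
known PE loads (515 / 5,956 / 26,653 / 69,045 molecules/bead) anchor
a calibration

    y = m·x + b,    x = log10(PE molecules/bead),  y = log10(FL2 geometric mean)

whose inverse `PE = 10^((log10 FL2 − b)/m)` converts every cell's FL2
signal into a receptor count. `cytoquant` implements the full
analysis — bead calibration, scatter/FL1 gating, autofluorescence
background subtraction, per-cell conversion, ensemble (mean ± SEM
across replicates) and cell-by-cell statistics (median, CV, skewness,
excess kurtosis, 500-receptor histograms, single-pass 3-SD outlier
exclusion), plus ANOVA/Tukey and Kolmogorov–Smirnov comparisons — and
a forward event simulator with per-event ground truth, so the whole
inverse pipeline is testable without an instrument. Packaged
scenarios emulate the published mouse skeletal-muscle endothelial
conditions (C57BL/6 and BALB/c, gastrocnemius and tibialis anterior,
VEGFR1/VEGFR2) and the in vitro human EC and 3T3 fibroblast
comparators.

It is aimed at quantitative-cytometry users and modelers who want a
reproducible, scriptable version of this analysis, or a sandbox for
testing how gating rules, background handling and outlier exclusion
shape receptor-census statistics.

## Worked example

```python
import cytoquant as cq

cfg = cq.load_scenario("c57bl6_gastrocnemius_vegfr1", n_cells=10000, seed=20120912)
res = cq.run_scenario(cfg)          # beads -> gate -> calibrate -> quantify
print(cq.build_report([res]).to_string(index=False))
```

prints

```
                  condition  n   mean  sem  n_cells  median  cv_percent  skewness  kurtosis
c57bl6_gastrocnemius_vegfr1 11 2000.0  0.0    89194    1793         109       1.5       1.4
```

Eleven simulated replicates of 10,000 events each were calibrated
(this session's fit: `m = 0.9998`, `b = 0.3017`, `r² = 1.0000` —
slope 1 and intercept log10(gain) for a linear detector at gain 2
a.u./PE), gated to singlet CD34⁺ cells, converted to receptors/cell
and background-subtracted (≈288 PE-equivalents). The recovered
ensemble mean of 2,000 VEGFR1/cell, pooled median of ~1,800 and CV of
~110% match the condition this scenario emulates; the SEM is tiny
because simulated replicates differ only by sampling noise, not
animal-to-animal variation. Downstream arithmetic gives whole-cell
budgets, e.g. with 80% of VEGFR1 intracellular:

```python
est = cq.compartment_estimate(surface=2800, surface_fraction=0.2)
cq.round_reported(est.intracellular, 1000)   # 11000.0 receptors/cell
```

The same stages are available as shell verbs (`cytoquant simulate |
gate | calibrate | quantify | cellstats | compare | all | report`),
each exchanging plain-text artifacts.

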