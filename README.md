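# lactoshelf

Most expressed human breastmilk in the home is stored in a −20 °C
freezer, a temperature at which the milk-fat-globule membrane (MFGM)
degrades, endogenous lipases gain access to triglycerides, and the milk
turns rancid: free fatty acids and glycerol accumulate, antioxidant
capacity collapses, and palatability drops. `lactoshelf` is a tested,
fully synthetic pipeline for studying this degradation process and the
screening workflow used to find food-derived preservation additives —
every input it consumes is generated by an explicit mechanistic model
with ground truth, so the whole analysis chain can be exercised and
validated without any milk or instrument data.

It is aimed at assay developers and computational scientists who need a
reproducible benchmark for high-throughput-screen (HTS) hit triage,
plate-reader data handling, storage-kinetics metrics, and survey
tabulation logic.

## The model

Glycerol release from a finite hydrolyzable triglyceride pool follows
saturating first-order kinetics

```
G(t) = g_max · (1 − exp(−ρ·k·t)),        FFA(t) = 3·G(t)
```

with donor-specific lipolysis rate `k` (month⁻¹, lognormal across
donors) and a dimensionless treatment rate multiplier `ρ` (ρ = 1
untreated; membrane-stabilising compounds such as pectin have ρ < 1).
Lipase substrate signal, lysozyme, protease and antioxidant capacity
each decay exponentially at their own rates; measurement noise is
mean-one multiplicative lognormal per well. On top of the simulator sit:

- **plate_io** — SBS 96-well plate matrix CSV reader/writer, layout
  binding, and vehicle-control validation (1% v/v DMSO and water on
  every plate);
- **screen_triage** — per-plate Z-scores against pooled vehicle wells,
  the ≤ 400 RFU primary-hit threshold, same-criterion retest, 2-fold
  dilution-series summarisation, and the > 75% lysozyme/protease
  retention gate;
- **storage_kinetics** — dilution arithmetic, reference normalisation,
  endpoint percent-reduction metrics, and nonlinear least-squares fits
  of the first-order law (`FirstOrderKinetics(t, y).fit()`);
- **stats_suite** — one-way/two-way/repeated-measures ANOVA, Tukey HSD,
  Bartlett and Brown–Forsythe tests, the |skew| ≤ 1 / |excess kurtosis|
  ≤ 2 normality gate, and Pearson chi-square;
- **survey_tab** — eligibility screening and branch-aware ("of whom")
  tabulation of a storage-practices survey.

## Worked example

```python
from lactoshelf.config import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(seed=1), "runs/r1")
print(manifest["stage_counts"])
```

```
{'screened': 2750, 'primary': 21, 'retested': 21, 'validated': 21}
```

A 2750-compound screen across 30 plates with 21 planted actives
(ρ ≤ 0.2) recovers all 21 through the primary threshold, retest and
retention gates. The storage summary (`runs/r1/storage_summary.json`)
reports a cohort mean glycerol reduction of **59.8%** at month 6 for the
combined pectin + ascorbic-acid treatment (ρ = 0.225) across 14
simulated donors, with lysozyme retention **80.1 ± 3.5%** — the treated
arm preserves roughly 60% of the glycerol production that otherwise
occurs in six months of freezer storage while leaving protective
enzymes above the 75% retention demand.

The same run is available from the shell:

```bash
lactoshelf all --config cfg.yaml --seed 1 --out runs/r1/
```

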