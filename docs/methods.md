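# Methods

## Degradation model

The simulator treats frozen-storage rancidification as lipase-driven
hydrolysis of a finite triglyceride-derived glycerol pool. For a donor
with lipolysis rate constant `k` (month⁻¹) and a treatment with rate
multiplier `ρ`:

- **Glycerol** `G(t) = g_max·(1 − e^{−ρkt})` (µM). The saturating form
  reconciles two observations about frozen milk: the lipolysis *rate*
  declines over storage while the *product* keeps accumulating. A
  linear-accumulation model cannot do both.
- **Free fatty acids** `FFA(t) = 3·G(t)`: complete hydrolysis of one
  triglyceride yields three FFAs and one glycerol. FFA is modelled by
  stoichiometry only; no independent FFA assay chemistry is simulated.
- **Lipase substrate signal** `bg + amp·ρ·e^{−0.5t}` (RFU). The decay
  reflects loss of enzymatic activity in the freezer; the multiplicative
  ρ encodes the mechanistic picture that membrane-stabilising compounds
  restrict lipase access to its substrate rather than subtracting a
  fixed amount of signal.
- **Antioxidant capacity** (A570 units) = endogenous ascorbate-equivalent
  pool decaying at 2.3 month⁻¹ (undetectable by ~2 months of freezer
  storage) + a persistent non-ascorbate pool + any supplemented
  ascorbate (100 µg/mL arm) decaying at 0.1 month⁻¹.
- **Lysozyme / protease** first-order decay at 0.04 month⁻¹, identical
  in treated and untreated arms unless a compound carries an explicit
  enzyme-suppression multiplier.

Treated and untreated trajectories of a donor share the same latent
donor draw (paired design); donor effects therefore cancel only through
the saturating nonlinearity, as in a real paired storage study.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `k_base` | 0.30 | month⁻¹ | calibrated so ~83% of the pool hydrolyses in 6 months untreated |
| donor multiplier | lognormal(0, 0.3) | — | wide inter-individual baseline variability |
| `g_max` | 500 | µM | plausible hydrolyzable pool for diluted milk in the luminescent glycerol assay's range |
| `ρ` (pectin+ascorbate) | 0.225 | — | calibrated: yields ~60% less month-6 glycerol than untreated |
| active cutoff | ρ ≤ 0.20 | — | ground-truth activity boundary for screens |
| inactive ρ | Normal(1.0, 0.10) | — | inert compounds scatter around no effect |
| lipase signal | 100 + 1400·ρ·e^{−0.5t} | RFU | vehicle wells read ~1.4–1.5k RFU at the 1-week screen read; actives fall under the 400 RFU threshold with a ≥7σ margin at 5% CV |
| enzyme decay | 0.04 | month⁻¹ | leaves ~79% of lysozyme/protease signal at month 6, above the 75% retention demand |
| measurement CV | 0.05 | fraction | typical plate-reader repeatability |

Noise is mean-one multiplicative lognormal per well/measurement. An
optional linear row+column plate gradient (≤ 20% drift) is off by
default. One master seed drives everything; per-donor, per-plate and
per-assay streams are derived by stable hashing of identifiers, so any
subset regenerates identically in isolation.

## Screen construction

2750 compounds are laid across 30 × 96-well plates, 92 sample wells per
plate plus two 1% v/v DMSO and two 1% v/v water vehicle wells (column
12; real control positions are rarely published, so a fixed edge column
is used). The primary read is the lipase signal after 0.25 months
(~1 week) at −20 °C. Hit triage: per-plate Z-scores against pooled
vehicle wells are reported as diagnostics, the operative primary gate is
the absolute ≤ 400 RFU threshold (a config flag switches to strict <);
retest applies the same criterion to an independently noised replica of
the screen; the final gate demands strictly > 75% lysozyme *and*
protease retention versus untreated milk at the same storage time (a
fresh-milk reference is available via config). With actives planted at
ρ ≤ 0.2 and CV ≤ 2%, active wells sit near 350 RFU and inactive wells
near 1400 RFU, so sensitivity and specificity are exactly 1 — verified
empirically over ≥ 20 seeds rather than assumed.

The dilution-series generator attenuates a compound's effect with
2-fold dilution as `ρ_eff(d) = 1 − (1 − ρ)·2^d` for dilution index
d ∈ {0, …, −7} (full effect undiluted, essentially none at −7). No
published dose–response law exists for these compounds; this is the
simplest monotone interpolation and is used only to produce dose tables
with a known trend.

## Storage metrics and kinetic fits

Percent glycerol reduction is an endpoint ratio,
`100·(1 − treated/untreated)` at the latest shared time ≥ 6 months
(nearest-time alignment, max gap 0.5 months); an AUC-ratio variant is
available via config. Volume fractions use the pre-transfer convention
(1.5 µL into 150 µL = 1% v/v). Normalisation divides by the mean of the
designated reference group (untreated fresh milk for antioxidant
capacity, untreated frozen milk for lipolysis) and is scale-invariant.

`FirstOrderKinetics` fits `G(t) = g_max(1 − e^{−kt})` by bounded
nonlinear least squares (initial g_max = 1.1 × max observation, initial
k from a log-linear regression of −log(1 − G/g_max₀) on t). Noiseless
trajectories are recovered to relative error < 10⁻⁶. At 10% CV with 8
time points the median relative error of k̂ is ~14% when the series
reaches ~94% saturation (grid to 9 months); truncating at 6 months (83%
saturation) degrades this to ~18% because g_max and k trade off almost
linearly short of the plateau — rate estimates from short series should
be treated with caution.

## Statistics

One-way ANOVA is computed directly from the sums-of-squares
decomposition; balanced two-way (sequential SS, which equals the
orthogonal decomposition when balanced, so no SS-type ambiguity) and
univariate repeated-measures ANOVA (subject as blocking factor, no
sphericity correction) go through statsmodels OLS. Unbalanced designs
raise an explicit error rather than silently choosing a SS type. Tukey
HSD uses the studentized-range distribution; Bartlett and Brown–Forsythe
(median-centred Levene) test variance homogeneity; the normality gate
uses bias-corrected sample skewness and excess kurtosis with the
|skew| ≤ 1 and |excess kurtosis| ≤ 2 rule — the band is interpreted on
*excess* kurtosis because a raw-kurtosis band of ±2 would reject the
normal distribution itself. Pearson chi-square runs without continuity
correction. Significance is α = 0.05 throughout. Note Brown–Forsythe is
conservative for small groups; its type-I error approaches the nominal
5% only at moderate group sizes (n ≈ 20).

## Survey generator and tabulation

Respondents are generated branch-consistently: storage-method questions
only for storers, freezer duration/reasons only for freezer users,
discard reasons only for discarders. Default marginals follow the
published storage-practices pattern (83% store, 68% of storers freeze,
durations 31/40/17/12%, 75% discard, 20% sensory change, 26% infant
rejection among storers). Tabulation records its denominator rule
explicitly; multi-select percentages may exceed 100% in total. A
planted monotone duration→sensory-change trend is available for
power/calibration studies of the chi-square cross-tab.

## What the generator does and does not emulate

It reproduces the *structure* of the real study — plate layouts with
vehicle controls, paired donor arms, multiplicative measurement noise,
branch-consistent survey data — with known ground truth. It does not
model oxidation product chemistry (peroxides, aldehydes, alkenals),
bacterial growth, freeze–thaw cycling, vitamin panels beyond an
ascorbate-equivalent capacity, plate-edge evaporation, or instrument
drift beyond the optional linear gradient. Passing tests therefore
demonstrate the correctness and calibration of the *analysis* chain
under the stated model, not the biological accuracy of the model itself;
real screens will have lower separation between actives and inactives
than the ≥7σ margin engineered here, and real hit-confirmation rates
(e.g. 21 primary → 15 confirmed) reflect assay drift and compound
behaviour the simulator deliberately leaves out.

## Problem sizes

Default study conditions: 14 donors, time courses to 6 months, 2750
compounds on 30 plates with 21 planted actives, 1049 survey
respondents. Calibration suites use 2000 ANOVA null replicates, 1000
variance-test replicates, 100-seed kinetic-fit studies, 20-seed screen
recovery checks, and 10⁵-respondent marginal-recovery checks.
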