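# Methods

## The problem

People with multiple sclerosis (MS) frequently report somatosensory
abnormalities. Skin *wetness* perception (hygrosensing) is inferred
centrally from thermal and tactile cues — human skin has no humidity
receptors — so damage anywhere along the spinothalamic or dorsal-column
pathways, or in the insular/somatosensory cortices, can degrade it.
This package implements the quantitative-sensory-testing (QST) analysis
used to ask two questions about a cohort of MS patients and matched
healthy controls:

1. **Group level** — does MS shift wetness perception as a group, either
   under normothermia or when whole-body mean skin temperature is driven
   warm or cold?
2. **Individual level** — do *particular* patients show hygrosensory
   loss relative to a normative control distribution, even when the
   group means do not differ?

The experimental protocol it models: three 50-min climate-chamber
sessions (thermoneutral / heat / cold) per participant; during the final
15 min a wet probe (1.32 cm², 0.8 mL water; 25 / 30 / 35 °C for
cold-/neutral-/warm-wet qualities) is applied statically and then
dynamically to the index finger pad, volar forearm and forehead, and the
participant marks wetness and thermal magnitude on 100-mm visual
analogue scales (VAS).

## Mean skin temperature

Whole-body mean skin temperature is the fixed-weight sum of six local
thermistors:

```
mean Tsk = 0.14·cheek + 0.19·chest + 0.11·forearm + 0.05·hand + 0.32·thigh + 0.19·back
```

Sampling is 2 Hz; the analysis window is the final 15 min of the session
(`[2100, 3000)` s — the half-open convention is ours, the protocol names
only "the final 15 min"). Because the weighting is linear, averaging the
weighted sum per sample equals weighting per-channel window averages; we
do the former. Gaps are not interpolated — 2-Hz data are dense and
imputation would add assumptions — they only reduce `n_samples`.
Session contrasts are paired within-participant differences with a
t-based 95 % CI on n−1 df, which matches the repeated-measures design;
a Tukey-adjusted alternative is available from the ANOVA module.

## Individual z-score profiling

For each (site, quality) cell with a normative reference (forehead and
finger pad; no forearm normative data set exists, those cells are
skipped with a warning):

```
z = (log10(x + 1) − mean_log) / sd_log
```

where `mean_log`, `sd_log` are the sample moments (n−1 denominator) of
the log-transformed pooled control ratings. References are always
recomputed from raw control values; log-scale moments cannot be
recovered from published raw-scale summaries. The `+1` mm offset keeps
ratings of 0 finite; it is configurable and recorded in output metadata.
Classification is strict: `z < −1.96` → LOSS, `z > +1.96` → GAIN,
anything else (including exact ties) → NORMAL. The published criterion
text contains a sign slip ("greater than −1.96" for loss); context and
the published table boldfacing make the intended rule `z < −1.96`, which
is what we implement. A participant is *flagged* if at least one cell is
abnormal; the summary reports distinct sites and qualities involved.

**A property worth knowing.** On log scale, a truncated-normal VAS cell
is left-skewed, so the estimated z of a healthy rating falls below −1.96
with probability ≈ 6 %, not the Gaussian 2.5 %. Over six profiled cells
that compounds to a ≈ 30 % chance that a healthy-profile participant is
flagged at least once. This is an intrinsic feature of the ±1.96
single-cell rule applied cell-wise without multiplicity control — it is
visible in our synthetic recovery experiments and should temper the
interpretation of single-cell abnormalities in real profiles.
Sensitivity for genuine floor-level loss (ratings near 0–5 mm on cells
whose normative mean is ≥ 40 mm) exceeds 0.95.

## Mixed-design ANOVA

Two-way mixed design: a between factor (group) crossed with a within
factor (mode, 2 levels; or session, 3 levels), complete cases only.
Because every subject provides every within level, cell counts are
proportional and the classical decomposition is orthogonal:

| effect | SS | tested against |
|---|---|---|
| group | m·Σᵢ nᵢ(ȳᵢ − ȳ)² | subjects within groups |
| subjects w. groups | m·Σₛ(ȳₛ − ȳᵢ₍ₛ₎)² | — |
| within | N·Σⱼ(ȳ.ⱼ − ȳ)² | residual |
| group × within | cell SS − group − within | residual |
| residual | by subtraction | — |

F ratios use the stratum-appropriate error terms; with 12 + 11 subjects
and 2 within levels every test has the (1, 21) df pair. For m ≥ 3 the
Greenhouse–Geisser ε — computed from the double-centered, group-pooled
within-level covariance matrix — multiplies the within-stratum dfs
unconditionally (no sphericity pretest), matching the convention of
reporting fractional dfs; ε is clipped to [1/(m−1), 1] and equals 1
exactly at m = 2. Effect sizes are percent of total variation,
100·SS/SS_total with subjects-within-groups included in the total.
The implementation is validated against an independent least-squares
projection oracle (explicit dummy design matrices, `lstsq`) to 1e-8 on
random small designs, and its type-I error under a spherical null sits
inside [0.035, 0.065] at α = 0.05 over 5000 simulations.

Post hocs: Tukey(-Kramer) HSD with the studentized-range CDF evaluated
by our own quadrature (160-node Gauss–Legendre inner integral over the
range probability, adaptive outer integral against the chi density of
the scale estimate; agrees with `scipy.stats.studentized_range` to
~1e-9 and with published q tables to 3 decimals); Sidak adjustment
`1 − (1−p)^m`; paired t contrasts. The error term and df that the
original post-hoc CIs used are unstated in the source material, so both
the paired-t and Tukey constructions are exposed.

Normality screening uses the one-sample Kolmogorov–Smirnov test with
sample-estimated mean/SD and the asymptotic p — deliberately the
everyday convention, and documented as anti-conservative (it
under-rejects) when parameters are estimated.

A-priori power uses the noncentral F for a one-way k-group design with
λ = f²·k·n. For the protocol's stated inputs (Cohen's f = 0.93,
α = 0.05, power = 0.8, k = 2) the direct computation gives **n = 6 per
group**; the original power software reported 8 (its exact procedure —
test family, tails — is unstated). We report our own number and note
that n = 8 per group exceeds the 0.8 target (power ≈ 0.92) under our
criterion.

## Synthetic cohort generator

The generator exists so every downstream stage is testable without any
data download. It encodes the study conditions as defaults:

| parameter | default | origin |
|---|---|---|
| wetness cell law | normal truncated to [0, 100] mm | VAS bounds |
| dynamic normative means (forehead) | 53.7 / 40.6 / 41.3 mm (SD 27.4 / 29.3 / 28.6), n = 51 | published normative summaries |
| dynamic normative means (finger pad) | 67.7 / 51.7 / 47.6 mm (SD 21.1 / 24.2 / 28.6), n = 31 | published normative summaries |
| dynamic−static increment | finger 15.5, forearm 12.4, forehead 19.7 mm | published mode contrasts |
| session wetness shift | 0 / +4.75 / −4.75 mm (neutral/heat/cold) | published heat−cold ≈ 9.5 mm |
| mean Tsk targets | 30.9 / 34.8 / 26.5 °C | published session means |
| Tsk noise | 0.5 °C between-participant SD | our choice, matches published spread |
| rectal | 37.0 ± 0.1 °C | stable-core protocol |
| loss injection floor | 2 ± 2 mm | published abnormal values of 0–3 mm |

Static cell baselines are the published dynamic means minus the site
increment, so generated DYNAMIC cells hit the published normative
values. The forearm, which has no published normative distribution, uses
a 40 ± 25 mm static baseline of our choosing (a plausible hairy-skin
cell between the forehead and finger-pad values).

Sampling is exact truncated normal by inverse CDF — the same law as
rejection sampling, chosen over clamping because clamping would pile
mass at 0/100 and mimic sensory loss spuriously. Everything is
deterministic given the seed (NumPy PCG64, recorded with a config hash
in the provenance output); temperature traces derive per
(participant, session) sub-seeds via CRC32 tags so they can be
regenerated independently.

Temperature traces ramp the mean-Tsk level linearly from the
thermoneutral baseline to the session target over the first 35 min and
hold it for the final 15; channels are the level plus fixed site offsets
whose weighted sum is zero, so the weighted mean equals the target
analytically, plus noise. With zero noise the window average reproduces
the targets exactly — and therefore the +3.9 / −4.4 °C session
contrasts by construction.

**What the generator does not emulate** (hence what passing tests do not
show about real data): correlations between a participant's cells (all
cells are drawn independently; real perceptual data are surely
positively correlated within participants), within-trial rating
dynamics, thermal-VAS structure beyond quality-ordered means (no mode or
session effects on thermal ratings), sweating/vasomotor physiology, and
integer-rounded VAS marks (ratings are stored as reals).

**Truncation attenuation.** Adding a shift δ to a cell mean moves the
*truncated* mean by less than δ when the mass sits near a scale end.
With the default ±4.75 mm session shifts the realized collapsed dynamic
heat−cold contrast is analytically ≈ 6.9 mm rather than the nominal
9.5 mm; similarly the forehead cold-wet cell's truncated mean is 52.6 mm
for a configured 53.7 mm. Tests therefore compare Monte-Carlo output
against exact truncated-normal expectations, not against the configured
(pre-truncation) parameters.

## Problem sizes used

The test suite and analysis scripts run on deliberately modest sizes:
the tested cohort at the study's 12 + 11, normative pools of 31–51
controls, 100 random designs for the ANOVA oracle check, 5000 replicates
for the type-I calibration, 200 seeded cohorts for the loss-recovery
experiment, and 2-Hz traces regenerated on demand rather than stored.

## Known limitations

* Published individual z-scores cannot be re-derived here: the normative
  raw values live in the study's external deposit, and no simple
  log-offset choice reproduces printed values like −16.47 from the
  printed raw summaries. The package therefore classifies published
  z-scores directly and recomputes z only for data it has raw values for.
* The per-participant false-flag behaviour described above means
  "exactly the injected participants are flagged" holds only
  approximately on synthetic cohorts; the recovery guarantees are stated
  per cell (sensitivity) and measured honestly per participant.
* Only two-group, single-within-factor designs are supported; no
  Huynh–Feldt correction, no unbalanced/missing-data mixed models.
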