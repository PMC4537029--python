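# Methods

## The DL synergy model

The package scores combination treatments against Bliss independence: if
PDT and an EGFR inhibitor act by distinct mechanisms, the expected
combination survival fraction is the product of the monotherapy survival
fractions, `SF_add = SF_PDT × SF_inhibitor`. Departures are measured on
the log scale by the difference in logarithms,

    DL = log10(SF_PDT) + log10(SF_inhibitor) − log10(SF_comb),

so DL > 0 means extra killing beyond independence, DL < 0 less, DL = 0
exact additivity. DL is base-10 by the package's convention; the choice is
cosmetic for inference because a base change rescales the DL mean and its
standard error by the same factor, leaving *t*, *p* and the call
unchanged (asserted to 1e-12 in the tests).

**Replication unit.** Survival fractions are formed *within* each
independent experiment (mean corrected signal of an arm divided by the
mean corrected untreated-control signal of the same experiment), and one
DL is computed per experiment from that experiment's three arms. This
pairing cancels experiment-level multiplicative effects, and it fixes the
degrees of freedom at n_experiments − 1 for the default analysis.
Statistics are never pooled across wells from different experiments.

**Test and call.** The DL replicates are tested against zero with a
two-sided one-sample *t*-test. Classification applies the significance
gate first: p < α (default 0.05) and DL > 0 → synergistic; p < α and
DL < 0 → antagonistic; anything else — including a tie at exactly
p = α — is additive. `dl_test` also accepts (mean, SE, df) summaries
directly so published summary rows can be re-tested as printed; published
tables often omit replicate counts, so the df is a caller-supplied input
there (the bundled summary rows are consistent with df = 5 for three of
the cell-line panels and df = 4 for the fourth and the xenograft row, and
that mapping ships with the data).

**Degenerate dispersion.** When the DL replicates are numerically
identical (SE below 1e-15), a mean within 1e-12 of zero is reported as
additive with p = 1 (exact additivity, typical of noiseless simulations);
a larger mean yields p = 0 with a warning, since the *t*-statistic is
unbounded. These tolerances are float round-off allowances, not tunable
thresholds.

## From plate to survival fraction

Blank (medium-only) wells define per-experiment background, subtracted
from every well; a plate whose corrected untreated-control mean is ≤ 0 is
rejected as uninterpretable. Corrected signal is treated as proportional
to viable cell number (the ATP-luminescence assumption); no nonlinearity
correction is attempted. Nonpositive survival fractions are a hard error
by default; an optional floor (typically 1e-4) clamps them for the log
transform, for plates where strong treatments push signals into the
background noise. Percent viability is 100 × mean SF across experiments
with SE = 100 × sd/√n. Fluorescent cell dose curves (migration/invasion
assays) are fitted by ordinary least squares of signal on cell number and
inverted as (signal − intercept)/slope; inverse predictions outside the
fitted range are flagged as extrapolated rather than rejected, because kit
protocols routinely read slightly beyond the highest standard.

## In-vivo analysis

Tumor volume is the orthogonal-diameter ellipsoid `V = π/6·d₁·d₂·d₃`
(mm³). Group growth summaries report mean ± SE by day over the animals
still on study (an animal leaves the summary after its event day; n per
cell is reported, SE is undefined at n = 1).

The in-vivo DL analog uses relative tumor burden at a fixed endpoint day:
SF = animal volume ÷ concurrent control-group mean. The control and the
two monotherapy groups enter as group means; the combination SF varies per
animal, giving the DL replicates (df = n_combination − 1, overridable).
The default endpoint is the last day common to all four groups; analyses
here use day 32, the day untreated tumors typically reach the ceiling.
This volume-at-endpoint reading is one of several possible constructions
(growth rates or areas under the growth curve are alternatives); it is the
most direct volume-based one and is surfaced as a parameter rather than
hidden.

Kaplan–Meier estimation delegates to lifelines' product-limit
implementation behind the `km_estimate` surface, with events processed
before censorings at tied times; the tests cross-check it against a
brute-force enumeration of risk sets. Events are declared only on
measurement days (no interpolation between visits), matching how an
ethical ceiling is actually enforced.

## Toxicity panel

The creatinine kit's two reads (1 and 30 min) are differenced per
standard, the ΔOD values regressed on concentration, and samples inverted
through the line. Urea nitrogen uses the same linear inversion on a single
endpoint read. AST/ALT kinetic activity is B/((T2 − T1)·V) in
nmol/min/ml = mU/ml, with B obtained by inverting both timepoint reads
through the pyruvate standard curve and differencing (the curve intercept
cancels). The activity formula is the only reading of the kit arithmetic
consistent with its stated units. Normal ranges (mouse serum) default to
creatinine 0.1–2.1 mg/dL, urea nitrogen 2–71 mg/dL, AST 37–329 mU/ml,
ALT 7–227 mU/ml, inclusive at both ends, and are configurable. Standard
concentrations for the urea kit are configuration defaults, not assay
constants.

## Synthetic-data generators

The generators define the package's test bed and encode the study design
they emulate: 3 independent experiments with treatments in triplicate for
viability, four 10-animal arms followed for 90 days with a 2000 mm³
ceiling for the xenograft study.

**Viability.** Noise is Gaussian on log10 SF (SD `noise_sd_log`, default
0.05), drawn once per treated arm per experiment — multiplicative on the
SF scale, which keeps simulated SFs positive and matches the statistic's
log scale; no noise model was specified by the emulated protocols, so this
is the package's choice. Combination arms realise
`SF_comb = SF_PDT × SF_inh × 10^(−true_DL)`, inverting the DL definition
so the noiseless pipeline recovers the truth exactly. Raw signal is
`blank + SF × (control − blank)`; optional additive per-well read noise
(`read_noise_sd`) is off by default so the default semantics are the exact
round trip. A vectorised sampler (`sample_dl_replicates`) draws
per-experiment DLs directly from the equivalent model
`DL_e ~ N(true_DL, noise_sd_log·√3)`; the Monte-Carlo calibration and
recovery checks use it to keep 10,000-dataset runs in seconds, and a
contract test pins its moments to the full plate pipeline.

**Xenografts.** Exponential growth `V(t) = V0·exp(r·m·t)` with control
rate r = ln10/32 per day (200 → 2000 mm³ in 32 days), group multipliers m,
per-animal lognormal rate heterogeneity (SD 0.15 on the log rate), and
independent N(0, 0.3 mm) jitter on each recorded diameter. On the rate
scale Bliss additivity is `m_comb = m_pdt + m_inh − 1`
(`additive_multiplier`); the default combination multiplier 0.18 sits
below the additive 0.30, building in true synergy. Events occur on the
first measurement day (every 2 days by default) whose recorded volume
reaches the ceiling; survivors are censored at day 90.

**What the simulators do not model:** plate spatial effects, assay
saturation/nonlinearity, photosensitizer dark toxicity kinetics,
pharmacokinetics, tumor shape anisotropy beyond independent diameter
jitter, measurement-schedule irregularities, and animal withdrawal for
reasons other than the ceiling. Passing tests therefore certify the
arithmetic and inference machinery under the stated noise models, not
robustness to those real-data features.

## Problem sizes and numerical choices

The calibration suite uses 10,000 simulated null datasets (type-I error
vs a reference *t*-test oracle, agreement within 3 binomial SEs), 1,000
datasets per truth for recovery/coverage, and 150 full-pipeline plates
for the sampler-contract check — sizes at which binomial Monte-Carlo error
is small relative to the tolerances being asserted. All generators accept
a seed and are bit-reproducible under it. Dose matching when pairing
combination arms with their mono arms is exact (doses are categorical
labels); standard-curve fits require ≥ 2 distinct x and a nonzero slope.

## Known limitations

- The in-vivo DL depends on the endpoint-day choice; late endpoints can
  condition the control mean on slower-growing survivors (animals that
  reached the ceiling no longer contribute measurements).
- With 3 experiments the *t*-test has low power for small DL; calls of
  "additive" are absence of evidence, not evidence of additivity.
- The SF floor, when enabled, biases DL upward for near-total-kill
  combinations; it exists to keep logs finite, not as an inference device.
- Percent-viability SEs assume experiments are exchangeable replicates;
  systematic between-day drifts are absorbed into the SF pairing only for
  DL, not for percent viability itself.
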