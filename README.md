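# combsynergy

Quantitative analysis of drug-combination experiments in photodynamic
therapy (PDT), built for preclinical studies that pair a photosensitizer
(e.g. chlorin e6 + light) with an EGFR inhibitor (nimotuzumab, cetuximab)
in oral-cancer cell lines and xenograft models. The package takes raw
plate-reader signals and animal measurements to a complete statistical
report: survival fractions, synergy calls, tumor-growth and survival
summaries, and a serum toxicity panel — and it ships simulators for every
assay so the whole pipeline is testable with known ground truth.

## The statistic at the core

Two treatments acting by independent mechanisms combine multiplicatively
on the survival-fraction scale (Bliss independence):

    SF_add = SF_PDT × SF_inhibitor

The observed combination survival `SF_comb` is compared with this
expectation by the **difference in logarithms**

    DL = log₁₀ SF_PDT + log₁₀ SF_inhibitor − log₁₀ SF_comb = log₁₀(SF_add / SF_comb)

One DL is computed per independent experiment (arms within an experiment
are paired, so plate effects cancel) and the replicates are tested against
zero with a two-sided one-sample *t*-test. With significance gate first:
`p < α` and DL > 0 → **synergistic**; `p < α` and DL < 0 →
**antagonistic**; otherwise **additive**. The *t* statistic and *p* are
invariant to the logarithm base; DL values are reported in log₁₀ units.

The same statistic is applied in vivo by treating relative tumor burden —
each animal's ellipsoid volume `V = π/6·d₁·d₂·d₃` divided by the
concurrent control mean at a fixed endpoint day — as the SF analog.
Survival is summarised with the Kaplan–Meier product-limit estimator under
ethical-limit censoring (event at the 2 cm³ ceiling, censoring at the
90-day horizon).

## Worked example

```python
import combsynergy as cs

spec = cs.ViabilitySimSpec(noise_sd_log=0.05, seed=42)   # true DL = 0.3
design, measurements = cs.simulate_viability_experiment(spec)
sf = cs.survival_fraction(cs.background_correct(measurements, design), design)
print(cs.synergy_table(design, sf)[["treatment", "dl", "se", "p", "call"]])
```

prints (seed 42):

```
              treatment       dl       se        p        call
  pdt_50+nimotuzumab_50 0.298139 0.016788 0.003156 synergistic
 pdt_50+nimotuzumab_100 0.282602 0.046275 0.025780 synergistic
 pdt_100+nimotuzumab_50 0.276639 0.053620 0.035576 synergistic
pdt_100+nimotuzumab_100 0.260291 0.060652 0.050240    additive
```

Each row is one combination arm of a 2×2 dose grid: the estimated DL is
close to the simulated truth of 0.3, and the *t*-test on 3 independent
experiments decides the call — the last row shows how a p-value landing
just above α = 0.05 is conservatively classified additive.

More narrative scripts live in `examples/` (published-summary re-testing,
the in-vitro pipeline, xenograft growth + Kaplan–Meier, the toxicity
panel). A thin CLI wraps the same stages:

```
combsynergy simulate --kind viability --seed 1 --out sim/
combsynergy viability --design sim/design.csv --measurements sim/measurements.csv --out out/
combsynergy synergy --design sim/design.csv --sf out/survival_fractions.csv --out synergy.csv
combsynergy all --seed 1 --out bundle/      # full pipeline + manifest
```

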