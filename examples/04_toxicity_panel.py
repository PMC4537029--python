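"""Serum toxicity panel: creatinine, urea nitrogen, AST activity.

Simulates kit reads with mild optical-density noise and runs the panel
calculators: the creatinine two-read standard-curve regression, the urea
endpoint inversion, and the kinetic AST activity B / ((T2 - T1) * V), then
flags every value against mouse-serum normal ranges.
"""

import combsynergy as cs

spec = cs.ToxicitySimSpec(read_noise_sd=0.002, seed=3)
panel = cs.simulate_toxicity_panel(spec)

od1, od30 = panel["creatinine_samples"][0]
creatinine = cs.creatinine_concentration(od1, od30, panel["creatinine_standards"])
urea = cs.endpoint_concentration(panel["urea_samples"][0], panel["urea_standards"])
curve = cs.fit_standard_curve(panel["pyruvate_standards"])
ast = cs.activity_from_read(panel["kinetic_reads"][0], curve)

for res in cs.flag_ranges(
    {"creatinine": creatinine, "urea_nitrogen": urea, "AST": ast}
):
    print(f"{res.analyte:14s} {res.value:7.2f} {res.units:6s} "
          f"normal [{res.normal_low}-{res.normal_high}] -> {res.flag}")

# Values inside their normal range indicate no kidney/liver toxicity signal;
# the simulated truths (0.5 mg/dL, 12 mg/dL, 50 mU/ml) are recovered up to
# the read noise.
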