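"""The synthetic-data generators: ground-truth inversion, determinism,
round trips, and agreement between the plate simulator and the vectorised
DL sampler."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import combsynergy as cs
from combsynergy.errors import InvalidInputError

sf = st.floats(min_value=1e-4, max_value=1.0)


class TestSimulateCombinationSF:
    @pytest.mark.parametrize(
        "sf_a, sf_b, true_dl, expected",
        [
            (0.25, 0.8, 0.0, 0.20),
            (0.25, 0.8, 1.0, 0.02),
            (0.5, 0.5, -0.30103, 0.5),
        ],
    )
    def test_worked_examples(self, sf_a, sf_b, true_dl, expected):
        assert cs.simulate_combination_sf(sf_a, sf_b, true_dl) == pytest.approx(
            expected, abs=1e-5
        )

    @given(a=sf, b=sf, dl=st.floats(min_value=-2, max_value=2))
    def test_inverts_dl_definition(self, a, b, dl):
        comb = cs.simulate_combination_sf(a, b, dl)
        assert comb > 0
        assert cs.dl_statistic(a, b, comb) == pytest.approx(dl, abs=1e-9)

    def test_nonpositive_sf_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.simulate_combination_sf(0.0, 0.5, 0.1)


class TestViabilitySimulator:
    def test_seed_determinism_bit_identical(self):
        spec = cs.ViabilitySimSpec(seed=1)
        _, ms1 = cs.simulate_viability_experiment(spec)
        _, ms2 = cs.simulate_viability_experiment(cs.ViabilitySimSpec(seed=1))
        pd.testing.assert_frame_equal(ms1.data, ms2.data)
        _, ms3 = cs.simulate_viability_experiment(cs.ViabilitySimSpec(seed=2))
        assert not ms1.data["signal"].equals(ms3.data["signal"])

    def test_noiseless_full_round_trip_recovers_true_dl(self, noiseless_sf):
        design, sf_records, spec = noiseless_sf
        table = cs.synergy_table(design, sf_records)
        for _, row in table.iterrows():
            assert row["dl"] == pytest.approx(
                spec.true_dl[row["treatment"]], abs=1e-12
            )

    def test_spec_validation(self):
        with pytest.raises(InvalidInputError):
            cs.ViabilitySimSpec(n_experiments=1)
        with pytest.raises(InvalidInputError):
            cs.ViabilitySimSpec(noise_sd_log=-0.1)
        with pytest.raises(InvalidInputError):
            cs.ViabilitySimSpec(true_sf={"pdt_50": 1.5})
        with pytest.raises(InvalidInputError):
            cs.ViabilitySimSpec(true_dl={"pdt_50": 0.3})

    def test_mean_recovered_dl_unbiased_on_log_scale(self):
        # >= 1000 noisy datasets: mean recovered DL within 3 MC SEs of truth
        true_dl = 0.3
        dls = cs.sample_dl_replicates(true_dl, 0.05, 3, 2000, seed=21)
        recovered = dls.mean(axis=1)
        mc_se = recovered.std(ddof=1) / math.sqrt(len(recovered))
        assert abs(recovered.mean() - true_dl) <= 3 * mc_se

    def test_dl_sampler_matches_plate_simulator_moments(self):
        """The vectorised DL sampler and the full plate pipeline describe the
        same noise model: identical truth, and replicate SD close to
        noise_sd_log * sqrt(3)."""
        noise = 0.05
        pipeline_dls = []
        for seed in range(150):
            spec = cs.ViabilitySimSpec(
                noise_sd_log=noise, seed=1000 + seed,
                true_dl={c: 0.3 for c in cs.grid_design().ids_with_role("combination")},
            )
            design, ms = cs.simulate_viability_experiment(spec)
            sf_records = cs.survival_fraction(
                cs.background_correct(ms, design), design
            )
            triple = cs.match_triples(design)[0]
            pipeline_dls.extend(cs.dl_replicates(triple, sf_records))
        pipeline_dls = np.asarray(pipeline_dls)
        sampled = cs.sample_dl_replicates(0.3, noise, 3, 150, seed=77).ravel()
        expected_sd = noise * math.sqrt(3)
        assert pipeline_dls.mean() == pytest.approx(0.3, abs=0.02)
        assert sampled.mean() == pytest.approx(0.3, abs=0.02)
        assert pipeline_dls.std(ddof=1) == pytest.approx(expected_sd, rel=0.25)
        assert sampled.std(ddof=1) == pytest.approx(expected_sd, rel=0.25)


class TestTumorSimulator:
    def test_seed_determinism(self):
        s1 = cs.simulate_tumor_cohort(cs.TumorSimSpec(seed=4))
        s2 = cs.simulate_tumor_cohort(cs.TumorSimSpec(seed=4))
        pd.testing.assert_frame_equal(s1.measurements, s2.measurements)
        pd.testing.assert_frame_equal(s1.survival, s2.survival)

    def test_zero_multiplier_all_censored_at_horizon(self):
        groups = {"frozen": cs.TumorGroupSpec(multiplier=0.0)}
        spec = cs.TumorSimSpec(groups=groups, seed=1)
        study = cs.simulate_tumor_cohort(spec)
        assert (study.survival["event"] == 0).all()
        assert (study.survival["time_days"] == spec.horizon_days).all()

    def test_fast_growth_events_at_closed_form_crossing_day(self):
        # noiseless exponential crosses the ceiling at t* = ln(C/V0)/r;
        # the event lands on the first measurement day >= t*
        groups = {"control": cs.TumorGroupSpec(multiplier=1.3)}
        spec = cs.TumorSimSpec(groups=groups, rate_noise_sd=0.0,
                               diameter_noise_sd=0.0, seed=0)
        study = cs.simulate_tumor_cohort(spec)
        t_star = math.log(
            spec.ceiling_volume_mm3 / 200.0
        ) / (spec.growth_rate * 1.3)
        days = sorted(spec.measurement_days)
        expected_day = next(d for d in days if d >= t_star)
        assert (study.survival["event"] == 1).all()
        assert (study.survival["time_days"] == expected_day).all()
        assert expected_day < spec.horizon_days

    def test_spec_validation(self):
        with pytest.raises(InvalidInputError):
            cs.TumorSimSpec(horizon_days=0)
        with pytest.raises(InvalidInputError):
            cs.TumorSimSpec(
                groups={"g": cs.TumorGroupSpec(initial_volume_mm3=3000.0)}
            )


class TestToxicitySimulator:
    def test_seed_determinism(self):
        p1 = cs.simulate_toxicity_panel(cs.ToxicitySimSpec(read_noise_sd=0.002, seed=6))
        p2 = cs.simulate_toxicity_panel(cs.ToxicitySimSpec(read_noise_sd=0.002, seed=6))
        assert p1["creatinine_standards"] == p2["creatinine_standards"]
        assert p1["urea_samples"] == p2["urea_samples"]

    def test_noiseless_panel_round_trips_exactly(self):
        spec = cs.ToxicitySimSpec(seed=0)
        panel = cs.simulate_toxicity_panel(spec)
        for (od1, od30), truth in zip(
            panel["creatinine_samples"], spec.true_creatinine_mg_dl
        ):
            got = cs.creatinine_concentration(od1, od30,
                                              panel["creatinine_standards"])
            assert got == pytest.approx(truth, abs=1e-9)
        for od, truth in zip(panel["urea_samples"], spec.true_urea_mg_dl):
            assert cs.endpoint_concentration(od, panel["urea_standards"]) == (
                pytest.approx(truth, abs=1e-9)
            )
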