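"""Tumor volume, growth summaries, the in-vivo DL analog, Kaplan-Meier."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import combsynergy as cs
from combsynergy.errors import AnalysisError, InvalidInputError, SchemaError

diam = st.floats(min_value=0.1, max_value=50.0)


class TestTumorVolume:
    def test_unit_sphere_factor(self):
        assert cs.tumor_volume(1, 1, 1) == pytest.approx(math.pi / 6)

    def test_six_mm_sphere(self):
        assert cs.tumor_volume(6, 6, 6) == pytest.approx(113.10, abs=0.01)

    @given(d1=diam, d2=diam, d3=diam)
    def test_permutation_invariance(self, d1, d2, d3):
        assert cs.tumor_volume(d1, d2, d3) == pytest.approx(
            cs.tumor_volume(d3, d2, d1), rel=1e-12
        )

    @given(d1=diam, d2=diam, d3=diam, k=st.floats(min_value=0.1, max_value=10.0))
    def test_homogeneous_of_degree_three(self, d1, d2, d3, k):
        assert cs.tumor_volume(k * d1, k * d2, k * d3) == pytest.approx(
            k**3 * cs.tumor_volume(d1, d2, d3), rel=1e-9
        )

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -2, 1), (1, 1, 0)])
    def test_nonpositive_diameter_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            cs.tumor_volume(*bad)


def _noiseless_study(**kwargs):
    spec = cs.TumorSimSpec(
        rate_noise_sd=0.0, diameter_noise_sd=0.0, seed=0, **kwargs
    )
    return spec, cs.simulate_tumor_cohort(spec)


class TestGrowthSummary:
    def test_noiseless_exponential_matches_closed_form(self):
        spec, study = _noiseless_study()
        summary = cs.growth_summary(study)
        ctrl = summary[summary["group"] == "control"]
        for _, row in ctrl.iterrows():
            expected = 200.0 * math.exp(spec.growth_rate * row["day"])
            assert row["mean_volume_mm3"] == pytest.approx(expected, rel=1e-9)

    def test_shuffled_rows_identical_summary(self):
        _, study = _noiseless_study()
        shuffled = cs.TumorStudy(
            measurements=study.measurements.sample(frac=1.0, random_state=4),
            survival=study.survival,
        )
        pd.testing.assert_frame_equal(
            cs.growth_summary(study), cs.growth_summary(shuffled)
        )

    def test_single_animal_se_missing(self):
        groups = {"control": cs.TumorGroupSpec(n_animals=1)}
        spec = cs.TumorSimSpec(groups=groups, rate_noise_sd=0, diameter_noise_sd=0,
                               seed=0)
        summary = cs.growth_summary(cs.simulate_tumor_cohort(spec))
        assert summary["n"].eq(1).all()
        assert summary["se_volume_mm3"].isna().all()

    def test_animals_excluded_after_event(self):
        _, study = _noiseless_study()
        summary = cs.growth_summary(study)
        ctrl = summary[summary["group"] == "control"]
        # all control animals cross the ceiling on the same (noiseless) day
        assert ctrl["day"].max() == study.survival.loc[
            study.survival["group"] == "control", "time_days"
        ].max()

    def test_missing_requested_day_rejected(self):
        _, study = _noiseless_study()
        with pytest.raises(AnalysisError, match="no measurements at day"):
            cs.growth_summary(study, days=[1])  # off the measurement grid


class TestInvivoDL:
    def test_additive_null_by_construction(self):
        groups = {
            "control": cs.TumorGroupSpec(multiplier=1.0),
            "pdt": cs.TumorGroupSpec(multiplier=0.6),
            "inhibitor": cs.TumorGroupSpec(multiplier=0.7),
            "combination": cs.TumorGroupSpec(
                multiplier=cs.additive_multiplier(0.6, 0.7)
            ),
        }
        spec = cs.TumorSimSpec(groups=groups, rate_noise_sd=0.0,
                               diameter_noise_sd=0.0, seed=0)
        res = cs.invivo_dl(cs.simulate_tumor_cohort(spec), endpoint_day=20)
        assert abs(res.dl_mean) < 1e-9
        assert res.call == "additive"

    def test_supermultiplicative_suppression_detected(self):
        study = cs.simulate_tumor_cohort(cs.TumorSimSpec(seed=5))
        res = cs.invivo_dl(study, endpoint_day=32)
        assert res.dl_mean > 0
        assert res.p_value < 0.05
        assert res.call == "synergistic"
        assert res.df == res.n - 1

    def test_reduces_to_dl_statistic_with_one_animal_per_group(self):
        groups = {
            name: cs.TumorGroupSpec(n_animals=2, multiplier=m)
            for name, m in
            [("control", 1.0), ("pdt", 0.6), ("inhibitor", 0.7),
             ("combination", 0.2)]
        }
        spec = cs.TumorSimSpec(groups=groups, rate_noise_sd=0.0,
                               diameter_noise_sd=0.0, seed=0)
        study = cs.simulate_tumor_cohort(spec)
        day = 20
        at = study.measurements[study.measurements["day"] == day]
        vols = at.groupby("group")["volume_mm3"].mean()
        expected = cs.dl_statistic(
            vols["pdt"] / vols["control"],
            vols["inhibitor"] / vols["control"],
            vols["combination"] / vols["control"],
        )
        res = cs.invivo_dl(study, endpoint_day=day)
        assert res.dl_mean == pytest.approx(expected, abs=1e-12)

    def test_missing_group_at_endpoint_named(self):
        _, study = _noiseless_study()
        keep = study.measurements["group"] != "pdt"
        broken = cs.TumorStudy(
            measurements=study.measurements[keep],
            survival=study.survival[study.survival["group"] != "pdt"],
        )
        with pytest.raises(AnalysisError, match="pdt"):
            cs.invivo_dl(broken, endpoint_day=20)


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        records = pd.DataFrame(
            {"animal_id": list("abcd"), "group": ["g"] * 4,
             "time_days": [90] * 4, "event": [0] * 4}
        )
        km = cs.km_estimate(records)
        assert km.survival_at(90) == 1.0
        assert km.percent_survival_at(90) == 100.0

    def test_no_censoring_equals_empirical_survival(self, km_oracle):
        times = [10, 20, 20, 35, 50, 70]
        records = pd.DataFrame(
            {"animal_id": [f"a{i}" for i in range(6)], "group": ["g"] * 6,
             "time_days": times, "event": [1] * 6}
        )
        km = cs.km_estimate(records)
        for t in [5, 10, 19, 20, 40, 70, 90]:
            empirical = np.mean(np.array(times) > t)
            assert km.survival_at(t) == pytest.approx(empirical, abs=1e-12)

    def test_matches_brute_force_product_limit_with_censoring(self, km_oracle):
        rng = np.random.default_rng(12)
        times = rng.integers(5, 90, size=10)
        events = rng.integers(0, 2, size=10)
        records = pd.DataFrame(
            {"animal_id": [f"a{i}" for i in range(10)], "group": ["g"] * 10,
             "time_days": times, "event": events}
        )
        km = cs.km_estimate(records)
        for t in sorted(set(times)) + [90]:
            assert km.survival_at(t) == pytest.approx(
                km_oracle(times, events, t), abs=1e-12
            )

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        records = pd.DataFrame(
            {"animal_id": [f"a{i}" for i in range(8)], "group": ["g"] * 8,
             "time_days": rng.integers(1, 91, size=8),
             "event": rng.integers(0, 2, size=8)}
        )
        km1 = cs.km_estimate(records)
        km2 = cs.km_estimate(records.sample(frac=1.0, random_state=9))
        pd.testing.assert_frame_equal(km1.table, km2.table)

    def test_nonpositive_times_rejected(self):
        records = pd.DataFrame(
            {"animal_id": ["a"], "group": ["g"], "time_days": [0], "event": [1]}
        )
        with pytest.raises((InvalidInputError, SchemaError)):
            cs.km_estimate(records)
        with pytest.raises((InvalidInputError, SchemaError)):
            cs.TumorStudy(
                measurements=pd.DataFrame(
                    {"animal_id": ["a"], "group": ["g"], "day": [0],
                     "d1_mm": [1.0], "d2_mm": [1.0], "d3_mm": [1.0]}
                ),
                survival=records,
            )
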