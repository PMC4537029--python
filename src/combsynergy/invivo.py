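"""Xenograft tumor growth, the in-vivo DL analog, and Kaplan-Meier survival.

Tumor size is measured as three orthogonal diameters d1, d2, d3 (mm) and
converted to an ellipsoid volume V = pi/6 * d1 * d2 * d3 (mm^3). Animals
are followed until their tumor reaches an ethical ceiling (default
2000 mm^3 = 2 cm^3, an event) or the study horizon (default 90 days,
censored).

The in-vivo synergy analog treats relative tumor burden as a survival
fraction: at a fixed endpoint day, each animal's volume is divided by the
concurrent control-group mean, the group-level SFs of the two monotherapies
enter the DL formula, and per-animal combination SFs supply the replicates
for the t-test (df = n_combination_animals - 1 unless overridden).

Kaplan-Meier estimation is the standard product-limit estimator
(via lifelines), with events processed before censorings at tied times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import AnalysisError, InvalidInputError, SchemaError
from .synergy import SynergyResult, dl_statistic, dl_test

__all__ = [
    "tumor_volume",
    "TumorStudy",
    "read_tumor_study",
    "growth_summary",
    "invivo_dl",
    "KMEstimate",
    "km_estimate",
]

TUMOR_COLUMNS = ("animal_id", "group", "day", "d1_mm", "d2_mm", "d3_mm")
SURVIVAL_COLUMNS = ("animal_id", "group", "time_days", "event")


def tumor_volume(d1: float, d2: float, d3: float) -> float:
    """Ellipsoid volume pi/6 * d1 * d2 * d3 from three orthogonal diameters
    in mm; symmetric in its arguments; result in mm^3."""
    if not (d1 > 0 and d2 > 0 and d3 > 0):
        raise InvalidInputError(
            f"diameters must all be > 0, got ({d1}, {d2}, {d3})"
        )
    return math.pi / 6.0 * d1 * d2 * d3


@dataclass
class TumorStudy:
    """Animal-level diameter time series plus survival records.

    ``measurements``: animal_id, group, day, d1_mm, d2_mm, d3_mm (+ derived
    volume_mm3). ``survival``: animal_id, group, time_days, event
    (1 = reached the ceiling, 0 = censored at the horizon).
    """

    measurements: pd.DataFrame = field(repr=False)
    survival: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in TUMOR_COLUMNS if c not in self.measurements.columns]
        if missing:
            raise SchemaError(f"tumor table missing column(s): {', '.join(missing)}")
        missing = [c for c in SURVIVAL_COLUMNS if c not in self.survival.columns]
        if missing:
            raise SchemaError(
                f"survival table missing column(s): {', '.join(missing)}"
            )
        m = self.measurements.copy()
        for c in ("d1_mm", "d2_mm", "d3_mm"):
            if (m[c] <= 0).any():
                row = m.index[m[c] <= 0][0]
                raise SchemaError(f"tumor table row {row}: column {c!r} must be > 0")
        if (m["day"] < 0).any():
            raise SchemaError("tumor table: day must be >= 0")
        m["volume_mm3"] = (
            np.pi / 6.0 * m["d1_mm"] * m["d2_mm"] * m["d3_mm"]
        )
        self.measurements = m.reset_index(drop=True)
        s = self.survival.copy()
        if (s["time_days"] <= 0).any():
            raise SchemaError("survival table: time_days must be > 0")
        if not s["event"].isin((0, 1)).all():
            raise SchemaError("survival table: event must be 0 or 1")
        self.survival = s.reset_index(drop=True)

    def groups(self) -> list[str]:
        return sorted(self.measurements["group"].unique())


def read_tumor_study(tumors_path: str | Path, survival_path: str | Path) -> TumorStudy:
    """Load a tumor-diameter CSV and a survival CSV into a TumorStudy."""
    return TumorStudy(
        measurements=pd.read_csv(tumors_path),
        survival=pd.read_csv(survival_path),
    )


def growth_summary(study: TumorStudy, days: list[int] | None = None) -> pd.DataFrame:
    """Per-group mean tumor volume +/- SE by measurement day.

    Animals are excluded from a day onward once they have had an event
    before that day (their survival record's time), so the summary tracks
    the animals still on study, with the per-cell n reported. SE is the
    sample SD / sqrt(n); it is missing (NaN) when n = 1.
    """
    m = study.measurements
    if days is not None:
        requested = set(days)
        for g in study.groups():
            have = set(m.loc[m["group"] == g, "day"].unique())
            absent = requested - have
            if absent:
                raise AnalysisError(
                    f"group {g!r}: no measurements at day(s) {sorted(absent)}"
                )
        m = m[m["day"].isin(days)]
    event_time = (
        study.survival.loc[study.survival["event"] == 1]
        .set_index("animal_id")["time_days"]
    )
    rows = []
    for (g, day), sub in m.groupby(["group", "day"], sort=True):
        cutoff = sub["animal_id"].map(event_time)
        alive = sub[cutoff.isna() | (sub["day"] <= cutoff)]
        n = len(alive)
        if n == 0:
            continue
        vols = alive["volume_mm3"].to_numpy()
        rows.append(
            {
                "group": g,
                "day": day,
                "n": n,
                "mean_volume_mm3": vols.mean(),
                "se_volume_mm3": (
                    vols.std(ddof=1) / math.sqrt(n) if n > 1 else math.nan
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["group", "day", "n", "mean_volume_mm3", "se_volume_mm3"]
    )


def invivo_dl(
    study: TumorStudy,
    endpoint_day: int | None = None,
    groups: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    df_override: int | None = None,
) -> SynergyResult:
    """DL synergy test on relative tumor burden at a fixed endpoint day.

    *groups* maps the roles ``control``, ``pdt``, ``inhibitor``,
    ``combination`` to group labels in the study (defaults to those literal
    labels). If *endpoint_day* is None, the last day at which all four
    groups were measured is used.

    SF analog per animal: volume at the endpoint day / mean control volume
    at that day. The monotherapy and control SFs enter as group means; the
    combination SF varies per animal, giving the DL replicates whose
    dispersion drives the t-test (df = n_combination - 1 by default).
    """
    groups = dict(groups or {})
    for role in ("control", "pdt", "inhibitor", "combination"):
        groups.setdefault(role, role)
    m = study.measurements

    def group_days(label: str) -> set:
        sub = m[m["group"] == label]
        if sub.empty:
            raise AnalysisError(f"group {label!r}: no tumor measurements")
        return set(sub["day"].unique())

    common = set.intersection(*(group_days(groups[r]) for r in groups))
    if endpoint_day is None:
        if not common:
            raise AnalysisError("no measurement day common to all four groups")
        endpoint_day = max(common)
    for role, label in groups.items():
        if endpoint_day not in group_days(label):
            raise AnalysisError(
                f"group {label!r} ({role}) has no measurement at day {endpoint_day}"
            )

    at_day = m[m["day"] == endpoint_day]

    def vols(label: str) -> np.ndarray:
        return at_day.loc[at_day["group"] == label, "volume_mm3"].to_numpy()

    control_mean = vols(groups["control"]).mean()
    sf_pdt = vols(groups["pdt"]).mean() / control_mean
    sf_inh = vols(groups["inhibitor"]).mean() / control_mean
    comb_sfs = vols(groups["combination"]) / control_mean
    dls = np.array([dl_statistic(sf_pdt, sf_inh, sf) for sf in comb_sfs])
    return dl_test(
        dls,
        df=df_override,
        alpha=alpha,
        label=f"{groups['combination']}@day{endpoint_day}",
    )


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate for one group."""

    group: str
    table: pd.DataFrame = field(repr=False)  # time, n_risk, n_event, n_censored, survival
    median_days: float  # inf when survival never falls below 0.5

    def survival_at(self, time: float) -> float:
        """S(t): the step-function value at *time* (right-continuous)."""
        t = self.table
        past = t[t["time"] <= time]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])

    def percent_survival_at(self, time: float) -> float:
        return 100.0 * self.survival_at(time)


def km_estimate(records: pd.DataFrame, group: str | None = None) -> KMEstimate:
    """Kaplan-Meier estimate from survival records
    (columns ``time_days``, ``event``; optionally filtered to *group*).

    S(0) = 1; the curve drops only at event times; censored animals leave
    the risk set without a drop (events precede censorings at tied times).
    """
    df = records
    if group is not None:
        df = df[df["group"] == group]
        if df.empty:
            raise AnalysisError(f"group {group!r}: no survival records")
    if df.empty:
        raise AnalysisError("no survival records")
    if (df["time_days"] <= 0).any():
        raise InvalidInputError("survival times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time_days"], event_observed=df["event"])
    ev = kmf.event_table.reset_index().rename(columns={"event_at": "time"})
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    table = pd.DataFrame(
        {
            "time": ev["time"].to_numpy(dtype=float),
            "n_risk": ev["at_risk"].to_numpy(dtype=int),
            "n_event": ev["observed"].to_numpy(dtype=int),
            "n_censored": ev["censored"].to_numpy(dtype=int),
            "survival": surv,
        }
    )
    median = float(kmf.median_survival_time_)
    return KMEstimate(
        group=group if group is not None else "",
        table=table,
        median_days=median,
    )
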