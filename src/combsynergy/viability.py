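"""Raw plate signals -> survival fractions and percent viability.

The luminescent (ATP) or fluorescent signal of a well is taken as
proportional to viable cell number. Within each independent experiment,
blank (medium-only) wells define the background, untreated-control wells
define 100% viability, and the survival fraction of an arm is the ratio of
background-corrected means:

    SF(condition, experiment) = mean(signal_condition) / mean(signal_control)

SFs are computed within each experiment and only then summarised across
experiments, so the number of independent experiments — not the number of
wells — sets the degrees of freedom used by the synergy t-test downstream.

The module also fits the linear fluorescent-cell dose curves used by
migration/invasion assays and inverts them from signal to cell number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assay import Design, MeasurementSet
from .errors import (
    AnalysisError,
    DegenerateFitError,
    InvalidInputError,
    UninterpretablePlateError,
)

__all__ = [
    "background_correct",
    "survival_fraction",
    "percent_viability",
    "StandardCurve",
    "InvertedQuantity",
    "fit_standard_curve",
    "invert_standard_curve",
]


def background_correct(measurements: MeasurementSet, design: Design) -> MeasurementSet:
    """Subtract the per-experiment mean blank signal from every well.

    Blank wells are removed from the output. Raises
    :class:`UninterpretablePlateError` if, after correction, any
    experiment's untreated-control mean is <= 0 (the plate cannot define
    SF = 1), and :class:`AnalysisError` if an experiment has no blank rows.
    """
    df = measurements.data.copy()
    blank_ids = set(design.ids_with_role("blank"))
    control_ids = set(design.ids_with_role("untreated_control"))
    corrected = []
    for exp, sub in df.groupby("experiment", sort=True):
        blanks = sub.loc[sub["condition_id"].isin(blank_ids), "signal"]
        if blanks.empty:
            raise AnalysisError(f"experiment {exp}: no blank wells to subtract")
        level = blanks.mean()
        out = sub.loc[~sub["condition_id"].isin(blank_ids)].copy()
        out["signal"] = out["signal"] - level
        ctrl = out.loc[out["condition_id"].isin(control_ids), "signal"]
        if not ctrl.empty and ctrl.mean() <= 0:
            raise UninterpretablePlateError(
                f"experiment {exp}: corrected untreated-control mean "
                f"{ctrl.mean():.3g} <= 0"
            )
        corrected.append(out)
    return MeasurementSet(pd.concat(corrected, ignore_index=True))


def survival_fraction(
    measurements: MeasurementSet,
    design: Design,
    sf_floor: float | None = None,
) -> pd.DataFrame:
    """Per-(condition, experiment) survival fractions from background-corrected
    signals.

    Returns a tidy frame with columns ``condition_id, experiment, sf``.
    The untreated control has sf = 1 in every experiment by construction.
    A nonpositive SF raises :class:`InvalidInputError` naming the condition
    unless *sf_floor* is given, in which case the SF is clamped to the floor
    (keeps the downstream log transform finite; a typical floor is 1e-4).
    """
    df = measurements.data
    control_ids = set(design.ids_with_role("untreated_control"))
    records = []
    for exp, sub in df.groupby("experiment", sort=True):
        ctrl = sub.loc[sub["condition_id"].isin(control_ids), "signal"]
        if ctrl.empty:
            raise AnalysisError(f"experiment {exp}: no untreated-control wells")
        denom = ctrl.mean()
        if denom <= 0:
            raise UninterpretablePlateError(
                f"experiment {exp}: untreated-control mean {denom:.3g} <= 0"
            )
        for cid, wells in sub.groupby("condition_id", sort=False):
            sf = wells["signal"].mean() / denom
            if cid in control_ids:
                sf = 1.0
            if sf <= 0:
                if sf_floor is None:
                    raise InvalidInputError(
                        f"condition {cid!r}, experiment {exp}: "
                        f"nonpositive survival fraction {sf:.3g} "
                        "(pass sf_floor to clamp)"
                    )
                sf = sf_floor
            elif sf_floor is not None:
                sf = max(sf, sf_floor)
            records.append(
                {"condition_id": cid, "experiment": int(exp), "sf": float(sf)}
            )
    return pd.DataFrame.from_records(
        records, columns=["condition_id", "experiment", "sf"]
    )


def percent_viability(sf_records: pd.DataFrame) -> pd.DataFrame:
    """Summarise SFs across experiments as percent viability vs control.

    mean% = 100 x mean(sf); SE% = 100 x sd(sf)/sqrt(n) with the sample SD
    (ddof=1) over independent experiments. Requires >= 2 experiments per
    condition.
    """
    rows = []
    for cid, sub in sf_records.groupby("condition_id", sort=False):
        sfs = sub["sf"].to_numpy(dtype=float)
        if len(sfs) < 2:
            raise AnalysisError(
                f"condition {cid!r}: percent_viability needs >= 2 experiments, "
                f"got {len(sfs)}"
            )
        rows.append(
            {
                "condition_id": cid,
                "n_experiments": len(sfs),
                "mean_pct": 100.0 * sfs.mean(),
                "se_pct": 100.0 * sfs.std(ddof=1) / np.sqrt(len(sfs)),
            }
        )
    return pd.DataFrame(rows, columns=["condition_id", "n_experiments", "mean_pct", "se_pct"])


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line through (known quantity, measured signal) points."""

    slope: float
    intercept: float
    r_squared: float
    x_min: float
    x_max: float

    def predict(self, quantity: float) -> float:
        return self.intercept + self.slope * quantity


class InvertedQuantity(NamedTuple):
    """Inverse prediction from a standard curve.

    ``extrapolated`` is True when the implied quantity falls outside the
    range of quantities the curve was fitted on; the value is still
    returned (flagged, not an error).
    """

    value: float
    extrapolated: bool


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of signal on known quantity.

    *points* is a sequence of ``(quantity, signal)`` pairs, e.g. plated cell
    number vs fluorescence. Requires >= 2 distinct quantities and a nonzero
    slope (otherwise the curve cannot be inverted)."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DegenerateFitError("need >= 2 (quantity, signal) points")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 2:
        raise DegenerateFitError("standard curve needs >= 2 distinct quantities")
    fit = stats.linregress(x, y)
    if fit.slope == 0:
        raise DegenerateFitError("zero-slope standard curve cannot be inverted")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def invert_standard_curve(curve: StandardCurve, signal: float) -> InvertedQuantity:
    """Map a measured signal back to a quantity: (signal - intercept) / slope."""
    value = (signal - curve.intercept) / curve.slope
    extrapolated = not (curve.x_min <= value <= curve.x_max)
    return InvertedQuantity(value=float(value), extrapolated=bool(extrapolated))
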