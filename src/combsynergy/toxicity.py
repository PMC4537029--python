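"""Serum toxicity-panel calculators: creatinine, urea nitrogen, AST/ALT.

Creatinine uses a two-read colorimetric kit: optical density is read 1 min
and 30 min after reagent addition, the standards' OD difference
(OD_30 - OD_1) is regressed on their known concentrations, and sample
concentrations are read off the regression line. Urea nitrogen is a
single endpoint read against endpoint standards, inverted the same way.

Aminotransferase (AST/ALT) activity comes from a kinetic two-timepoint
read: the pyruvate generated between the reads (B, nmol, from a pyruvate
standard curve) divided by the elapsed time and the sample volume,

    activity = B / ((T2 - T1) * V)   [nmol/min/ml = mU/ml]

Values are flagged against configurable normal ranges for mouse serum
(closed intervals, clinical convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import InvalidInputError
from .viability import StandardCurve, fit_standard_curve, invert_standard_curve

__all__ = [
    "NORMAL_RANGES",
    "KineticRead",
    "PanelResult",
    "enzyme_activity",
    "activity_from_read",
    "creatinine_concentration",
    "endpoint_concentration",
    "flag_ranges",
]

#: Normal ranges for mouse serum: analyte -> (low, high, units).
NORMAL_RANGES: dict[str, tuple[float, float, str]] = {
    "creatinine": (0.1, 2.1, "mg/dL"),
    "urea_nitrogen": (2.0, 71.0, "mg/dL"),
    "AST": (37.0, 329.0, "mU/ml"),
    "ALT": (7.0, 227.0, "mU/ml"),
}


@dataclass(frozen=True)
class KineticRead:
    """Two-timepoint kinetic read for one sample well."""

    od_t1: float
    od_t2: float
    t1_min: float
    t2_min: float
    sample_volume_ml: float
    pyruvate_nmol: float | None = None  # B, once resolved via the standard curve

    def __post_init__(self) -> None:
        if self.t2_min <= self.t1_min:
            raise InvalidInputError(
                f"t2 ({self.t2_min} min) must be after t1 ({self.t1_min} min)"
            )
        if self.sample_volume_ml <= 0:
            raise InvalidInputError("sample volume must be > 0 ml")


@dataclass(frozen=True)
class PanelResult:
    """One analyte's value flagged against its normal range."""

    analyte: str
    value: float
    units: str
    normal_low: float
    normal_high: float

    @property
    def in_range(self) -> bool:
        return self.normal_low <= self.value <= self.normal_high

    @property
    def flag(self) -> str:
        if self.value < self.normal_low:
            return "below"
        if self.value > self.normal_high:
            return "above"
        return "in_range"


def enzyme_activity(b_nmol: float, t1_min: float, t2_min: float, v_ml: float) -> float:
    """Kinetic activity B / ((T2 - T1) * V) in mU/ml (nmol/min/ml).

    *b_nmol* is the product generated between the reads, obtained from the
    pyruvate standard curve.
    """
    if t2_min <= t1_min:
        raise InvalidInputError(f"t2 ({t2_min}) must be after t1 ({t1_min})")
    if v_ml <= 0:
        raise InvalidInputError(f"sample volume must be > 0 ml, got {v_ml}")
    return b_nmol / ((t2_min - t1_min) * v_ml)


def activity_from_read(read: KineticRead, pyruvate_curve: StandardCurve) -> float:
    """Resolve B from the OD change via the pyruvate standard curve, then
    apply :func:`enzyme_activity`.

    Both reads are inverted through the curve and differenced, so the
    curve's intercept cancels: B = (OD_t2 - OD_t1) / slope.
    """
    b2 = invert_standard_curve(pyruvate_curve, read.od_t2).value
    b1 = invert_standard_curve(pyruvate_curve, read.od_t1).value
    b = b2 - b1
    return enzyme_activity(b, read.t1_min, read.t2_min, read.sample_volume_ml)


def creatinine_concentration(
    sample_od_1min: float,
    sample_od_30min: float,
    standards: Sequence[tuple[float, float, float]],
) -> float:
    """Creatinine (mg/dL) from the two-read protocol.

    *standards* holds ``(concentration mg/dL, od_1min, od_30min)`` for >= 2
    distinct concentrations. The standards' OD difference is regressed on
    concentration and the sample's OD difference is inverted through the
    fitted line.
    """
    points = [(conc, od30 - od1) for conc, od1, od30 in standards]
    curve = fit_standard_curve(points)
    delta = sample_od_30min - sample_od_1min
    return invert_standard_curve(curve, delta).value


def endpoint_concentration(
    sample_od: float, standards: Sequence[tuple[float, float]]
) -> float:
    """Concentration from a single endpoint read against ``(conc, od)``
    standards (used for the urea-nitrogen kit)."""
    curve = fit_standard_curve(list(standards))
    return invert_standard_curve(curve, sample_od).value


def flag_ranges(
    values: Mapping[str, float],
    ranges: Mapping[str, tuple[float, float, str]] | None = None,
) -> list[PanelResult]:
    """Flag measured analyte values against normal ranges.

    *values* maps analyte name -> value; *ranges* overrides
    :data:`NORMAL_RANGES`. Unknown analytes raise
    :class:`InvalidInputError`.
    """
    ranges = dict(NORMAL_RANGES if ranges is None else ranges)
    results = []
    for analyte, value in values.items():
        if analyte not in ranges:
            raise InvalidInputError(
                f"unrecognised analyte {analyte!r}; known: {sorted(ranges)}"
            )
        low, high, units = ranges[analyte]
        results.append(
            PanelResult(
                analyte=analyte,
                value=float(value),
                units=units,
                normal_low=low,
                normal_high=high,
            )
        )
    return results
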