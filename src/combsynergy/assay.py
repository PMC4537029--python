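"""Experimental-design and measurement-table model with CSV/TSV I/O.

An in-vitro experiment is described by two tidy tables:

* a **design** table — one row per treatment arm (``TreatmentCondition``):
  photosensitizer dose (µM), light dose (J/cm²), inhibitor name and dose
  (µg/ml), and a role that says how the arm is used downstream;
* a **measurements** table — one row per well
  (``condition_id, experiment, replicate, signal``), long format, as a
  plate reader exports it.

The design also encodes which arms compose each combination:
``match_triples`` pairs every combination arm with the PDT arm and the
inhibitor monotherapy arm carrying identical doses, the pairing the
Bliss-independence expectation SF_add = SF_PDT x SF_inhibitor needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DesignError, SchemaError

#: Roles an arm can play. ``blank`` wells contain medium only and are used
#: for background subtraction; ``untreated_control`` defines SF = 1.
ROLES = (
    "blank",
    "untreated_control",
    "light_only",
    "mono_ps",
    "mono_inhibitor",
    "pdt",
    "combination",
)

DESIGN_COLUMNS = (
    "condition_id",
    "role",
    "photosensitizer_dose",
    "light_dose",
    "inhibitor_name",
    "inhibitor_dose",
)
MEASUREMENT_COLUMNS = ("condition_id", "experiment", "replicate", "signal")


@dataclass(frozen=True)
class TreatmentCondition:
    """One experimental arm.

    Doses are categorical design labels (matched exactly, no tolerance):
    ``photosensitizer_dose`` in µM, ``light_dose`` in J/cm²,
    ``inhibitor_dose`` in µg/ml.
    """

    condition_id: str
    role: str
    photosensitizer_dose: float = 0.0
    light_dose: float = 0.0
    inhibitor_name: str | None = None
    inhibitor_dose: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DesignError(
                f"condition {self.condition_id!r}: unknown role {self.role!r}; "
                f"expected one of {ROLES}"
            )
        for name in ("photosensitizer_dose", "light_dose", "inhibitor_dose"):
            if getattr(self, name) < 0:
                raise DesignError(
                    f"condition {self.condition_id!r}: {name} must be >= 0"
                )
        if self.role == "blank" and (
            self.photosensitizer_dose or self.light_dose or self.inhibitor_dose
        ):
            raise DesignError(
                f"condition {self.condition_id!r}: blank wells must have all doses 0"
            )
        if self.role == "combination" and not (
            self.photosensitizer_dose > 0
            and self.light_dose > 0
            and self.inhibitor_dose > 0
        ):
            raise DesignError(
                f"condition {self.condition_id!r}: a combination arm needs "
                "photosensitizer, light and inhibitor doses all > 0"
            )
        if self.role in ("mono_inhibitor", "combination") and not self.inhibitor_name:
            raise DesignError(
                f"condition {self.condition_id!r}: role {self.role!r} requires "
                "an inhibitor_name"
            )


@dataclass(frozen=True)
class CombinationTriple:
    """Ids of a PDT arm, the matching inhibitor monotherapy arm, and the
    combination arm they compose."""

    pdt_id: str
    inhibitor_id: str
    combination_id: str


class Design:
    """An ordered, validated collection of :class:`TreatmentCondition`."""

    def __init__(self, conditions: Iterable[TreatmentCondition]):
        self._conditions: dict[str, TreatmentCondition] = {}
        for cond in conditions:
            if cond.condition_id in self._conditions:
                raise DesignError(f"duplicate condition_id {cond.condition_id!r}")
            self._conditions[cond.condition_id] = cond

    def __len__(self) -> int:
        return len(self._conditions)

    def __iter__(self):
        return iter(self._conditions.values())

    def __contains__(self, condition_id: str) -> bool:
        return condition_id in self._conditions

    def __getitem__(self, condition_id: str) -> TreatmentCondition:
        try:
            return self._conditions[condition_id]
        except KeyError:
            raise DesignError(f"unknown condition_id {condition_id!r}") from None

    def __eq__(self, other) -> bool:
        return isinstance(other, Design) and self._conditions == other._conditions

    def ids_with_role(self, role: str) -> list[str]:
        return [c.condition_id for c in self if c.role == role]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition_id": c.condition_id,
                    "role": c.role,
                    "photosensitizer_dose": c.photosensitizer_dose,
                    "light_dose": c.light_dose,
                    "inhibitor_name": c.inhibitor_name or "",
                    "inhibitor_dose": c.inhibitor_dose,
                }
                for c in self
            ],
            columns=list(DESIGN_COLUMNS),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Design":
        _require_columns(frame, DESIGN_COLUMNS, what="design")
        conditions = []
        for i, row in frame.iterrows():
            name = row["inhibitor_name"]
            if pd.isna(name) or name == "":
                name = None
            try:
                conditions.append(
                    TreatmentCondition(
                        condition_id=str(row["condition_id"]),
                        role=str(row["role"]),
                        photosensitizer_dose=float(row["photosensitizer_dose"]),
                        light_dose=float(row["light_dose"]),
                        inhibitor_name=name,
                        inhibitor_dose=float(row["inhibitor_dose"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"design row {i}: {exc}") from exc
        return cls(conditions)


@dataclass
class MeasurementSet:
    """Long table of raw well signals keyed by condition, experiment and
    replicate. ``data`` always carries the four schema columns; unknown
    columns in input files are preserved but ignored."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _require_columns(self.data, MEASUREMENT_COLUMNS, what="measurements")
        self.data = self.data.reset_index(drop=True)

    def validate(self, design: Design) -> "MeasurementSet":
        """Check referential integrity against *design*.

        Raises :class:`SchemaError` naming the offending row/column for a
        dangling condition_id, a negative signal, or an experiment with no
        untreated-control wells.
        """
        df = self.data
        for i, cid in df["condition_id"].items():
            if cid not in design:
                raise SchemaError(
                    f"measurements row {i}: condition_id {cid!r} not in design"
                )
        neg = df.index[df["signal"] < 0]
        if len(neg):
            raise SchemaError(
                f"measurements row {neg[0]}: column 'signal' is negative"
            )
        bad = df.index[(df["experiment"] < 1) | (df["replicate"] < 1)]
        if len(bad):
            raise SchemaError(
                f"measurements row {bad[0]}: experiment and replicate must be >= 1"
            )
        control_ids = set(design.ids_with_role("untreated_control"))
        for exp, sub in df.groupby("experiment"):
            if not sub["condition_id"].isin(control_ids).any():
                raise SchemaError(
                    f"experiment {exp}: no untreated_control rows "
                    "(column 'condition_id')"
                )
        return self

    def experiments(self) -> list[int]:
        return sorted(self.data["experiment"].unique())


def _require_columns(frame: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_design(path: str | Path) -> Design:
    """Read and validate a design CSV/TSV."""
    return Design.from_frame(_read_table(path))


def write_design(design: Design, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_measurements(path: str | Path, design: Design | None = None) -> MeasurementSet:
    """Read a measurements CSV/TSV; validate against *design* if given."""
    frame = _read_table(path)
    _require_columns(frame, MEASUREMENT_COLUMNS, what="measurements")
    frame = frame.copy()
    frame["condition_id"] = frame["condition_id"].astype(str)
    frame["experiment"] = frame["experiment"].astype(int)
    frame["replicate"] = frame["replicate"].astype(int)
    frame["signal"] = frame["signal"].astype(float)
    ms = MeasurementSet(frame)
    if design is not None:
        ms.validate(design)
    return ms


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis result table as CSV (period decimals, UTF-8)."""
    table.to_csv(path, index=False)


def match_triples(design: Design) -> list[CombinationTriple]:
    """Pair every combination arm with its PDT and inhibitor mono arms.

    Matching is exact on doses: the PDT arm must share the combination's
    photosensitizer and light doses, the mono-inhibitor arm its inhibitor
    name and dose. Two candidate mono arms with identical doses raise
    :class:`DesignError`; a combination with no match is reported with a
    warning and excluded.
    """
    pdt_arms = [design[i] for i in design.ids_with_role("pdt")]
    inh_arms = [design[i] for i in design.ids_with_role("mono_inhibitor")]
    triples: list[CombinationTriple] = []
    for comb_id in design.ids_with_role("combination"):
        comb = design[comb_id]
        pdt_matches = [
            a
            for a in pdt_arms
            if a.photosensitizer_dose == comb.photosensitizer_dose
            and a.light_dose == comb.light_dose
        ]
        inh_matches = [
            a
            for a in inh_arms
            if a.inhibitor_name == comb.inhibitor_name
            and a.inhibitor_dose == comb.inhibitor_dose
        ]
        if len(pdt_matches) > 1 or len(inh_matches) > 1:
            raise DesignError(
                f"combination {comb_id!r}: ambiguous mono-arm match "
                f"({len(pdt_matches)} PDT, {len(inh_matches)} inhibitor candidates)"
            )
        if not pdt_matches or not inh_matches:
            warnings.warn(
                f"combination {comb_id!r} has no matching "
                f"{'PDT' if not pdt_matches else 'inhibitor'} mono arm; skipped",
                stacklevel=2,
            )
            continue
        triples.append(
            CombinationTriple(
                pdt_id=pdt_matches[0].condition_id,
                inhibitor_id=inh_matches[0].condition_id,
                combination_id=comb_id,
            )
        )
    return triples


def grid_design(
    ps_doses: Iterable[float] = (50.0, 100.0),
    inhibitor_doses: Iterable[float] = (50.0, 100.0),
    inhibitor: str = "nimotuzumab",
    light_dose: float = 1.0,
) -> Design:
    """Build the standard factorial design used throughout the package:

    blank and untreated-control wells, a light-only arm, photosensitizer-only
    and inhibitor-only arms at each dose, PDT arms at each photosensitizer
    dose, and one combination arm per (PDT dose x inhibitor dose) cell.
    Defaults mirror a 2 x 2 grid of 50/100 µM photosensitizer against
    50/100 µg/ml inhibitor at 1 J/cm² light.
    """
    ps_doses = list(ps_doses)
    inhibitor_doses = list(inhibitor_doses)
    conds = [
        TreatmentCondition("blank", "blank"),
        TreatmentCondition("control", "untreated_control"),
        TreatmentCondition("light_only", "light_only", light_dose=light_dose),
    ]
    for d in ps_doses:
        conds.append(
            TreatmentCondition(f"ps_{d:g}", "mono_ps", photosensitizer_dose=d)
        )
        conds.append(
            TreatmentCondition(
                f"pdt_{d:g}", "pdt", photosensitizer_dose=d, light_dose=light_dose
            )
        )
    for d in inhibitor_doses:
        conds.append(
            TreatmentCondition(
                f"{inhibitor}_{d:g}",
                "mono_inhibitor",
                inhibitor_name=inhibitor,
                inhibitor_dose=d,
            )
        )
    for dp in ps_doses:
        for di in inhibitor_doses:
            conds.append(
                TreatmentCondition(
                    f"pdt_{dp:g}+{inhibitor}_{di:g}",
                    "combination",
                    photosensitizer_dose=dp,
                    light_dose=light_dose,
                    inhibitor_name=inhibitor,
                    inhibitor_dose=di,
                )
            )
    return Design(conds)
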