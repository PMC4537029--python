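"""The difference-in-logarithms (DL) synergy statistic.

Under Bliss independence two treatments acting by distinct mechanisms
combine multiplicatively on the survival-fraction scale:

    SF_add = SF_PDT x SF_inhibitor

The observed combination survival SF_comb is compared with this expectation
on the log scale:

    DL = log10(SF_PDT) + log10(SF_inhibitor) - log10(SF_comb)
       = log10(SF_add / SF_comb)

DL > 0 means the combination killed more cells than independence predicts
(synergy), DL < 0 less (antagonism), DL = 0 exact additivity. One DL is
computed per independent experiment — the arms of an experiment are paired,
so plate-level effects cancel — and the DLs are tested against zero with a
two-sided one-sample t-test. The classification gate is significance first:
p < alpha and DL > 0 -> synergistic; p < alpha and DL < 0 -> antagonistic;
otherwise additive.

Base-10 logarithms are used for reporting; the t statistic, p-value and
call are invariant to the base since a base change rescales the DL mean and
its SE identically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assay import CombinationTriple, Design, match_triples
from .errors import AnalysisError, InvalidInputError

__all__ = [
    "SynergyResult",
    "dl_statistic",
    "dl_replicates",
    "dl_test",
    "synergy_table",
    "classify",
]

CALLS = ("synergistic", "additive", "antagonistic")


@dataclass(frozen=True)
class SynergyResult:
    """Outcome of the DL t-test for one combination."""

    label: str
    dl_mean: float  # log10 units
    dl_se: float  # log10 units
    df: int
    t_statistic: float
    p_value: float
    call: str
    alpha: float = 0.05
    n: int | None = None  # number of DL replicates, when known

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidInputError(f"p_value {self.p_value} outside [0, 1]")
        if self.call not in CALLS:
            raise InvalidInputError(f"unknown call {self.call!r}")


def dl_statistic(sf_pdt: float, sf_mono: float, sf_comb: float) -> float:
    """DL = log10(sf_pdt) + log10(sf_mono) - log10(sf_comb).

    All three survival fractions must be > 0 (clamp upstream with an SF
    floor if a plate produced nonpositive corrected signals).
    """
    for name, sf in (("sf_pdt", sf_pdt), ("sf_mono", sf_mono), ("sf_comb", sf_comb)):
        if not sf > 0:
            raise InvalidInputError(f"{name} must be > 0, got {sf}")
    return math.log10(sf_pdt) + math.log10(sf_mono) - math.log10(sf_comb)


def classify(dl_mean: float, p_value: float, alpha: float = 0.05) -> str:
    """Significance gate first, then the sign of DL; ties at p == alpha are
    conservative (additive)."""
    if p_value < alpha:
        if dl_mean > 0:
            return "synergistic"
        if dl_mean < 0:
            return "antagonistic"
    return "additive"


def dl_replicates(
    triple: CombinationTriple, sf_records: pd.DataFrame
) -> np.ndarray:
    """One DL per experiment in which all three arms of *triple* are present.

    Experiments are matched by their index; an experiment missing any arm is
    dropped with a warning. Fewer than 2 complete experiments raise
    :class:`AnalysisError` (no standard error is estimable).
    """
    wide = sf_records.pivot_table(
        index="experiment", columns="condition_id", values="sf"
    )
    needed = [triple.pdt_id, triple.inhibitor_id, triple.combination_id]
    missing_cols = [c for c in needed if c not in wide.columns]
    if missing_cols:
        raise AnalysisError(
            f"triple {triple.combination_id!r}: no SF records at all for "
            f"{missing_cols}"
        )
    sub = wide[needed]
    complete = sub.dropna()
    dropped = sorted(set(sub.index) - set(complete.index))
    if dropped:
        warnings.warn(
            f"triple {triple.combination_id!r}: experiments {dropped} missing "
            "an arm; dropped",
            stacklevel=2,
        )
    if len(complete) < 2:
        raise AnalysisError(
            f"triple {triple.combination_id!r}: only {len(complete)} complete "
            "experiment(s); >= 2 required for a standard error"
        )
    return np.array(
        [
            dl_statistic(row[triple.pdt_id], row[triple.inhibitor_id],
                         row[triple.combination_id])
            for _, row in complete.iterrows()
        ]
    )


def dl_test(
    dls: Sequence[float] | np.ndarray | None = None,
    *,
    dl_mean: float | None = None,
    dl_se: float | None = None,
    df: int | None = None,
    alpha: float = 0.05,
    label: str = "",
) -> SynergyResult:
    """Two-sided one-sample t-test of DL against zero.

    Either pass the vector of per-experiment DLs (``dl_se = sd/sqrt(n)``,
    ``df = n - 1`` unless overridden), or pass summary statistics
    ``dl_mean``/``dl_se``/``df`` directly — the latter lets published
    summary rows be re-tested as printed.

    Degenerate SE: ``dl_se == 0`` with a nonzero mean yields p = 0 with a
    warning (infinitely concentrated replicates); with a zero mean,
    p = 1 / additive.
    """
    if not 0 < alpha < 1:
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha}")
    n: int | None = None
    if dls is not None:
        arr = np.asarray(dls, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise AnalysisError(
                f"need >= 2 DL replicates for a t-test, got {arr.size}"
            )
        n = int(arr.size)
        dl_mean = float(arr.mean())
        dl_se = float(arr.std(ddof=1) / math.sqrt(n))
        if df is None:
            df = n - 1
    else:
        if dl_mean is None or dl_se is None or df is None:
            raise InvalidInputError(
                "summary-mode dl_test needs dl_mean, dl_se and df"
            )
    if df < 1:
        raise InvalidInputError(f"df must be >= 1, got {df}")
    if dl_se < 0:
        raise InvalidInputError(f"dl_se must be >= 0, got {dl_se}")

    # Degenerate dispersion: replicates numerically identical. A mean
    # within float round-off of zero is exact additivity, not infinite
    # evidence, hence the 1e-12 absolute tolerance.
    if dl_se <= 1e-15:
        if abs(dl_mean) <= 1e-12:
            t_stat, p = 0.0, 1.0
        else:
            warnings.warn(
                "zero standard error with nonzero DL mean; p set to 0",
                stacklevel=2,
            )
            t_stat = math.inf if dl_mean > 0 else -math.inf
            p = 0.0
    else:
        t_stat = dl_mean / dl_se
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return SynergyResult(
        label=label,
        dl_mean=float(dl_mean),
        dl_se=float(dl_se),
        df=int(df),
        t_statistic=float(t_stat),
        p_value=p,
        call=classify(dl_mean, p, alpha),
        alpha=alpha,
        n=n,
    )


def synergy_table(
    design: Design,
    sf_records: pd.DataFrame,
    alpha: float = 0.05,
    df_override: int | None = None,
    group: str = "",
) -> pd.DataFrame:
    """One DL t-test row per matched combination triple.

    Columns mirror a published synergy summary: group, treatment, dl, se,
    df, t, p, call. An empty design (no combinations) yields an empty frame.
    """
    rows = []
    for triple in match_triples(design):
        dls = dl_replicates(triple, sf_records)
        res = dl_test(
            dls, df=df_override, alpha=alpha, label=triple.combination_id
        )
        rows.append(
            {
                "group": group,
                "treatment": triple.combination_id,
                "dl": res.dl_mean,
                "se": res.dl_se,
                "df": res.df,
                "t": res.t_statistic,
                "p": res.p_value,
                "call": res.call,
            }
        )
    return pd.DataFrame(
        rows, columns=["group", "treatment", "dl", "se", "df", "t", "p", "call"]
    )
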