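"""Published DL summary rows shipped with the package.

A prior chlorin-e6 PDT + EGFR-inhibitor study reported, for each cell line
and dose combination (and one xenograft cohort), the mean DL, its standard
error, the t-test p-value and the synergy call. Those printed summaries
are bundled here so they can be re-tested through :func:`~combsynergy.
synergy.dl_test` in summary mode.

Values printed as a bound ("< 0.0001") are parsed into a numeric column
holding the bound with a companion ``*_is_bound`` flag. The HUVEC rows
print an SE column identical to the p column (a typesetting defect in the
source table); their SEs should not be trusted for recomputation.

Replicate counts/degrees of freedom were not printed. The in-vitro rows
for the OSCC, SCC-25 and HUVEC lines are numerically consistent with
df = 5, the HSC-3 and xenograft rows with df = 4;
:func:`degrees_of_freedom` encodes that mapping.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reported_synergy_rows", "degrees_of_freedom"]

_DF_BY_GROUP = {
    "OSCC": 5,
    "SCC-25": 5,
    "HUVEC": 5,
    "HSC-3": 4,
    "in vivo OSCC": 4,
}


def _parse_bounded(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    is_bound = series.str.startswith("<")
    values = series.str.lstrip("<").astype(float)
    return values, is_bound


def load_reported_synergy_rows() -> pd.DataFrame:
    """The 17 published summary rows as a DataFrame.

    Columns: group, treatment, dl, se, se_is_bound, p, p_is_bound, call, df.
    """
    with resources.files("combsynergy.data").joinpath(
        "reported_synergy_rows.csv"
    ).open() as fh:
        raw = pd.read_csv(fh, dtype=str)
    out = pd.DataFrame(
        {"group": raw["group"], "treatment": raw["treatment"],
         "dl": raw["dl"].astype(float)}
    )
    out["se"], out["se_is_bound"] = _parse_bounded(raw["se"])
    out["p"], out["p_is_bound"] = _parse_bounded(raw["p"])
    out["call"] = raw["call"].str.lower()
    out["df"] = out["group"].map(_DF_BY_GROUP).astype(int)
    return out


def degrees_of_freedom(group: str) -> int:
    """df consistent with the printed t-test p-values for *group*."""
    return _DF_BY_GROUP[group]
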