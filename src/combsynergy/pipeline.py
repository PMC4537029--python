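"""End-to-end orchestration: simulate -> viability -> synergy -> in vivo ->
toxicity, with a run manifest for provenance.

Each stage is independently callable from the library; this module chains
them with one :class:`RunConfig`, writes every stage's table under a run
directory, and records the config, seed and library versions in
``manifest.json`` so any output can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .assay import write_design, write_results
from .errors import InvalidInputError
from .invivo import growth_summary, invivo_dl, km_estimate
from .simulate import (
    TumorSimSpec,
    ToxicitySimSpec,
    ViabilitySimSpec,
    simulate_toxicity_panel,
    simulate_tumor_cohort,
    simulate_viability_experiment,
)
from .synergy import synergy_table
from .toxicity import (
    activity_from_read,
    creatinine_concentration,
    endpoint_concentration,
    flag_ranges,
)
from .viability import (
    background_correct,
    fit_standard_curve,
    percent_viability,
    survival_fraction,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Tunables of a full synthetic-data run."""

    out_dir: str = "combsynergy_run"
    seed: int = 0
    alpha: float = 0.05
    sf_floor: float | None = None
    df_override: int | None = None
    endpoint_day: int | None = 32
    noise_sd_log: float = 0.05
    n_experiments: int = 3
    replicates_per_experiment: int = 3
    log_base_label: str = "log10"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidInputError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.endpoint_day is not None and self.endpoint_day <= 0:
            raise InvalidInputError("endpoint_day must be > 0")
        if self.seed is not None and not 0 <= int(self.seed) < 2**31:
            raise InvalidInputError("seed must be in [0, 2**31)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidInputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _manifest(config: RunConfig, outputs: list[str]) -> dict:
    return {
        "config": dataclasses.asdict(config),
        "outputs": outputs,
        "versions": {
            "combsynergy": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on freshly simulated data and write the bundle.

    Returns a dict of the in-memory stage results; files are written under
    ``config.out_dir``. Deterministic given config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)

    # --- in vitro ---------------------------------------------------------
    vspec = ViabilitySimSpec(
        n_experiments=config.n_experiments,
        replicates_per_experiment=config.replicates_per_experiment,
        noise_sd_log=config.noise_sd_log,
        seed=seed,
    )
    design, raw = simulate_viability_experiment(vspec)
    corrected = background_correct(raw, design)
    sf = survival_fraction(corrected, design, sf_floor=config.sf_floor)
    viability_pct = percent_viability(sf)
    syn = synergy_table(
        design, sf, alpha=config.alpha, df_override=config.df_override
    )

    # --- in vivo ----------------------------------------------------------
    tspec = TumorSimSpec(seed=seed + 1)
    study = simulate_tumor_cohort(tspec)
    growth = growth_summary(study)
    invivo_result = invivo_dl(
        study, endpoint_day=config.endpoint_day, alpha=config.alpha
    )
    km_tables = []
    km_summary = []
    for group in study.groups():
        km = km_estimate(study.survival, group=group)
        t = km.table.copy()
        t.insert(0, "group", group)
        km_tables.append(t)
        km_summary.append(
            {
                "group": group,
                "percent_survival_at_horizon": km.percent_survival_at(
                    tspec.horizon_days
                ),
                "median_survival_days": km.median_days,
            }
        )
    km_curves = pd.concat(km_tables, ignore_index=True)
    km_summary = pd.DataFrame(km_summary)

    # --- toxicity ---------------------------------------------------------
    xspec = ToxicitySimSpec(seed=seed + 2)
    panel_data = simulate_toxicity_panel(xspec)
    pyr_curve = fit_standard_curve(panel_data["pyruvate_standards"])
    panel_rows = []
    for i, (od1, od30) in enumerate(panel_data["creatinine_samples"], 1):
        value = creatinine_concentration(
            od1, od30, panel_data["creatinine_standards"]
        )
        panel_rows.append(("creatinine", f"sample_{i}", value))
    for i, od in enumerate(panel_data["urea_samples"], 1):
        value = endpoint_concentration(od, panel_data["urea_standards"])
        panel_rows.append(("urea_nitrogen", f"sample_{i}", value))
    for i, read in enumerate(panel_data["kinetic_reads"], 1):
        panel_rows.append(("AST", f"sample_{i}", activity_from_read(read, pyr_curve)))
    flagged = []
    for analyte, sample, value in panel_rows:
        (res,) = flag_ranges({analyte: value})
        flagged.append(
            {
                "analyte": analyte,
                "sample": sample,
                "value": value,
                "units": res.units,
                "normal_low": res.normal_low,
                "normal_high": res.normal_high,
                "flag": res.flag,
            }
        )
    panel = pd.DataFrame(flagged)

    # --- write bundle -----------------------------------------------------
    invivo_row = pd.DataFrame(
        [
            {
                "group": "combination",
                "endpoint_day": config.endpoint_day,
                "dl": invivo_result.dl_mean,
                "se": invivo_result.dl_se,
                "df": invivo_result.df,
                "t": invivo_result.t_statistic,
                "p": invivo_result.p_value,
                "call": invivo_result.call,
            }
        ]
    )
    tables = {
        "design.csv": design.to_frame(),
        "measurements_raw.csv": raw.data,
        "survival_fractions.csv": sf,
        "percent_viability.csv": viability_pct,
        "synergy_table.csv": syn,
        "tumor_measurements.csv": study.measurements,
        "tumor_survival.csv": study.survival,
        "growth_summary.csv": growth,
        "invivo_synergy.csv": invivo_row,
        "km_curves.csv": km_curves,
        "km_summary.csv": km_summary,
        "toxicity_panel.csv": panel,
    }
    for name, frame in tables.items():
        write_results(frame, out / name)
    write_design(design, out / "design.csv")
    manifest = _manifest(config, sorted(tables))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "design": design,
        "survival_fractions": sf,
        "percent_viability": viability_pct,
        "synergy_table": syn,
        "tumor_study": study,
        "growth_summary": growth,
        "invivo_synergy": invivo_result,
        "km_summary": km_summary,
        "toxicity_panel": panel,
        "manifest": manifest,
    }
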