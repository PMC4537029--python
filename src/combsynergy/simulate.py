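"""Synthetic assays with known ground truth.

Every downstream stage of the package can be exercised without the
original study data: this module simulates

* **viability plates** — a factorial PDT x inhibitor design whose treated
  arms have known true survival fractions and whose combinations have a
  known true DL. Noise is Gaussian on log10 SF (multiplicative on the SF
  scale, so simulated SFs stay positive and match the log-scale statistic),
  drawn once per arm per independent experiment; optional additive read
  noise perturbs individual wells.
* **xenograft cohorts** — exponential tumor growth V(t) = V0 * exp(r*m*t)
  with a per-group rate multiplier m, per-animal lognormal rate
  heterogeneity, measurement-day diameter jitter, an event when the volume
  reaches the ethical ceiling on a measurement day, and censoring at the
  study horizon. Bliss additivity on relative volume corresponds to
  m_comb = m_pdt + m_inhibitor - 1 (:func:`additive_multiplier`); pushing
  m_comb below that value builds in true in-vivo synergy.
* **toxicity kinetics** — linear standard curves with additive read noise
  for the creatinine/urea endpoint assays and the pyruvate curve behind
  the AST/ALT kinetic reads.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import Design, MeasurementSet, grid_design, match_triples
from .errors import InvalidInputError
from .invivo import TumorStudy
from .toxicity import KineticRead

__all__ = [
    "simulate_combination_sf",
    "ViabilitySimSpec",
    "simulate_viability_experiment",
    "sample_dl_replicates",
    "TumorGroupSpec",
    "TumorSimSpec",
    "additive_multiplier",
    "simulate_tumor_cohort",
    "ToxicitySimSpec",
    "simulate_toxicity_panel",
]


def simulate_combination_sf(sf_a: float, sf_b: float, true_dl: float) -> float:
    """Combination SF that realises a chosen DL: sf_a * sf_b * 10**(-true_dl).

    Inverts the DL definition, so a noiseless pipeline recovers *true_dl*
    exactly. true_dl = 0 gives the Bliss-additive product.
    """
    if not (sf_a > 0 and sf_b > 0):
        raise InvalidInputError(
            f"mono survival fractions must be > 0, got ({sf_a}, {sf_b})"
        )
    return sf_a * sf_b * 10.0 ** (-true_dl)


# ---------------------------------------------------------------------------
# Viability plates
# ---------------------------------------------------------------------------

def _default_true_sf() -> dict[str, float]:
    # Typical magnitudes for a chlorin-e6 PDT grid: strong PDT kill,
    # mild photosensitizer-only / light-only / antibody-only effects.
    return {
        "light_only": 0.75,
        "ps_50": 0.92,
        "ps_100": 0.88,
        "pdt_50": 0.25,
        "pdt_100": 0.22,
        "nimotuzumab_50": 0.85,
        "nimotuzumab_100": 0.80,
    }


def _default_true_dl() -> dict[str, float]:
    return {
        "pdt_50+nimotuzumab_50": 0.3,
        "pdt_50+nimotuzumab_100": 0.3,
        "pdt_100+nimotuzumab_50": 0.3,
        "pdt_100+nimotuzumab_100": 0.3,
    }


@dataclass
class ViabilitySimSpec:
    """Ground truth and noise model for a simulated viability assay.

    ``true_sf`` maps every treated (non-control, non-combination) arm of
    *design* to its true survival fraction in (0, 1]; ``true_dl`` maps each
    combination arm to its true DL in log10 units. ``noise_sd_log`` is the
    SD of the Gaussian noise applied to log10 SF per arm per experiment;
    ``read_noise_sd`` (RLU) perturbs individual wells additively and
    defaults to 0 so the noiseless round-trip is exact by default.
    """

    true_sf: Mapping[str, float] = field(default_factory=_default_true_sf)
    true_dl: Mapping[str, float] = field(default_factory=_default_true_dl)
    design: Design = field(default_factory=grid_design)
    n_experiments: int = 3
    replicates_per_experiment: int = 3
    noise_sd_log: float = 0.05
    control_signal_mean: float = 1.0e6
    blank_signal_mean: float = 500.0
    read_noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_experiments < 2:
            raise InvalidInputError("n_experiments must be >= 2")
        if self.replicates_per_experiment < 1:
            raise InvalidInputError("replicates_per_experiment must be >= 1")
        if self.noise_sd_log < 0 or self.read_noise_sd < 0:
            raise InvalidInputError("noise SDs must be >= 0")
        if self.blank_signal_mean >= self.control_signal_mean:
            raise InvalidInputError("control signal must exceed blank signal")
        for cid, sf in self.true_sf.items():
            if not (0 < sf <= 1):
                raise InvalidInputError(
                    f"true_sf[{cid!r}] = {sf} outside (0, 1]"
                )
        for cid in self.true_sf:
            if cid not in self.design:
                raise InvalidInputError(f"true_sf names unknown arm {cid!r}")
        comb_ids = set(self.design.ids_with_role("combination"))
        for cid in self.true_dl:
            if cid not in comb_ids:
                raise InvalidInputError(
                    f"true_dl names non-combination arm {cid!r}"
                )
        missing = comb_ids - set(self.true_dl)
        if missing:
            raise InvalidInputError(
                f"true_dl missing combination arm(s): {sorted(missing)}"
            )


def simulate_viability_experiment(
    spec: ViabilitySimSpec,
) -> tuple[Design, MeasurementSet]:
    """Simulate raw plate signals for *spec*'s design.

    Per experiment e and treated arm c, the realized SF is
    ``true_sf_c * 10**eps`` with ``eps ~ N(0, noise_sd_log)`` (combination
    arms derive their true SF from their mono arms and true DL via
    :func:`simulate_combination_sf`, with their own independent eps).
    Raw well signal = blank + SF * (control - blank), plus optional
    additive read noise per well. Untreated controls realise SF = 1,
    blanks SF = 0.
    """
    rng = np.random.default_rng(spec.seed)
    design = spec.design
    triples = match_triples(design)
    true_sf = dict(spec.true_sf)
    for t in triples:
        true_sf[t.combination_id] = simulate_combination_sf(
            true_sf[t.pdt_id], true_sf[t.inhibitor_id], spec.true_dl[t.combination_id]
        )
    span = spec.control_signal_mean - spec.blank_signal_mean

    rows = []
    for exp in range(1, spec.n_experiments + 1):
        for cond in design:
            cid = cond.condition_id
            if cond.role == "blank":
                sf = 0.0
            elif cond.role == "untreated_control":
                sf = 1.0
            else:
                eps = rng.normal(0.0, spec.noise_sd_log) if spec.noise_sd_log else 0.0
                sf = true_sf[cid] * 10.0 ** eps
            level = spec.blank_signal_mean + sf * span
            for rep in range(1, spec.replicates_per_experiment + 1):
                signal = level
                if spec.read_noise_sd:
                    signal += rng.normal(0.0, spec.read_noise_sd)
                rows.append(
                    {
                        "condition_id": cid,
                        "experiment": exp,
                        "replicate": rep,
                        "signal": max(signal, 0.0),
                    }
                )
    ms = MeasurementSet(pd.DataFrame(rows)).validate(design)
    return design, ms


def sample_dl_replicates(
    true_dl: float,
    noise_sd_log: float,
    n_experiments: int = 3,
    n_datasets: int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorised per-experiment DL draws, shape (n_datasets, n_experiments).

    Equivalent to running :func:`simulate_viability_experiment` (zero read
    noise) through the full SF -> DL pipeline for one triple: each of the
    three arms contributes independent N(0, noise_sd_log) noise on log10 SF,
    so DL_e = true_dl + eps_pdt + eps_mono - eps_comb, i.e.
    DL_e ~ N(true_dl, noise_sd_log * sqrt(3)).
    """
    if n_experiments < 2:
        raise InvalidInputError("n_experiments must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    eps = rng.normal(0.0, noise_sd_log, size=(3, n_datasets, n_experiments))
    return true_dl + eps[0] + eps[1] - eps[2]


# ---------------------------------------------------------------------------
# Xenograft cohorts
# ---------------------------------------------------------------------------

def additive_multiplier(m_a: float, m_b: float) -> float:
    """Rate multiplier under Bliss additivity of the two mono effects.

    Relative volume vs control after time t is exp(r*t*(m-1)), so log SFs
    add exactly when (m_comb - 1) = (m_a - 1) + (m_b - 1).
    """
    return m_a + m_b - 1.0


@dataclass(frozen=True)
class TumorGroupSpec:
    """One treatment group of a simulated cohort."""

    n_animals: int = 10
    initial_volume_mm3: float = 200.0
    multiplier: float = 1.0  # scales the cohort growth rate


def _default_groups() -> dict[str, TumorGroupSpec]:
    # Control crosses the 2000 mm^3 ceiling around day 32; monotherapies
    # delay it; the combination is suppressed beyond the additive null
    # (additive would be 0.62 + 0.68 - 1 = 0.30).
    return {
        "control": TumorGroupSpec(multiplier=1.0),
        "pdt": TumorGroupSpec(multiplier=0.62),
        "inhibitor": TumorGroupSpec(multiplier=0.68),
        "combination": TumorGroupSpec(multiplier=0.18),
    }


@dataclass
class TumorSimSpec:
    """Ground truth for a simulated xenograft study.

    ``growth_rate`` is the control-group exponential rate per day (natural
    log scale); group multipliers scale it. ``rate_noise_sd`` is the SD of
    per-animal lognormal rate heterogeneity; ``diameter_noise_sd`` (mm)
    jitters each measured diameter. Animals are measured on
    ``measurement_days`` until their volume first reaches
    ``ceiling_volume_mm3`` (event) and are censored at ``horizon_days``.
    """

    groups: Mapping[str, TumorGroupSpec] = field(default_factory=_default_groups)
    growth_rate: float = np.log(10.0) / 32.0  # control: 200 -> 2000 mm^3 in 32 d
    measurement_days: Sequence[int] = tuple(range(0, 91, 2))
    rate_noise_sd: float = 0.15
    diameter_noise_sd: float = 0.3
    ceiling_volume_mm3: float = 2000.0
    horizon_days: int = 90
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.horizon_days <= 0:
            raise InvalidInputError("horizon_days must be > 0")
        if self.rate_noise_sd < 0 or self.diameter_noise_sd < 0:
            raise InvalidInputError("noise SDs must be >= 0")
        for name, g in self.groups.items():
            if g.n_animals < 1:
                raise InvalidInputError(f"group {name!r}: n_animals must be >= 1")
            if self.ceiling_volume_mm3 <= g.initial_volume_mm3:
                raise InvalidInputError(
                    f"group {name!r}: ceiling must exceed the initial volume"
                )
        if not self.measurement_days:
            raise InvalidInputError("measurement_days must be nonempty")
        if min(self.measurement_days) < 0:
            raise InvalidInputError("measurement_days must be >= 0")


def simulate_tumor_cohort(spec: TumorSimSpec) -> TumorStudy:
    """Simulate diameters and survival records for every group of *spec*.

    Per animal i in group g: V_i(t) = V0 * exp(r * m_g * h_i * t) with
    h_i = exp(N(0, rate_noise_sd)). On each measurement day the target
    volume is converted to an equilateral diameter d = (6V/pi)^(1/3),
    each of the three recorded diameters is jittered independently, and the
    recorded (jittered) volume decides the ceiling event. Measurements stop
    at the event day; animals alive past the horizon are censored there.
    """
    rng = np.random.default_rng(spec.seed)
    days = sorted(d for d in spec.measurement_days if d <= spec.horizon_days)
    meas_rows, surv_rows = [], []
    for gname, g in spec.groups.items():
        for i in range(1, g.n_animals + 1):
            aid = f"{gname}_{i:02d}"
            h = np.exp(rng.normal(0.0, spec.rate_noise_sd)) if spec.rate_noise_sd else 1.0
            rate = spec.growth_rate * g.multiplier * h
            event_time: int | None = None
            for day in days:
                vol = g.initial_volume_mm3 * np.exp(rate * day)
                d_eq = (6.0 * vol / np.pi) ** (1.0 / 3.0)
                d1, d2, d3 = (
                    max(d_eq + rng.normal(0.0, spec.diameter_noise_sd), 0.1)
                    if spec.diameter_noise_sd
                    else d_eq
                    for _ in range(3)
                )
                meas_rows.append(
                    {
                        "animal_id": aid,
                        "group": gname,
                        "day": day,
                        "d1_mm": d1,
                        "d2_mm": d2,
                        "d3_mm": d3,
                    }
                )
                recorded_vol = np.pi / 6.0 * d1 * d2 * d3
                if recorded_vol >= spec.ceiling_volume_mm3 and day > 0:
                    event_time = day
                    break
            if event_time is not None:
                surv_rows.append(
                    {"animal_id": aid, "group": gname, "time_days": event_time,
                     "event": 1}
                )
            else:
                surv_rows.append(
                    {"animal_id": aid, "group": gname,
                     "time_days": spec.horizon_days, "event": 0}
                )
    return TumorStudy(
        measurements=pd.DataFrame(meas_rows),
        survival=pd.DataFrame(surv_rows),
    )


# ---------------------------------------------------------------------------
# Toxicity kinetics
# ---------------------------------------------------------------------------

@dataclass
class ToxicitySimSpec:
    """Ground truth for the serum panel simulators.

    Standard curves are linear with additive Gaussian OD read noise.
    Creatinine follows the two-read protocol (OD difference regressed on
    concentration); AST/ALT reads realise a chosen true activity through
    the pyruvate curve.
    """

    true_creatinine_mg_dl: Sequence[float] = (0.5, 0.7, 0.9)
    creatinine_standards_mg_dl: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    creatinine_slope_od_per_mg_dl: float = 0.03
    creatinine_intercept_od: float = 0.01
    true_urea_mg_dl: Sequence[float] = (12.0, 12.8, 13.5)
    urea_standards_mg_dl: Sequence[float] = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
    urea_slope_od_per_mg_dl: float = 0.008
    urea_intercept_od: float = 0.05
    true_activity_mu_ml: Sequence[float] = (50.0, 48.0, 17.0)
    pyruvate_standards_nmol: Sequence[float] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    pyruvate_slope_od_per_nmol: float = 0.05
    pyruvate_intercept_od: float = 0.02
    t1_min: float = 10.0
    t2_min: float = 60.0
    sample_volume_ml: float = 0.005
    read_noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.t2_min <= self.t1_min:
            raise InvalidInputError("t2_min must exceed t1_min")
        if self.sample_volume_ml <= 0:
            raise InvalidInputError("sample_volume_ml must be > 0")
        if self.read_noise_sd < 0:
            raise InvalidInputError("read_noise_sd must be >= 0")


def simulate_toxicity_panel(spec: ToxicitySimSpec) -> dict:
    """Simulate standards and sample reads for the whole serum panel.

    Returns a dict with keys ``creatinine_standards`` (conc, od_1min,
    od_30min), ``creatinine_samples`` (od_1min, od_30min),
    ``urea_standards`` (conc, od), ``urea_samples`` (od),
    ``pyruvate_standards`` (nmol, od) and ``kinetic_reads``
    (:class:`~combsynergy.toxicity.KineticRead` per sample).
    """
    rng = np.random.default_rng(spec.seed)

    def noisy(x: float) -> float:
        return x + (rng.normal(0.0, spec.read_noise_sd) if spec.read_noise_sd else 0.0)

    # Creatinine: the information is in OD_30 - OD_1; give OD_1 a flat level.
    cre_standards = [
        (
            c,
            noisy(0.1),
            noisy(0.1 + spec.creatinine_intercept_od
                  + spec.creatinine_slope_od_per_mg_dl * c),
        )
        for c in spec.creatinine_standards_mg_dl
    ]
    cre_samples = [
        (
            noisy(0.1),
            noisy(0.1 + spec.creatinine_intercept_od
                  + spec.creatinine_slope_od_per_mg_dl * c),
        )
        for c in spec.true_creatinine_mg_dl
    ]
    urea_standards = [
        (c, noisy(spec.urea_intercept_od + spec.urea_slope_od_per_mg_dl * c))
        for c in spec.urea_standards_mg_dl
    ]
    urea_samples = [
        noisy(spec.urea_intercept_od + spec.urea_slope_od_per_mg_dl * c)
        for c in spec.true_urea_mg_dl
    ]
    pyr_standards = [
        (b, noisy(spec.pyruvate_intercept_od + spec.pyruvate_slope_od_per_nmol * b))
        for b in spec.pyruvate_standards_nmol
    ]
    dt = spec.t2_min - spec.t1_min
    reads = []
    for act in spec.true_activity_mu_ml:
        b = act * dt * spec.sample_volume_ml  # nmol generated between reads
        od1 = noisy(spec.pyruvate_intercept_od)
        od2 = noisy(spec.pyruvate_intercept_od
                    + spec.pyruvate_slope_od_per_nmol * b)
        reads.append(
            KineticRead(
                od_t1=od1,
                od_t2=od2,
                t1_min=spec.t1_min,
                t2_min=spec.t2_min,
                sample_volume_ml=spec.sample_volume_ml,
            )
        )
    return {
        "creatinine_standards": cre_standards,
        "creatinine_samples": cre_samples,
        "urea_standards": urea_standards,
        "urea_samples": urea_samples,
        "pyruvate_standards": pyr_standards,
        "kinetic_reads": reads,
    }
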