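"""Virtual renal-transplant cohorts with the study's sampling design.

The generator emulates the clinical design the model was built on: 51 early
post-transplant and 48 stable subjects on twice-daily oral MMF, sampled over
one dosing interval at day 4 (7 doses given, the 7th starting the sampled
interval) at the nominal times 0, 0.5, 1, 1.5, 2, 3, 4, 6, 8 and 12 h
post-dose.  Individual parameters are drawn with lognormal inter-individual
variability, observations carry proportional residual error, and values
below the assay's quantification limit are flagged.

Demographic covariates (age, weight, albumin, creatinine clearance, serum
creatinine) are drawn from stage-specific normal distributions matching the
study cohort but have no effect on the generated kinetics — they exist so
covariate selection can be null-tested against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import Dataset, Observation, SubjectRecord
from .model_core import (
    DoseEvent,
    PopulationModel,
    apply_covariates,
    conc_profile,
    individual_params,
)

__all__ = ["CohortDesign", "generate_cohort", "censor_blq"]

#: stage -> (mean, sd) of demographic covariates, truncated to [lo, hi]
_DEMOGRAPHICS = {
    "AGE": ((33.39, 8.10), (42.29, 9.25), (18.0, 80.0)),
    "WEIGHT": ((64.02, 10.45), (65.31, 10.54), (35.0, 120.0)),
    "ALBUMIN": ((41.94, 4.95), (46.07, 2.24), (25.0, 60.0)),
    "CRCL": ((62.55, 20.75), (74.51, 19.29), (10.0, 160.0)),
    "SCR": ((147.76, 73.75), (105.27, 22.62), (40.0, 600.0)),
}


@dataclass(frozen=True)
class CohortDesign:
    """Study design knobs: cohort sizes, sampling grid, dosing, censoring.

    ``daily_dose_mg`` holds the per-stage mean +/- sd of the total daily MMF
    dose; per-administration doses are half the (truncated-normal) draw,
    rounded to the 250 mg menu and clipped to the stage's clinical range
    (early 500-1500 mg, stable 250-750 mg per dose).
    """

    n_early: int = 51
    n_stable: int = 48
    sampling_times: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0)
    daily_dose_mg: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {0: (1690.0, 440.0), 1: (1090.0, 290.0)}
    )
    dose_menu_mg: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {0: (500.0, 1500.0), 1: (250.0, 750.0)}
    )
    interval: float = 12.0
    n_doses: int = 7  # doses administered before/at the sampled interval (day 4)
    lloq: float = 0.04
    time_jitter: float = 0.0  # optional relative jitter on sampling times

    def __post_init__(self) -> None:
        times = self.sampling_times
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sampling times must be sorted and unique")
        if self.n_early < 0 or self.n_stable < 0 or self.n_early + self.n_stable < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.lloq <= 0:
            raise ValueError("LLOQ must be > 0")


def _draw_dose(rng: np.random.Generator, design: CohortDesign, stage: int) -> float:
    mean, sd = design.daily_dose_mg[stage]
    lo, hi = design.dose_menu_mg[stage]
    daily = rng.normal(mean, sd)
    while not (2 * lo <= daily <= 2 * hi):
        daily = rng.normal(mean, sd)
    return float(np.clip(np.round(daily / 2.0 / 250.0) * 250.0, lo, hi))


def generate_cohort(
    model: PopulationModel,
    design: CohortDesign | None = None,
    seed: int | None = 0,
) -> Dataset:
    """Simulate a cohort from ``model`` under ``design``; reproducible by seed."""
    design = design or CohortDesign()
    rng = np.random.default_rng(seed)
    omega2 = model.omega2_array()
    sigma = model.sigma_prop

    subjects = []
    stages = [0] * design.n_early + [1] * design.n_stable
    interval_start = (design.n_doses - 1) * design.interval
    for i, stage in enumerate(stages):
        dose = _draw_dose(rng, design, stage)
        covariates = {"STAGE": float(stage)}
        for name, (early, stable, (lo, hi)) in _DEMOGRAPHICS.items():
            mean, sd = (early, stable)[stage]
            value = rng.normal(mean, sd)
            while not (lo <= value <= hi):
                value = rng.normal(mean, sd)
            covariates[name] = round(float(value), 2)

        eta = rng.normal(0.0, 1.0, size=6) * np.sqrt(omega2)
        typ = apply_covariates(model, covariates)
        params = individual_params(typ, eta)

        doses = tuple(
            DoseEvent(k * design.interval, dose) for k in range(design.n_doses)
        )
        offsets = np.asarray(design.sampling_times, dtype=float)
        if design.time_jitter > 0:
            jitter = 1.0 + rng.uniform(-design.time_jitter, design.time_jitter, offsets.size)
            offsets = np.sort(np.abs(offsets * jitter))
        times = interval_start + offsets
        pred = conc_profile(params, doses, times)
        eps = rng.normal(0.0, sigma, size=times.size)
        dv = pred * (1.0 + eps)
        dv = np.maximum(dv, 0.0)  # negative simulated values truncated, then flagged
        blq = dv < design.lloq
        observations = tuple(
            Observation(float(t), float(c), bool(b)) for t, c, b in zip(times, dv, blq)
        )
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                stage=stage,
                doses=doses,
                observations=observations,
                covariates=covariates,
            )
        )
    return Dataset(subjects=tuple(subjects), lloq=design.lloq)


def censor_blq(dataset: Dataset, lloq: float | None = None, rule: str = "flag-only") -> Dataset:
    """Apply a below-quantification rule uniformly to every observation.

    rule: 'flag-only' marks values < LLOQ; 'discard' removes them;
    'half-lloq' replaces them with LLOQ/2 (flag kept).
    """
    if rule not in ("discard", "half-lloq", "flag-only"):
        raise ValueError(f"unknown BLQ rule {rule!r}")
    lloq = dataset.lloq if lloq is None else lloq
    if lloq <= 0:
        raise ValueError("LLOQ must be > 0")
    subjects = []
    for s in dataset.subjects:
        new_obs = []
        for o in s.observations:
            below = o.dv < lloq
            if below and rule == "discard":
                continue
            if below and rule == "half-lloq":
                new_obs.append(replace(o, dv=lloq / 2.0, blq=True))
            else:
                new_obs.append(replace(o, blq=bool(below)))
        subjects.append(replace(s, observations=tuple(new_obs)))
    return Dataset(subjects=tuple(subjects), lloq=lloq)
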