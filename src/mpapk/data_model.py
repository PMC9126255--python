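"""Event-level dataset representation and NONMEM-style CSV I/O.

A :class:`Dataset` holds one :class:`SubjectRecord` per subject; each record
carries the dosing events, the timed concentration observations (with a
below-quantification flag) and the subject-level covariates, post-transplant
stage included.  Every downstream module consumes these objects — nothing
else in the package re-parses files.

The on-disk dialect is a NONMEM-style event CSV with columns
``ID, TIME, AMT, DV, EVID, BLQ, STAGE`` plus any number of extra numeric
covariate columns (age, weight, albumin, ...).  ``EVID=1`` rows are doses
(AMT > 0), ``EVID=0`` rows are observations.  ``MDV`` is inferred, never
required.  Times are decimal hours since the subject's first dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import DoseEvent, Regimen, expand_regimen_times

__all__ = [
    "Observation",
    "ObservationRecord",
    "SubjectRecord",
    "Dataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "expand_regimen",
]

RESERVED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "BLQ", "STAGE")


class DatasetError(ValueError):
    """Raised for malformed event files or records (carries row context)."""


@dataclass(frozen=True)
class Observation:
    """A timed concentration observation (mg/L) with a BLQ flag."""

    time: float
    dv: float
    blq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DatasetError(f"observation time must be >= 0, got {self.time}")
        if not self.blq and self.dv < 0:
            raise DatasetError(f"concentration must be >= 0, got {self.dv}")


@dataclass(frozen=True)
class ObservationRecord:
    """A single event row as it appears in the event file."""

    subject_id: str
    time: float
    event_type: str  # "dose" | "observation"
    amount: float = 0.0
    dv: float = float("nan")
    blq: bool = False


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: stage, regimen summary, covariates, events."""

    subject_id: str
    stage: int
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in (0, 1):
            raise DatasetError(f"subject {self.subject_id}: stage must be 0 or 1")
        if not self.doses:
            raise DatasetError(f"subject {self.subject_id}: no dose events")
        dose_times = [d.time for d in self.doses]
        obs_times = [o.time for o in self.observations]
        if sorted(dose_times) != dose_times or sorted(obs_times) != obs_times:
            raise DatasetError(f"subject {self.subject_id}: events must be time-sorted")
        if self.observations and min(obs_times) < min(dose_times):
            raise DatasetError(
                f"subject {self.subject_id}: first observation precedes first dose"
            )

    @property
    def dose_amount(self) -> float:
        """Dose per administration (mg), assuming a fixed repeated dose."""
        return self.doses[0].amount

    @property
    def last_dose_time(self) -> float:
        return self.doses[-1].time

    def observation_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.array([o.time for o in self.observations])
        dv = np.array([o.dv for o in self.observations])
        blq = np.array([o.blq for o in self.observations], dtype=bool)
        return t, dv, blq


@dataclass(frozen=True)
class Dataset:
    """A cohort of subjects plus the assay's lower limit of quantification."""

    subjects: tuple[SubjectRecord, ...]
    lloq: float = 0.04

    def __post_init__(self) -> None:
        if self.lloq <= 0:
            raise DatasetError(f"LLOQ must be > 0, got {self.lloq}")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DatasetError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def by_stage(self, stage: int) -> "Dataset":
        return replace(self, subjects=tuple(s for s in self.subjects if s.stage == stage))

    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)


def expand_regimen(regimen: Regimen) -> list[DoseEvent]:
    """Dose events at 0, interval, ..., (n-1)*interval with the stated amount."""
    return [DoseEvent(float(t), regimen.dose) for t in expand_regimen_times(regimen)]


def _row_error(index: int, message: str) -> DatasetError:
    return DatasetError(f"row {index}: {message}")


def read_dataset(path: str | Path, lloq: float = 0.04) -> Dataset:
    """Read a NONMEM-style event CSV into a validated :class:`Dataset`.

    Raises :class:`DatasetError` with the offending row number for missing
    columns, negative or unsorted times, unknown EVID codes, dose rows
    without AMT, or observation rows without DV.
    """
    frame = pd.read_csv(path)
    missing = [c for c in ("ID", "TIME", "AMT", "DV", "EVID", "STAGE") if c not in frame.columns]
    if missing:
        raise DatasetError(f"missing required columns: {', '.join(missing)}")
    covariate_cols = [c for c in frame.columns if c not in RESERVED_COLUMNS]
    has_blq = "BLQ" in frame.columns

    subjects: list[SubjectRecord] = []
    for subject_id, group in frame.groupby("ID", sort=False):
        doses: list[DoseEvent] = []
        observations: list[Observation] = []
        last_time = -np.inf
        for index, row in group.iterrows():
            time = float(row["TIME"])
            if time < 0:
                raise _row_error(index, f"negative TIME {time}")
            if time < last_time:
                raise _row_error(index, f"TIME {time} not sorted within subject {subject_id}")
            last_time = time
            evid = int(row["EVID"])
            if evid == 1:
                amt = float(row["AMT"])
                if not amt > 0:
                    raise _row_error(index, f"dose row needs AMT > 0, got {row['AMT']!r}")
                doses.append(DoseEvent(time, amt))
            elif evid == 0:
                blq = bool(row["BLQ"]) if has_blq else False
                dv = float(row["DV"])
                if np.isnan(dv) and not blq:
                    raise _row_error(index, "observation row needs DV or BLQ flag")
                observations.append(Observation(time, 0.0 if np.isnan(dv) else dv, blq))
            else:
                raise _row_error(index, f"unknown EVID {evid} (expected 0 or 1)")
        stage_values = group["STAGE"].unique()
        if len(stage_values) != 1:
            raise DatasetError(f"subject {subject_id}: STAGE must be constant")
        covariates = {c: float(group[c].iloc[0]) for c in covariate_cols}
        covariates["STAGE"] = float(stage_values[0])
        subjects.append(
            SubjectRecord(
                subject_id=str(subject_id),
                stage=int(stage_values[0]),
                doses=tuple(doses),
                observations=tuple(observations),
                covariates=covariates,
            )
        )
    return Dataset(subjects=tuple(subjects), lloq=lloq)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset back to the NONMEM-style CSV dialect read by
    :func:`read_dataset` (round-trips field-for-field)."""
    rows = []
    covariate_cols = sorted(
        {name for s in dataset.subjects for name in s.covariates} - {"STAGE"}
    )
    for subject in dataset.subjects:
        events: list[tuple[float, int, dict]] = []
        for dose in subject.doses:
            events.append((dose.time, 1, {"AMT": dose.amount, "DV": np.nan, "BLQ": 0}))
        for obs in subject.observations:
            events.append((obs.time, 0, {"AMT": 0.0, "DV": obs.dv, "BLQ": int(obs.blq)}))
        # doses sort before observations at equal times
        events.sort(key=lambda e: (e[0], -e[1]))
        for time, evid, extra in events:
            row = {
                "ID": subject.subject_id,
                "TIME": time,
                "EVID": evid,
                "STAGE": subject.stage,
                **extra,
            }
            for c in covariate_cols:
                row[c] = subject.covariates.get(c, np.nan)
            rows.append(row)
    columns = ["ID", "TIME", "AMT", "DV", "EVID", "BLQ", "STAGE", *covariate_cols]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
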