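"""Non-compartmental exposure metrics for one steady-state dosing interval.

AUC uses the linear trapezoidal rule with linear interpolation; the terminal
slope (lambda_z) is a least-squares fit of log concentration against time
over the last monotone-decreasing positive observations.  Apparent clearance
is dose / AUC_ss,12h and the apparent volume CL_F / lambda_z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Dataset, SubjectRecord

__all__ = ["NCAResult", "trapezoid_auc", "terminal_slope", "nca_summary", "nca_table"]


class NCAError(ValueError):
    pass


@dataclass(frozen=True)
class NCAResult:
    """Per-subject non-compartmental summary over one dosing interval.

    ``tmax`` is relative to the start of the sampled interval;
    ``tmax_absolute`` is hours since the subject's first dose.
    Dose-normalised AUC is expressed per gram of MMF.
    """

    subject_id: str
    stage: int
    dose_mg: float
    auc_ss_12h: float
    cmax: float
    cmin: float
    tmax: float
    tmax_absolute: float
    lambda_z: float  # NaN when inestimable
    t_half: float  # NaN when inestimable
    cl_f: float
    vd_f: float
    auc_per_gram: float


def trapezoid_auc(times, concs) -> float:
    """Linear-trapezoid AUC; interior NaNs filled by linear interpolation."""
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if times.size < 2:
        raise NCAError("AUC needs at least 2 points")
    if np.any(np.diff(times) <= 0):
        raise NCAError("times must be strictly increasing")
    if np.any(concs[np.isfinite(concs)] < 0):
        raise NCAError("concentrations must be >= 0")
    missing = ~np.isfinite(concs)
    if missing.any():
        if missing[0] or missing[-1]:
            raise NCAError("cannot interpolate missing endpoint concentrations")
        concs = concs.copy()
        concs[missing] = np.interp(times[missing], times[~missing], concs[~missing])
    return float(np.trapezoid(concs, times))


def terminal_slope(times, concs, n_points: int = 3) -> tuple[float, float]:
    """(lambda_z, t_half) from the last ``n_points`` terminal observations.

    Flagged inestimable (NaN, NaN) — not an exception — when the terminal
    phase has non-positive or non-decreasing concentrations.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if n_points < 2:
        raise NCAError("terminal fit needs >= 2 points")
    t = times[-n_points:]
    c = concs[-n_points:]
    if t.size < 2 or np.any(c <= 0) or np.any(np.diff(c) >= 0):
        return float("nan"), float("nan")
    slope, _ = np.polyfit(t, np.log(c), 1)
    if slope >= 0:
        return float("nan"), float("nan")
    lambda_z = -float(slope)
    return lambda_z, math.log(2.0) / lambda_z


def nca_summary(subject: SubjectRecord, lambda_z_points: int = 3) -> NCAResult:
    """Non-compartmental summary of a subject's steady-state interval profile.

    Cmax/Tmax are the observed maximum; Cmin is the pre-dose (trough)
    observation; CL/F = dose / AUC; Vd/F = CL_F / lambda_z.
    """
    if not subject.observations:
        raise NCAError(f"subject {subject.subject_id}: no observations")
    t_abs, dv, _ = subject.observation_arrays()
    if t_abs.size < 2:
        raise NCAError(f"subject {subject.subject_id}: need >= 2 observations")
    start = subject.last_dose_time
    t = t_abs - start
    if np.any(t < -1e-9):
        raise NCAError(
            f"subject {subject.subject_id}: observations precede the final dose"
        )
    auc = trapezoid_auc(t, dv)
    imax = int(np.argmax(dv))
    lambda_z, t_half = terminal_slope(t, dv, lambda_z_points)
    dose = subject.dose_amount
    cl_f = dose / auc if auc > 0 else float("nan")
    vd_f = cl_f / lambda_z if lambda_z and np.isfinite(lambda_z) else float("nan")
    return NCAResult(
        subject_id=subject.subject_id,
        stage=subject.stage,
        dose_mg=dose,
        auc_ss_12h=auc,
        cmax=float(dv[imax]),
        cmin=float(dv[0]),
        tmax=float(t[imax]),
        tmax_absolute=float(t_abs[imax]),
        lambda_z=lambda_z,
        t_half=t_half,
        cl_f=cl_f,
        vd_f=vd_f,
        auc_per_gram=auc / (dose / 1000.0),
    )


def nca_table(dataset: Dataset, lambda_z_points: int = 3) -> pd.DataFrame:
    """Per-subject NCA results for a whole cohort as a DataFrame."""
    rows = [vars(nca_summary(s, lambda_z_points)) for s in dataset.subjects]
    return pd.DataFrame(rows)
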