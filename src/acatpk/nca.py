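"""Noncompartmental summary of simulated concentration profiles.

Cmax/Tmax, linear trapezoidal AUC on the dense grid, terminal slope λz by
log-linear regression, AUC extrapolation to infinity and the accumulation
index R = 1/(1 − e^(−k·τ)). Concentrations in mg/L are numerically equal
to µg/mL, so AUC values come out directly in µg·h/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .absorption import AbsorptionResult
from .disposition import ConcentrationProfile
from .params import DrugParameters, SubjectParameters, ValidationError

__all__ = [
    "PKSummary",
    "cmax_tmax",
    "auc_trapezoid",
    "terminal_lambda_z",
    "auc_infinity",
    "accumulation_index",
    "summarize_regimen",
]


@dataclass(frozen=True)
class PKSummary:
    """One row of a regimen comparison table.

    fa/fdp/f are percentages of total administered dose; cmax mg/L; tmax h;
    AUCs in µg·h/mL; lambda_z 1/h. ``extrapolated_fraction`` is the share
    of AUC0-inf contributed by the tail beyond the simulated horizon.
    """

    label: str
    route: str
    dose: float
    n_doses: int
    interval: float
    fa: float
    fdp: float
    f: float
    cmax: float
    tmax: float
    auc_0_t: float
    auc_0_inf: float
    lambda_z: float
    accumulation_index: float
    extrapolated_fraction: float

    def __post_init__(self) -> None:
        if self.auc_0_inf + 1e-12 < self.auc_0_t:
            raise ValidationError("auc_0_inf must be >= auc_0_t")
        if self.cmax < 0:
            raise ValidationError("cmax must be >= 0")

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "label": self.label,
                "route": self.route,
                "dose_mg": self.dose,
                "n_doses": self.n_doses,
                "interval_h": self.interval,
                "fa_percent": self.fa,
                "fdp_percent": self.fdp,
                "f_percent": self.f,
                "cmax_mg_per_L": self.cmax,
                "tmax_h": self.tmax,
                "auc_0_inf_ug_h_per_mL": self.auc_0_inf,
                "auc_0_t_ug_h_per_mL": self.auc_0_t,
                "lambda_z_per_h": self.lambda_z,
                "accumulation_index": self.accumulation_index,
                "extrapolated_fraction": self.extrapolated_fraction,
            }
        )


def cmax_tmax(profile: ConcentrationProfile) -> tuple[float, float]:
    """Global maximum concentration and its time; earliest time on ties."""
    c = profile.central_conc
    if c.size == 0:
        raise ValidationError("empty profile")
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(profile.times[i])


def auc_trapezoid(profile: ConcentrationProfile, t_end: float | None = None) -> float:
    """Linear trapezoidal AUC from 0 to ``t_end`` (default: full grid)."""
    t = profile.times
    if t_end is None:
        t_end = float(t[-1])
    if t_end > t[-1] + 1e-9:
        raise ValidationError(f"t_end {t_end} beyond the simulated grid ({t[-1]} h)")
    mask = t <= t_end + 1e-9
    return float(np.trapezoid(profile.central_conc[mask], t[mask]))


def terminal_lambda_z(profile: ConcentrationProfile, window: float = 2.0) -> float:
    """Terminal elimination rate constant, 1/h.

    −slope of a log-linear OLS fit over the last ``window`` hours of the
    grid. The window must be an input-free tail: it may not contain a
    dosing time (for oral profiles the lumen must also have stopped
    delivering drug, which is the caller's responsibility) and all
    concentrations in it must be positive.
    """
    t = profile.times
    t_lo = t[-1] - window
    mask = t >= t_lo - 1e-9
    if mask.sum() < 3:
        raise ValidationError("terminal window must contain at least 3 points")
    for td in profile.dosing_times:
        if td > t_lo + 1e-9:
            raise ValidationError(
                f"dose at {td} h falls inside the terminal window (> {t_lo:.2f} h)"
            )
    c = profile.central_conc[mask]
    if np.any(c <= 0):
        raise ValidationError("non-positive concentration in the terminal window")
    fit = linregress(t[mask], np.log(c))
    return float(-fit.slope)


def auc_infinity(
    profile: ConcentrationProfile, lambda_z: float | None = None, window: float = 2.0
) -> float:
    """AUC0-inf = AUC0-t_last + C_last/λz, µg·h/mL.

    ``lambda_z`` may be supplied (e.g. the model elimination constant when
    the terminal phase is not input-free); otherwise it is estimated from
    the last ``window`` hours.
    """
    if lambda_z is None:
        lambda_z = terminal_lambda_z(profile, window)
    if lambda_z <= 0:
        raise ValidationError(f"lambda_z must be > 0, got {lambda_z}")
    return auc_trapezoid(profile) + float(profile.central_conc[-1]) / lambda_z


def accumulation_index(k: float, tau: float) -> float:
    """Steady-state to single-dose exposure ratio R = 1/(1 − e^(−k·τ))."""
    if k <= 0 or tau <= 0:
        raise ValidationError("k and tau must be > 0")
    return 1.0 / (1.0 - math.exp(-k * tau))


def summarize_regimen(
    profile: ConcentrationProfile,
    drug: DrugParameters,
    subject: SubjectParameters,
    absorption: AbsorptionResult | None = None,
    *,
    label: str = "",
    dose: float | None = None,
    n_doses: int | None = None,
    interval: float | None = None,
    lambda_z_window: float = 2.0,
) -> PKSummary:
    """Assemble a full regimen summary row.

    For IV runs (``absorption is None``) fa = fdp = f = 100% and λz is
    measured from the flux-free terminal window. For oral runs the
    bioavailability fractions come from the lumen model and the tail is
    extrapolated with the model elimination constant CL/V, because colonic
    absorption can still be feeding the plasma at the end of the horizon
    and a measured tail slope would reflect that flux, not elimination.
    """
    k_model = drug.elimination_rate(subject.body_mass)
    cmax, tmax = cmax_tmax(profile)
    auc_t = auc_trapezoid(profile)
    n_doses = n_doses if n_doses is not None else len(profile.dosing_times)
    if interval is None:
        dt = profile.dosing_times
        interval = float(dt[1] - dt[0]) if len(dt) > 1 else float(profile.duration)
    if absorption is None:
        fa = fdp = f = 100.0
        lz = terminal_lambda_z(profile, lambda_z_window)
    else:
        fa, fdp, f = (
            100.0 * absorption.fa,
            100.0 * absorption.fdp,
            100.0 * absorption.f,
        )
        lz = k_model
    auc_inf = auc_infinity(profile, lambda_z=lz)
    tail = float(profile.central_conc[-1]) / lz
    r_acc = accumulation_index(k_model, interval) if n_doses > 1 else 1.0
    return PKSummary(
        label=label,
        route=profile.route,
        dose=float(dose) if dose is not None else float("nan"),
        n_doses=n_doses,
        interval=interval,
        fa=fa,
        fdp=fdp,
        f=f,
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        lambda_z=lz,
        accumulation_index=r_acc,
        extrapolated_fraction=tail / auc_inf if auc_inf > 0 else 0.0,
    )
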