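"""One-compartment systemic disposition with IV-infusion and oral inputs.

The central compartment follows dA/dt = input(t) − (CL/V)·A with
V = vc_per_kg · body mass; plasma concentration is Cp = A/V (mg/L).
IV infusions enter at a constant rate dose/duration during each infusion
window; oral doses enter as the portal flux computed by the lumen model
(:mod:`acatpk.absorption`), integrated jointly so that doses co-mingle in
the lumen. Multiple doses are handled by restarting the solver at each
dosing time with a state-continuous jump (no profile superposition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .absorption import AbsorptionResult, SolverOptions, simulate_gi_transit
from .params import (
    DoseRegimen,
    DrugParameters,
    GIPhysiology,
    SubjectParameters,
    ValidationError,
    validate_regimen,
)

__all__ = [
    "ConcentrationProfile",
    "analytic_infusion_conc",
    "simulate_iv_infusion",
    "simulate_oral_regimen",
]


@dataclass(frozen=True)
class ConcentrationProfile:
    """Central-compartment concentration on a dense uniform time grid."""

    times: np.ndarray  # h
    central_conc: np.ndarray  # mg/L (≡ µg/mL)
    dosing_times: tuple[float, ...]
    route: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.central_conc, dtype=float)
        if t.ndim != 1 or t.size < 2 or c.shape != t.shape:
            raise ValidationError("times and central_conc must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(c < -1e-9 * max(c.max(initial=0.0), 1.0)):
            raise ValidationError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "central_conc", np.maximum(c, 0.0))

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "conc_mg_per_L": self.central_conc})

    def plot(self, ax=None, **kwargs):
        """Plot Cp(t); creates an axis if none is given."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.central_conc, **kwargs)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("plasma concentration (mg/L)")
        return ax


def analytic_infusion_conc(
    t: np.ndarray | float, dose: float, duration: float, cl: float, v: float
) -> np.ndarray | float:
    """Closed-form one-compartment concentration for a single infusion.

    During the infusion (0 ≤ t ≤ T): C = (R0/CL)·(1 − e^(−k·t)) with
    R0 = dose/T and k = CL/V; afterwards C decays as C(T)·e^(−k·(t−T)).
    Used as the independent oracle for the numerical route.
    """
    for name, val in (("dose", dose), ("duration", duration), ("cl", cl), ("v", v)):
        if val <= 0:
            raise ValidationError(f"{name} must be > 0")
    t_arr = np.asarray(t, dtype=float)
    k = cl / v
    r0 = dose / duration
    c_end = (r0 / cl) * (1.0 - np.exp(-k * duration))
    c = np.where(
        t_arr <= duration,
        (r0 / cl) * (1.0 - np.exp(-k * np.maximum(t_arr, 0.0))),
        c_end * np.exp(-k * (t_arr - duration)),
    )
    c = np.where(t_arr < 0.0, 0.0, c)
    return c if np.ndim(t) else float(c)


def _grid(sim_duration: float, step: float) -> np.ndarray:
    n = int(round(sim_duration / step))
    return np.linspace(0.0, sim_duration, n + 1)


def simulate_iv_infusion(
    drug: DrugParameters,
    subject: SubjectParameters,
    regimen: DoseRegimen,
    *,
    solver: SolverOptions | None = None,
) -> ConcentrationProfile:
    """Numerically integrate repeated constant-rate infusions.

    The ODE is solved piecewise between infusion on/off switch points at
    tight tolerances; the analytic solution remains available as an
    independent check (:func:`analytic_infusion_conc`).
    """
    validate_regimen(regimen)
    if regimen.route != "iv_infusion":
        raise ValidationError("simulate_iv_infusion requires an iv_infusion regimen")
    solver = solver or SolverOptions()
    v = drug.volume_of_distribution(subject.body_mass)
    k = drug.clearance / v
    r0 = regimen.dose / regimen.infusion_duration

    switch = {0.0, regimen.sim_duration}
    for t0 in regimen.dosing_times:
        switch.add(t0)
        switch.add(min(t0 + regimen.infusion_duration, regimen.sim_duration))
    bounds = sorted(switch)

    def rate(t: float) -> float:
        r = 0.0
        for t0 in regimen.dosing_times:
            if t0 <= t < t0 + regimen.infusion_duration:
                r += r0
        return r

    grid = _grid(regimen.sim_duration, solver.grid_step)
    conc = np.zeros_like(grid)
    a = 0.0
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        if t1 - t0 < 1e-12:
            continue
        r_seg = rate(0.5 * (t0 + t1))

        def rhs(t: float, y: np.ndarray) -> list[float]:
            return [r_seg - k * y[0]]

        sol = solve_ivp(
            rhs,
            (t0, t1),
            [a],
            method="LSODA",
            rtol=1e-11,
            atol=1e-13,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"infusion integration failed: {sol.message}")
        mask = (grid >= t0 - 1e-9) & (grid <= t1 + 1e-9)
        conc[mask] = sol.sol(grid[mask])[0] / v
        a = float(sol.y[0, -1])

    return ConcentrationProfile(
        times=grid,
        central_conc=conc,
        dosing_times=regimen.dosing_times,
        route=regimen.route,
    )


def simulate_oral_regimen(
    drug: DrugParameters,
    subject: SubjectParameters,
    physiology: GIPhysiology,
    regimen: DoseRegimen,
    *,
    e_gut: float = 0.0,
    e_h: float = 0.0,
    solver: SolverOptions | None = None,
    keep_trajectory: bool = False,
) -> tuple[ConcentrationProfile, AbsorptionResult]:
    """Simulate an oral tablet regimen: coupled lumen + central compartment.

    Each administration deposits a fresh tablet in the running lumen state;
    the absorption summary (fa, fdp, f) is computed on the total
    administered mass at the end of the horizon.
    """
    validate_regimen(regimen)
    if regimen.route != "oral_tablet_ir":
        raise ValidationError("simulate_oral_regimen requires an oral_tablet_ir regimen")
    solver = solver or SolverOptions()
    v = drug.volume_of_distribution(subject.body_mass)
    k = drug.clearance / v
    events = [(t0, regimen.dose, regimen.dose_volume) for t0 in regimen.dosing_times]
    absorption, central = simulate_gi_transit(
        drug,
        physiology,
        events,
        regimen.sim_duration,
        e_gut=e_gut,
        e_h=e_h,
        elimination_rate=k,
        solver=solver,
        keep_trajectory=keep_trajectory,
    )
    profile = ConcentrationProfile(
        times=absorption.time_grid,
        central_conc=np.maximum(central, 0.0) / v,
        dosing_times=regimen.dosing_times,
        route=regimen.route,
    )
    return profile, absorption
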