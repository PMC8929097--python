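"""Apparent permeability (Papp) from transwell transport assays.

Papp = (dQ/dt) / (C0 · A), where dQ/dt is the rate of appearance of
compound in the receiver (basolateral) chamber, C0 the initial donor
(apical) concentration and A the filter area. Repeated sampling with
buffer replacement is corrected by adding the mass carried out in each
withdrawn sample back into the cumulative transported amount:

    Q_n = C_n · V_receiver + Σ_{i<n} C_i · V_sample

The flux is the free-intercept OLS slope of Q versus time over all
receiver time points (robust to a short lag phase). Papp can be mapped to
an effective human jejunal permeability through a log10-linear relation.

Concentration unit note: all concentrations here are µmol/cm³ ≡ µmol/mL
(60 µM = 0.06 µmol/mL), volumes mL, so Q is in µmol and flux µmol/s with
times in seconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .params import ValidationError

__all__ = [
    "TransportAssay",
    "PappEstimate",
    "SinkConditionWarning",
    "cumulative_transported",
    "linear_flux",
    "apparent_permeability",
    "recovery_percent",
    "papp_to_peff",
    "estimate_papp",
    "DEFAULT_PEFF_COEFFICIENTS",
]

_MIN_PER_S = 60.0


class SinkConditionWarning(UserWarning):
    """Receiver concentration exceeded 10% of donor: sink assumption weak."""


@dataclass(frozen=True)
class TransportAssay:
    """Apical-to-basolateral transwell transport dataset.

    ``receiver_concentrations`` has one row per replicate and one column
    per entry of ``times`` (minutes, ascending). Concentrations are in
    µmol/mL; volumes in mL; filter area in cm².
    """

    times: np.ndarray  # min
    receiver_concentrations: np.ndarray  # (n_replicates, n_times), µmol/mL
    donor_c0: float  # µmol/mL
    apical_volume: float  # mL
    receiver_volume: float  # mL
    sample_volume: float  # mL withdrawn and replaced at each time point
    filter_area: float  # cm²
    final_apical_concentration: float | None = None  # µmol/mL

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.atleast_2d(np.asarray(self.receiver_concentrations, dtype=float))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "receiver_concentrations", c)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be 1-D and strictly ascending")
        if c.shape[1] != t.size:
            raise ValidationError(
                f"receiver_concentrations has {c.shape[1]} columns for {t.size} times"
            )
        if np.any(c < 0):
            raise ValidationError("receiver concentrations must be >= 0")
        if self.donor_c0 <= 0:
            raise ValidationError("donor_c0 must be > 0")
        for name in ("apical_volume", "receiver_volume", "filter_area"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0.0 <= self.sample_volume <= self.receiver_volume):
            raise ValidationError("sample_volume must be in [0, receiver_volume]")

    @property
    def n_replicates(self) -> int:
        return self.receiver_concentrations.shape[0]

    @property
    def apical_load(self) -> float:
        """Initial donor amount C0·V_apical, µmol."""
        return self.donor_c0 * self.apical_volume

    def to_frame(self) -> pd.DataFrame:
        """Long format: replicate, time_min, receiver_conc_uM (µM = nmol/mL)."""
        rows = []
        for r in range(self.n_replicates):
            for j, t in enumerate(self.times):
                rows.append(
                    {
                        "replicate": r + 1,
                        "time_min": float(t),
                        "receiver_conc_uM": self.receiver_concentrations[r, j] * 1e3,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PappEstimate:
    """Result of a Papp calculation across replicates."""

    papp: float  # cm/s, mean across replicates
    sem: float  # cm/s, standard error of the mean
    per_replicate_papp: tuple[float, ...]
    flux: float  # µmol/s, slope of the mean cumulative curve
    r_squared: float

    def __post_init__(self) -> None:
        if self.papp < 0 and abs(self.papp) > 1e-15:
            # negative estimates can only come from decreasing (noisy) data
            warnings.warn("negative Papp estimate from non-monotone data", UserWarning)


def cumulative_transported(
    receiver_concentrations: np.ndarray,
    receiver_volume: float,
    sample_volume: float,
) -> np.ndarray:
    """Cumulative amount in the receiver corrected for sampling, µmol.

    Q_n = C_n·V_receiver + Σ_{i<n} C_i·V_sample. With ``sample_volume`` 0
    this reduces to C·V_receiver.
    """
    c = np.asarray(receiver_concentrations, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValidationError("expected a non-empty 1-D concentration series")
    if receiver_volume <= 0:
        raise ValidationError("receiver_volume must be > 0")
    if sample_volume < 0 or sample_volume > receiver_volume:
        raise ValidationError("sample_volume must be in [0, receiver_volume]")
    removed = np.concatenate([[0.0], np.cumsum(c[:-1]) * sample_volume])
    return c * receiver_volume + removed


def linear_flux(times: np.ndarray, cumulative: np.ndarray) -> tuple[float, float]:
    """OLS slope (free intercept) of cumulative amount vs time.

    ``times`` in seconds → flux in µmol/s. Returns (flux, r²).
    """
    t = np.asarray(times, dtype=float)
    q = np.asarray(cumulative, dtype=float)
    if t.size != q.size or t.size < 2:
        raise ValidationError("need >= 2 matching (time, amount) points")
    if np.ptp(t) == 0:
        raise ValidationError("all time points identical")
    fit = linregress(t, q)
    r2 = float(fit.rvalue**2) if not math.isnan(fit.rvalue) else 1.0
    return float(fit.slope), r2


def apparent_permeability(flux: float, donor_c0: float, area: float) -> float:
    """Papp = flux / (C0 · A), cm/s (flux µmol/s, C0 µmol/cm³, A cm²)."""
    if donor_c0 <= 0 or area <= 0:
        raise ValidationError("donor_c0 and area must be > 0")
    return flux / (donor_c0 * area)


def recovery_percent(assay: TransportAssay) -> pd.DataFrame:
    """Percent of the apical load recovered per compartment.

    Basolateral recovery is the sampling-corrected cumulative receiver
    amount (mean over replicates) as % of C0·V_apical per time point;
    apical recovery (constant column) uses the final apical concentration
    when available.
    """
    q = np.vstack(
        [
            cumulative_transported(
                assay.receiver_concentrations[r], assay.receiver_volume, assay.sample_volume
            )
            for r in range(assay.n_replicates)
        ]
    )
    baso = 100.0 * q.mean(axis=0) / assay.apical_load
    out = pd.DataFrame({"time_min": assay.times, "basolateral_percent": baso})
    if assay.final_apical_concentration is not None:
        apical = 100.0 * assay.final_apical_concentration / assay.donor_c0
        out["apical_percent_final"] = apical
    return out


DEFAULT_PEFF_COEFFICIENTS: tuple[float, float] = (
    math.log10(0.59e-4 / 5.8e-6),  # ≈ 1.0074: pure scale anchored on gemcitabine
    1.0,
)


def papp_to_peff(
    papp: float, coefficients: tuple[float, float] = DEFAULT_PEFF_COEFFICIENTS
) -> float:
    """Map Caco-2 Papp to human jejunal Peff: log10 Peff = a + b·log10 Papp.

    The default is a pure scale (b = 1) anchored so a Papp of 5.8e-6 cm/s
    maps to the reference jejunal permeability 0.59e-4 cm/s.
    """
    if papp <= 0:
        raise ValidationError(f"papp must be > 0, got {papp}")
    a, b = coefficients
    return 10.0 ** (a + b * math.log10(papp))


def estimate_papp(assay: TransportAssay) -> PappEstimate:
    """Estimate Papp from a transwell assay (per replicate and pooled).

    Emits :class:`SinkConditionWarning` if any measured receiver
    concentration exceeds 10% of the donor concentration.
    """
    if np.any(assay.receiver_concentrations > 0.1 * assay.donor_c0):
        warnings.warn(
            "receiver concentration exceeded 10% of donor; sink-condition "
            "assumption of the Papp calculation is weak",
            SinkConditionWarning,
            stacklevel=2,
        )
    t_s = assay.times * _MIN_PER_S
    per_rep = []
    curves = []
    for r in range(assay.n_replicates):
        q = cumulative_transported(
            assay.receiver_concentrations[r], assay.receiver_volume, assay.sample_volume
        )
        curves.append(q)
        fl, _ = linear_flux(t_s, q)
        per_rep.append(apparent_permeability(fl, assay.donor_c0, assay.filter_area))
    mean_q = np.mean(curves, axis=0)
    flux, r2 = linear_flux(t_s, mean_q)
    papp = float(np.mean(per_rep))
    sem = (
        float(np.std(per_rep, ddof=1) / math.sqrt(len(per_rep)))
        if len(per_rep) > 1
        else 0.0
    )
    return PappEstimate(
        papp=papp,
        sem=sem,
        per_replicate_papp=tuple(per_rep),
        flux=flux,
        r_squared=r2,
    )
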