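"""Model/Results surface of the package.

:class:`PBPKModel` bundles a drug, a subject and a GI physiology and
simulates dosing regimens; :meth:`PBPKModel.calibrate_colon_asf` returns a
calibrated copy whose colonic absorption scale reproduces a reference
fraction absorbed. :class:`Caco2PermeabilityModel` fits the apparent
permeability of a transwell dataset. Both return results objects carrying
estimates and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as _config
from .absorption import (
    AbsorptionResult,
    SolverOptions,
    calibrate_asf,
    regional_absorption_fractions,
)
from .caco2 import (
    PappEstimate,
    TransportAssay,
    estimate_papp,
    papp_to_peff,
    recovery_percent,
    DEFAULT_PEFF_COEFFICIENTS,
)
from .disposition import (
    ConcentrationProfile,
    simulate_iv_infusion,
    simulate_oral_regimen,
)
from .nca import PKSummary, summarize_regimen
from .params import (
    DoseRegimen,
    DrugParameters,
    GIPhysiology,
    SubjectParameters,
    ValidationError,
    default_human_physiology,
    default_subject,
    validate_regimen,
)

__all__ = ["PBPKModel", "PBPKResults", "Caco2PermeabilityModel", "PappResults"]


@dataclass(frozen=True)
class PBPKResults:
    """One simulated regimen: profile, absorption summary and NCA row."""

    model: "PBPKModel"
    regimen: DoseRegimen
    profile: ConcentrationProfile
    absorption: AbsorptionResult | None
    label: str = ""

    @cached_property
    def pk(self) -> PKSummary:
        return summarize_regimen(
            self.profile,
            self.model.drug,
            self.model.subject,
            self.absorption,
            label=self.label,
            dose=self.regimen.dose,
            n_doses=self.regimen.n_doses,
            interval=self.regimen.interval,
        )

    def regional_absorption(self) -> pd.DataFrame:
        if self.absorption is None:
            raise ValidationError("regional absorption applies to oral runs only")
        return regional_absorption_fractions(self.absorption)

    def to_frame(self) -> pd.DataFrame:
        return self.profile.to_frame()

    def summary(self) -> str:
        s = self.pk.to_series()
        lines = [
            f"PBPK simulation summary — {self.label or self.regimen.route}",
            f"  route: {self.regimen.route}, dose {self.regimen.dose:g} mg × "
            f"{self.regimen.n_doses}, interval {self.regimen.interval:g} h",
            f"  Fa     {s.fa_percent:8.3f} %",
            f"  FDp    {s.fdp_percent:8.3f} %",
            f"  F      {s.f_percent:8.3f} %",
            f"  Cmax   {s.cmax_mg_per_L:8.3f} mg/L at Tmax {s.tmax_h:.2f} h",
            f"  AUC0-t {s.auc_0_t_ug_h_per_mL:8.3f} µg·h/mL",
            f"  AUC0-∞ {s.auc_0_inf_ug_h_per_mL:8.3f} µg·h/mL",
            f"  λz     {s.lambda_z_per_h:8.3f} 1/h",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        return self.profile.plot(ax=ax, label=self.label or None, **kwargs)


@dataclass(frozen=True)
class PBPKModel:
    """ACAT-style absorption coupled to one-compartment disposition."""

    drug: DrugParameters
    subject: SubjectParameters = field(default_factory=default_subject)
    physiology: GIPhysiology = field(default_factory=default_human_physiology)
    e_gut: float = 0.0
    e_h: float = 0.0
    solver: SolverOptions = field(default_factory=SolverOptions)
    calibration: dict | None = None

    @classmethod
    def from_configs(
        cls,
        drug_path: str | Path,
        subject_path: str | Path | None = None,
        physiology_path: str | Path | None = None,
        **kwargs,
    ) -> "PBPKModel":
        drug = _config.load_drug_parameters(drug_path)
        subject = (
            _config.load_subject(subject_path) if subject_path else default_subject()
        )
        physiology = (
            _config.load_physiology(physiology_path)
            if physiology_path
            else default_human_physiology()
        )
        return cls(drug=drug, subject=subject, physiology=physiology, **kwargs)

    def calibrate_colon_asf(
        self,
        target_fa: float,
        dose: float,
        dose_volume: float = 250.0,
        *,
        sim_duration: float = 24.0,
        tol: float = 1e-3,
    ) -> "PBPKModel":
        """Return a copy whose colonic ASF reproduces ``target_fa``.

        Calibration runs once against a single reference dose; every other
        regimen simulated with the returned model is a prediction.
        """
        phys, info = calibrate_asf(
            target_fa,
            self.drug,
            self.physiology,
            dose,
            dose_volume,
            sim_duration=sim_duration,
            tol=tol,
            solver=self.solver,
        )
        info = dict(info, target_fa=target_fa, dose=dose, dose_volume=dose_volume)
        return PBPKModel(
            drug=self.drug,
            subject=self.subject,
            physiology=phys,
            e_gut=self.e_gut,
            e_h=self.e_h,
            solver=self.solver,
            calibration=info,
        )

    def simulate(
        self,
        regimen: DoseRegimen,
        *,
        label: str = "",
        keep_trajectory: bool = False,
    ) -> PBPKResults:
        validate_regimen(regimen)
        if regimen.route == "iv_infusion":
            profile = simulate_iv_infusion(
                self.drug, self.subject, regimen, solver=self.solver
            )
            absorption = None
        else:
            profile, absorption = simulate_oral_regimen(
                self.drug,
                self.subject,
                self.physiology,
                regimen,
                e_gut=self.e_gut,
                e_h=self.e_h,
                solver=self.solver,
                keep_trajectory=keep_trajectory,
            )
        return PBPKResults(
            model=self,
            regimen=regimen,
            profile=profile,
            absorption=absorption,
            label=label,
        )


@dataclass(frozen=True)
class PappResults:
    """Fitted apparent permeability with replicate spread and recovery."""

    estimate: PappEstimate
    peff: float  # cm/s, mapped effective jejunal permeability
    recovery: pd.DataFrame
    n_replicates: int

    @property
    def papp(self) -> float:
        return self.estimate.papp

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Caco-2 apparent permeability fit",
            f"  replicates      {self.n_replicates}",
            f"  Papp            {e.papp:.3e} ± {e.sem:.2e} cm/s (mean ± SEM)",
            f"  flux (dQ/dt)    {e.flux:.3e} µmol/s",
            f"  r²              {e.r_squared:.4f}",
            f"  mapped Peff     {self.peff:.3e} cm/s",
        ]
        return "\n".join(lines)

    def to_series(self) -> pd.Series:
        e = self.estimate
        return pd.Series(
            {
                "papp_cm_per_s": e.papp,
                "sem_cm_per_s": e.sem,
                "flux_umol_per_s": e.flux,
                "r_squared": e.r_squared,
                "peff_cm_per_s": self.peff,
                "n_replicates": self.n_replicates,
            }
        )


class Caco2PermeabilityModel:
    """OLS flux model for apical-to-basolateral transwell transport."""

    def __init__(
        self,
        assay: TransportAssay,
        peff_coefficients: tuple[float, float] = DEFAULT_PEFF_COEFFICIENTS,
    ):
        self.assay = assay
        self.peff_coefficients = peff_coefficients

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        *,
        donor_c0: float = 0.06,
        apical_volume: float = 0.4,
        receiver_volume: float = 1.2,
        sample_volume: float = 0.6,
        filter_area: float = 1.12,
        **kwargs,
    ) -> "Caco2PermeabilityModel":
        """Build from a tidy table: replicate, time_min, receiver_conc_uM."""
        required = {"replicate", "time_min", "receiver_conc_uM"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"assay table missing columns {sorted(missing)}")
        wide = frame.pivot_table(
            index="replicate", columns="time_min", values="receiver_conc_uM"
        ).sort_index(axis=1)
        if wide.isna().any().any():
            bad = frame.loc[frame.receiver_conc_uM.isna()].index.tolist()
            raise ValidationError(f"incomplete assay table (missing cells; rows {bad})")
        assay = TransportAssay(
            times=wide.columns.to_numpy(dtype=float),
            receiver_concentrations=wide.to_numpy() * 1e-3,  # µM → µmol/mL
            donor_c0=donor_c0,
            apical_volume=apical_volume,
            receiver_volume=receiver_volume,
            sample_volume=sample_volume,
            filter_area=filter_area,
        )
        return cls(assay, **kwargs)

    def fit(self) -> PappResults:
        estimate = estimate_papp(self.assay)
        peff = (
            papp_to_peff(estimate.papp, self.peff_coefficients)
            if estimate.papp > 0
            else 0.0
        )
        return PappResults(
            estimate=estimate,
            peff=peff,
            recovery=recovery_percent(self.assay),
            n_replicates=self.assay.n_replicates,
        )
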