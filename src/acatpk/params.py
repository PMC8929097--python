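"""Core domain types: drug, subject, GI physiology and dosing regimen.

All quantities are carried in the units used throughout the package:
masses in mg, volumes in mL, lengths in cm (except particle radius, µm),
times in hours (except where a field is explicitly in seconds), clearance
in L/h, concentrations in mg/mL for lumen fluid and mg/L for plasma.
Unit conversions happen where a quantity enters a rate expression, never
in the stored fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "ValidationError",
    "DrugParameters",
    "SubjectParameters",
    "GICompartment",
    "GIPhysiology",
    "DoseRegimen",
    "gemcitabine",
    "default_subject",
    "default_human_physiology",
    "validate_regimen",
]


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


def _positive(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValidationError(f"{name} must be a finite number > 0, got {value!r}")


def _non_negative(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value >= 0):
        raise ValidationError(f"{name} must be a finite number >= 0, got {value!r}")


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical and pharmacokinetic inputs of one compound.

    Attributes
    ----------
    molecular_weight : float
        g/mol.
    logP : float
        Octanol/water partition coefficient of the neutral species.
    solubility : float
        Aqueous saturation solubility Cs, mg/mL, at ``solubility_ph``.
    mean_precipitation_time : float
        First-order time constant for precipitation of supersaturated
        dissolved drug, seconds.
    particle_density : float
        g/mL.
    particle_radius : float
        Initial (mono-disperse) particle radius, µm.
    diffusion_coefficient : float
        Aqueous diffusion coefficient, cm²/s.
    blood_plasma_ratio : float
        Whole blood / plasma concentration ratio (informational for the
        linear disposition model).
    peff_jejunal : float
        Human effective jejunal permeability, cm/s.
    fup : float
        Fraction unbound in plasma, in (0, 1].
    vc_per_kg : float
        Central volume of distribution, L/kg.
    clearance : float
        Systemic clearance, L/h.
    """

    name: str
    molecular_weight: float
    logP: float
    solubility: float
    solubility_ph: float
    mean_precipitation_time: float
    particle_density: float
    particle_radius: float
    diffusion_coefficient: float
    blood_plasma_ratio: float
    peff_jejunal: float
    fup: float
    vc_per_kg: float
    clearance: float

    def __post_init__(self) -> None:
        for fname in (
            "molecular_weight",
            "solubility",
            "mean_precipitation_time",
            "particle_density",
            "particle_radius",
            "diffusion_coefficient",
            "blood_plasma_ratio",
            "vc_per_kg",
            "clearance",
        ):
            _positive(fname, getattr(self, fname))
        _non_negative("peff_jejunal", self.peff_jejunal)
        if not (0.0 < self.fup <= 1.0):
            raise ValidationError(f"fup must be in (0, 1], got {self.fup!r}")
        if not (0.0 <= self.solubility_ph <= 14.0):
            raise ValidationError(
                f"solubility_ph must be in [0, 14], got {self.solubility_ph!r}"
            )

    def volume_of_distribution(self, body_mass: float) -> float:
        """Central volume Vc in L for a subject of ``body_mass`` kg."""
        _positive("body_mass", body_mass)
        return self.vc_per_kg * body_mass

    def elimination_rate(self, body_mass: float) -> float:
        """First-order elimination rate constant CL/Vc, 1/h."""
        return self.clearance / self.volume_of_distribution(body_mass)

    def half_life(self, body_mass: float) -> float:
        """Elimination half-life ln2·Vc/CL, hours."""
        return math.log(2.0) / self.elimination_rate(body_mass)


@dataclass(frozen=True)
class SubjectParameters:
    """Minimal subject description; only body mass enters the model."""

    body_mass: float = 70.0  # kg

    def __post_init__(self) -> None:
        _positive("body_mass", self.body_mass)


@dataclass(frozen=True)
class GICompartment:
    """One well-stirred luminal compartment of the GI tract.

    ``absorption_scale_factor`` (ASF) multiplies the intrinsic absorption
    rate constant 2·Peff/R of the compartment; 0 marks a non-absorbing
    segment (stomach by default).
    """

    name: str
    volume: float  # mL
    radius: float  # cm
    mean_transit_time: float  # h
    ph: float
    absorption_scale_factor: float = 1.0

    def __post_init__(self) -> None:
        _positive("volume", self.volume)
        _positive("radius", self.radius)
        _positive("mean_transit_time", self.mean_transit_time)
        _non_negative("absorption_scale_factor", self.absorption_scale_factor)


@dataclass(frozen=True)
class GIPhysiology:
    """Anatomically ordered chain of GI compartments (stomach first)."""

    compartments: tuple[GICompartment, ...]
    small_intestine_names: tuple[str, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.compartments)
        object.__setattr__(self, "compartments", comps)
        object.__setattr__(
            self, "small_intestine_names", tuple(self.small_intestine_names)
        )
        if len(comps) < 3:
            raise ValidationError("physiology needs at least 3 compartments")
        names = [c.name for c in comps]
        if len(set(names)) != len(names):
            raise ValidationError(f"compartment names must be unique: {names}")
        unknown = set(self.small_intestine_names) - set(names)
        if unknown:
            raise ValidationError(f"unknown small-intestine names: {sorted(unknown)}")
        if names[0] in self.small_intestine_names:
            raise ValidationError("the first compartment (stomach) cannot be intestinal")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.compartments)

    @property
    def stomach(self) -> GICompartment:
        return self.compartments[0]

    @property
    def colon_names(self) -> tuple[str, ...]:
        """Compartments distal to the small intestine (excludes stomach)."""
        si = set(self.small_intestine_names)
        return tuple(c.name for c in self.compartments[1:] if c.name not in si)

    def small_intestine_transit_time(self) -> float:
        """Summed mean transit time of the small-intestine chain, hours."""
        si = set(self.small_intestine_names)
        return sum(c.mean_transit_time for c in self.compartments if c.name in si)

    def with_scaled_asf(
        self, colon_multiplier: float = 1.0, global_multiplier: float = 1.0
    ) -> "GIPhysiology":
        """Return a copy with colon (and optionally all) ASF values scaled."""
        _non_negative("colon_multiplier", colon_multiplier)
        _non_negative("global_multiplier", global_multiplier)
        colon = set(self.colon_names)
        new = []
        for c in self.compartments:
            m = global_multiplier * (colon_multiplier if c.name in colon else 1.0)
            new.append(replace(c, absorption_scale_factor=c.absorption_scale_factor * m))
        return GIPhysiology(tuple(new), self.small_intestine_names)


_ROUTES = ("iv_infusion", "oral_tablet_ir")


@dataclass(frozen=True)
class DoseRegimen:
    """A repeated-administration schedule for one route.

    First dose at t = 0, subsequent doses every ``interval`` hours.
    ``infusion_duration`` applies to IV infusions only; ``dose_volume``
    (fluid co-administered with the tablet) to oral doses only.
    """

    route: str
    dose: float  # mg per administration
    n_doses: int = 1
    interval: float = 24.0  # h
    infusion_duration: float | None = None  # h
    dose_volume: float | None = None  # mL
    sim_duration: float = 24.0  # h

    def __post_init__(self) -> None:
        if self.route not in _ROUTES:
            raise ValidationError(f"route must be one of {_ROUTES}, got {self.route!r}")
        _positive("dose", self.dose)
        _positive("sim_duration", self.sim_duration)
        if self.n_doses < 1:
            raise ValidationError(f"n_doses must be >= 1, got {self.n_doses}")
        if self.n_doses > 1:
            _positive("interval", self.interval)
            if (self.n_doses - 1) * self.interval >= self.sim_duration:
                raise ValidationError(
                    "last dose at "
                    f"{(self.n_doses - 1) * self.interval} h falls outside the "
                    f"{self.sim_duration} h simulation horizon"
                )
        if self.route == "iv_infusion":
            if self.infusion_duration is None:
                raise ValidationError("iv_infusion regimens need infusion_duration")
            _positive("infusion_duration", self.infusion_duration)
            if self.dose_volume is not None:
                raise ValidationError("dose_volume applies to oral regimens only")
        else:
            if self.dose_volume is None:
                object.__setattr__(self, "dose_volume", 250.0)
            _positive("dose_volume", self.dose_volume)
            if self.infusion_duration is not None:
                raise ValidationError(
                    "infusion_duration applies to iv_infusion regimens only"
                )

    @property
    def dosing_times(self) -> tuple[float, ...]:
        return tuple(i * self.interval for i in range(self.n_doses))

    @property
    def total_dose(self) -> float:
        return self.dose * self.n_doses


def validate_regimen(regimen: DoseRegimen) -> DoseRegimen:
    """Re-run all regimen invariants and return the regimen unchanged."""
    DoseRegimen(
        route=regimen.route,
        dose=regimen.dose,
        n_doses=regimen.n_doses,
        interval=regimen.interval,
        infusion_duration=regimen.infusion_duration,
        dose_volume=regimen.dose_volume
        if regimen.route == "iv_infusion"
        else regimen.dose_volume,
        sim_duration=regimen.sim_duration,
    )
    return regimen


def gemcitabine() -> DrugParameters:
    """Gemcitabine parameter set used by the packaged oral-vs-IV study.

    Physicochemical values and jejunal permeability as reported for this
    compound (solubility 5.01 mg/mL at pH 7.92, Peff 0.59e-4 cm/s, Vc
    1.45 L/kg); systemic clearance 120 L/h per the FDA label. The printed
    diffusion coefficient is interpreted as 0.93e-5 cm²/s (the positive
    exponent found in some sources is a typographical impossibility).
    Particle radius 25 µm is a conventional immediate-release default.
    """
    return DrugParameters(
        name="gemcitabine",
        molecular_weight=263.2,
        logP=-1.32,
        solubility=5.01,
        solubility_ph=7.92,
        mean_precipitation_time=900.0,
        particle_density=1.2,
        particle_radius=25.0,
        diffusion_coefficient=0.93e-5,
        blood_plasma_ratio=1.12,
        peff_jejunal=0.59e-4,
        fup=0.846,
        vc_per_kg=1.45,
        clearance=120.0,
    )


def default_subject() -> SubjectParameters:
    """70 kg reference adult (Vc 1.45 L/kg → 101.5 L for gemcitabine)."""
    return SubjectParameters(body_mass=70.0)


# Fasted-state human GI table (volume mL, radius cm, transit h, pH, ASF).
# Adapted from the published CAT/ACAT physiologies; small-intestine transit
# sums to 3.30 h. The stomach does not absorb (ASF 0).
_FASTED_TABLE: tuple[tuple[str, float, float, float, float, float], ...] = (
    ("stomach", 47.0, 9.67, 0.25, 1.30, 0.0),
    ("duodenum", 42.0, 1.60, 0.26, 6.00, 1.0),
    ("jejunum1", 154.0, 1.53, 0.95, 6.20, 1.0),
    ("jejunum2", 122.0, 1.45, 0.76, 6.40, 1.0),
    ("ileum1", 94.0, 1.33, 0.59, 6.60, 1.0),
    ("ileum2", 71.0, 1.21, 0.43, 6.90, 1.0),
    ("ileum3", 49.0, 1.08, 0.31, 7.40, 1.0),
    ("caecum", 47.0, 3.39, 4.50, 6.40, 1.0),
    ("asc_colon", 50.0, 2.41, 13.50, 6.80, 1.0),
)

_SMALL_INTESTINE = ("duodenum", "jejunum1", "jejunum2", "ileum1", "ileum2", "ileum3")


def default_human_physiology(body_mass: float = 70.0) -> GIPhysiology:
    """Nine-compartment fasted human GI physiology.

    The compartment table is a population default and does not scale with
    body mass; ``body_mass`` is validated for interface symmetry with the
    disposition model (which does use it).
    """
    _positive("body_mass", body_mass)
    comps = tuple(
        GICompartment(
            name=n,
            volume=v,
            radius=r,
            mean_transit_time=t,
            ph=ph,
            absorption_scale_factor=asf,
        )
        for (n, v, r, t, ph, asf) in _FASTED_TABLE
    )
    return GIPhysiology(compartments=comps, small_intestine_names=_SMALL_INTESTINE)
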