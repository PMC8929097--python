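"""Synthetic-data generators for validation without external datasets.

The transwell generator reproduces the assay protocol used in the
packaged study: 60 µM apical donor, 0.4 mL apical / 1.2 mL basolateral
volumes, a 0.6 mL basolateral sample withdrawn and replaced with buffer
every 30 min for 2 h, four replicates. It solves the exact two-chamber
diffusion system (no sink approximation), so the sink-condition bias of
the standard Papp estimator is measurable against the known truth.
Measurement noise is multiplicative Gaussian (HPLC-like proportional
error) applied to measured concentrations only — the latent state
conserves mass exactly.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm

from .caco2 import TransportAssay, estimate_papp
from .params import DrugParameters, ValidationError, gemcitabine

__all__ = [
    "AssayProtocol",
    "AssayLatentState",
    "generate_caco2_assay",
    "generate_virtual_drug",
    "papp_recovery_experiment",
    "DEFAULT_DRUG_RANGES",
]


@dataclass(frozen=True)
class AssayProtocol:
    """Transwell protocol geometry and schedule (defaults: packaged study)."""

    donor_c0: float = 0.06  # µmol/mL (60 µM)
    apical_volume: float = 0.4  # mL
    receiver_volume: float = 1.2  # mL
    sample_volume: float = 0.6  # mL
    sample_times: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0)  # min
    filter_area: float = 1.12  # cm²
    replicates: int = 4

    def __post_init__(self) -> None:
        if self.donor_c0 <= 0:
            raise ValidationError("donor_c0 must be > 0")
        if not (0 <= self.sample_volume <= self.receiver_volume):
            raise ValidationError("sample_volume must be in [0, receiver_volume]")
        if self.replicates < 1:
            raise ValidationError("need at least one replicate")
        if len(self.sample_times) < 2 or any(
            b <= a for a, b in zip(self.sample_times, self.sample_times[1:])
        ):
            raise ValidationError("sample_times must be >= 2 ascending values")


@dataclass(frozen=True)
class AssayLatentState:
    """Noise-free internals of a generated assay (mass in µmol)."""

    receiver_conc: np.ndarray  # latent receiver conc at each sample time, pre-withdrawal
    apical_final_conc: float
    withdrawn_mass: float  # total mass carried out by sampling
    apical_mass_final: float
    receiver_mass_final: float

    def total_mass(self) -> float:
        return self.apical_mass_final + self.receiver_mass_final + self.withdrawn_mass


def _exact_two_chamber(true_papp: float, protocol: AssayProtocol):
    """Propagate the exact two-chamber diffusion with sampling events."""
    va, vr, vs = protocol.apical_volume, protocol.receiver_volume, protocol.sample_volume
    k = true_papp * protocol.filter_area  # cm³/s
    rate = np.array([[-k / va, k / vr], [k / va, -k / vr]])
    m = np.array([protocol.donor_c0 * va, 0.0])  # [apical, receiver] mass, µmol
    latent_cr = []
    withdrawn = 0.0
    t_prev = None
    for t_min in protocol.sample_times:
        if t_prev is not None:
            dt_s = (t_min - t_prev) * 60.0
            m = expm(rate * dt_s) @ m
        cr = m[1] / vr
        latent_cr.append(cr)
        taken = cr * vs
        m[1] -= taken  # replaced with blank buffer; volume unchanged
        withdrawn += taken
        t_prev = t_min
    return np.array(latent_cr), m, withdrawn


def generate_caco2_assay(
    true_papp: float,
    protocol: AssayProtocol | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    *,
    return_latent: bool = False,
) -> TransportAssay | tuple[TransportAssay, AssayLatentState]:
    """Simulate a transwell assay with a known true permeability.

    Measured receiver concentrations are the latent (pre-withdrawal)
    concentrations perturbed by multiplicative Gaussian noise with
    coefficient of variation ``noise_cv``, independently per replicate and
    time point, clipped at zero. Deterministic given ``seed``.
    """
    if true_papp < 0:
        raise ValidationError("true_papp must be >= 0")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    protocol = protocol or AssayProtocol()
    latent_cr, m_final, withdrawn = _exact_two_chamber(true_papp, protocol)
    rng = np.random.default_rng(seed)
    noise = rng.normal(
        loc=1.0, scale=noise_cv, size=(protocol.replicates, latent_cr.size)
    )
    measured = np.maximum(latent_cr[None, :] * noise, 0.0)
    apical_final = m_final[0] / protocol.apical_volume
    apical_measured = max(
        apical_final * rng.normal(loc=1.0, scale=noise_cv), 0.0
    )
    assay = TransportAssay(
        times=np.asarray(protocol.sample_times, dtype=float),
        receiver_concentrations=measured,
        donor_c0=protocol.donor_c0,
        apical_volume=protocol.apical_volume,
        receiver_volume=protocol.receiver_volume,
        sample_volume=protocol.sample_volume,
        filter_area=protocol.filter_area,
        final_apical_concentration=apical_measured,
    )
    if not return_latent:
        return assay
    latent = AssayLatentState(
        receiver_conc=latent_cr,
        apical_final_conc=apical_final,
        withdrawn_mass=withdrawn,
        apical_mass_final=m_final[0],
        receiver_mass_final=m_final[1],
    )
    return assay, latent


DEFAULT_DRUG_RANGES: dict[str, tuple[float, float]] = {
    "peff_jejunal": (1e-6, 1e-3),  # cm/s, log-uniform
    "solubility": (0.01, 100.0),  # mg/mL, log-uniform
    "clearance": (1.0, 200.0),  # L/h, log-uniform
    "vc_per_kg": (0.1, 5.0),  # L/kg, log-uniform
}


def generate_virtual_drug(
    seed: int, ranges: dict[str, tuple[float, float]] | None = None
) -> DrugParameters:
    """Reproducible random drug with log-uniform PK/permeability draws.

    Fields not covered by ``ranges`` keep the packaged reference-compound
    values, giving a plausible small-molecule profile.
    """
    ranges = {**DEFAULT_DRUG_RANGES, **(ranges or {})}
    for name, (lo, hi) in ranges.items():
        if not (0 < lo < hi):
            raise ValidationError(f"invalid range for {name}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    draws = {
        name: float(10.0 ** rng.uniform(math.log10(lo), math.log10(hi)))
        for name, (lo, hi) in ranges.items()
    }
    base = gemcitabine()
    return replace(base, name=f"virtual-{seed}", **draws)


def papp_recovery_experiment(
    n_seeds: int,
    true_papp: float,
    noise_cv: float,
    protocol: AssayProtocol | None = None,
    base_seed: int = 0,
) -> dict[str, float]:
    """Monte-Carlo parameter recovery for the Papp estimator.

    Generates ``n_seeds`` assays at the given truth and noise level, runs
    the standard estimation pipeline on each and reports the median
    relative error, relative RMSE and mean relative bias of the estimates.
    """
    if n_seeds < 1:
        raise ValidationError("n_seeds must be >= 1")
    if true_papp <= 0:
        raise ValidationError("true_papp must be > 0 for relative errors")
    rel_errors = []
    import warnings as _warnings

    for i in range(n_seeds):
        assay = generate_caco2_assay(
            true_papp, protocol, noise_cv, seed=base_seed + i
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            est = estimate_papp(assay)
        rel_errors.append((est.papp - true_papp) / true_papp)
    rel = np.array(rel_errors)
    return {
        "median_abs_relative_error": float(np.median(np.abs(rel))),
        "relative_rmse": float(np.sqrt(np.mean(rel**2))),
        "mean_relative_bias": float(np.mean(rel)),
        "n": n_seeds,
    }
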