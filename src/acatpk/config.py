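"""Structured-text (TOML) configuration loading and JSON export.

One file per object kind. Units in the files are exactly the units of the
corresponding dataclass fields (see :mod:`acatpk.params`); no conversion
happens at load time beyond type coercion.

Schemas
-------
``[drug]``       name, molecular_weight, logP, solubility, solubility_ph,
                 mean_precipitation_time, particle_density, particle_radius,
                 diffusion_coefficient, blood_plasma_ratio, peff_jejunal,
                 fup, vc_per_kg, clearance
``[subject]``    body_mass
``[regimen]``    route, dose, n_doses, interval, sim_duration and, per
                 route, infusion_duration or dose_volume
``[physiology]`` small_intestine = [...] plus one ``[[physiology.compartment]]``
                 table per compartment with name, volume, radius,
                 mean_transit_time, ph, absorption_scale_factor
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path
from typing import Any

from .params import (
    DoseRegimen,
    DrugParameters,
    GICompartment,
    GIPhysiology,
    SubjectParameters,
    ValidationError,
)

__all__ = [
    "SchemaError",
    "load_drug_parameters",
    "load_subject",
    "load_regimen",
    "load_physiology",
    "to_json",
    "packaged_config",
]


class SchemaError(ValueError):
    """A config file is missing a section or field, or has extras."""


def _read_table(path: str | Path, section: str) -> dict[str, Any]:
    path = Path(path)
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    if section not in doc:
        raise SchemaError(f"{path}: missing [{section}] section")
    table = doc[section]
    if not isinstance(table, dict):
        raise SchemaError(f"{path}: [{section}] must be a table")
    return table


def _pop_fields(
    table: dict[str, Any], required: tuple[str, ...], optional: tuple[str, ...], where: str
) -> dict[str, Any]:
    out: dict[str, Any] = {}
    table = dict(table)
    for name in required:
        if name not in table:
            raise SchemaError(f"{where}: missing required field '{name}'")
        out[name] = table.pop(name)
    for name in optional:
        if name in table:
            out[name] = table.pop(name)
    if table:
        raise SchemaError(f"{where}: unknown fields {sorted(table)}")
    return out


_DRUG_FIELDS = tuple(f.name for f in dataclasses.fields(DrugParameters))


def load_drug_parameters(path: str | Path) -> DrugParameters:
    """Load and validate a ``[drug]`` config file."""
    table = _pop_fields(_read_table(path, "drug"), _DRUG_FIELDS, (), f"{path} [drug]")
    return DrugParameters(**table)


def load_subject(path: str | Path) -> SubjectParameters:
    table = _pop_fields(
        _read_table(path, "subject"), ("body_mass",), (), f"{path} [subject]"
    )
    return SubjectParameters(**table)


def load_regimen(path: str | Path) -> DoseRegimen:
    table = _pop_fields(
        _read_table(path, "regimen"),
        ("route", "dose"),
        ("n_doses", "interval", "infusion_duration", "dose_volume", "sim_duration"),
        f"{path} [regimen]",
    )
    return DoseRegimen(**table)


def load_physiology(path: str | Path) -> GIPhysiology:
    table = dict(_read_table(path, "physiology"))
    if "small_intestine" not in table:
        raise SchemaError(f"{path} [physiology]: missing 'small_intestine'")
    si = tuple(table.pop("small_intestine"))
    rows = table.pop("compartment", None)
    if table:
        raise SchemaError(f"{path} [physiology]: unknown fields {sorted(table)}")
    if not rows:
        raise SchemaError(f"{path} [physiology]: no [[physiology.compartment]] tables")
    comps = []
    for i, row in enumerate(rows):
        fields = _pop_fields(
            row,
            ("name", "volume", "radius", "mean_transit_time", "ph"),
            ("absorption_scale_factor",),
            f"{path} compartment #{i}",
        )
        comps.append(GICompartment(**fields))
    return GIPhysiology(compartments=tuple(comps), small_intestine_names=si)


def to_json(obj: Any, path: str | Path | None = None) -> str:
    """Serialize a validated domain object (dataclass) to JSON."""
    if not dataclasses.is_dataclass(obj):
        raise TypeError(f"expected a dataclass instance, got {type(obj)!r}")
    text = json.dumps(dataclasses.asdict(obj), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def packaged_config(name: str) -> Path:
    """Path of a config file shipped inside the package (``acatpk/data``)."""
    here = Path(__file__).resolve().parent / "data" / name
    if not here.exists():
        raise FileNotFoundError(f"no packaged config named {name!r}")
    return here
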