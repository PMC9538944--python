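"""Packaged parameter sets: species physiology, chemicals, reference constants.

Everything here is data, not model structure.  Users can load their own YAML
files with the same shape via :func:`load_species_file` /
:func:`load_chemicals_file` and pass the resulting objects anywhere the
built-ins are accepted.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .ivive import ChemicalProps, FishPhysiology


def _read_packaged(name: str) -> dict:
    ref = resources.files("fishbcf.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def _species_table() -> dict:
    return _read_packaged("species.yaml")


@lru_cache(maxsize=None)
def _chemical_table() -> dict:
    return _read_packaged("chemicals.yaml")


@lru_cache(maxsize=None)
def reference_values() -> dict:
    """Study-reported constants (mean clearances, reported kB and BCF values)."""
    return _read_packaged("reference_values.yaml")


def available_species() -> tuple[str, ...]:
    return tuple(_species_table())


def available_chemicals() -> tuple[str, ...]:
    return tuple(_chemical_table())


def get_species(name: str) -> FishPhysiology:
    """Load a packaged physiology set (trout_reference, trout_study, carp_study)."""
    try:
        raw = _species_table()[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown species set {name!r}; available: {available_species()}"
        ) from None
    return FishPhysiology(**raw)


def get_chemical(name: str) -> ChemicalProps:
    """Load a packaged chemical descriptor set (MXC, BaP)."""
    try:
        raw = _chemical_table()[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown chemical {name!r}; available: {available_chemicals()}"
        ) from None
    return ChemicalProps(**raw)


def load_species_file(path: str | Path, name: str) -> FishPhysiology:
    with open(path, "r", encoding="utf-8") as fh:
        table = yaml.safe_load(fh)
    if name not in table:
        raise ConfigurationError(f"species set {name!r} not in {path}")
    return FishPhysiology(**table[name])


def load_chemicals_file(path: str | Path, name: str) -> ChemicalProps:
    with open(path, "r", encoding="utf-8") as fh:
        table = yaml.safe_load(fh)
    if name not in table:
        raise ConfigurationError(f"chemical {name!r} not in {path}")
    return ChemicalProps(**table[name])


def mean_clint(species: str, chemical: str, cell_state: str = "fresh") -> float:
    """Study-reported mean in vitro intrinsic clearance, mL/h/10^6 cells."""
    key = "mean_clint_fresh" if cell_state == "fresh" else "mean_clint_cryo"
    try:
        return float(reference_values()[key][species][chemical]["mean"])
    except KeyError:
        raise ConfigurationError(
            f"no reported clearance for {species}/{chemical}/{cell_state}"
        ) from None


def reported_kb(species: str, chemical: str) -> float:
    """Study-reported extrapolated kB (fresh cells), 1/d."""
    return float(reference_values()["reported_kb_predicted"][species][chemical])
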