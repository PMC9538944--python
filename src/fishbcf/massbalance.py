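"""Kinetic mass-balance rate constants and BCF prediction.

A one-compartment bioconcentration model for a fish exposed via water:

    dC_f/dt = k1 C_w - (k2 + kE + kG + kB) C_f

with gill uptake k1 (L/kg/d), respiratory elimination k2, fecal egestion kE,
growth dilution kG and biotransformation kB (all 1/d).  At steady state

    BCF = k1 / (k2 + kE + kG + kB)   [L/kg wet weight].

The default rate-constant suite is allometric and temperature-driven:

    gill uptake efficiency  E_W = (1.85 + 155 / Kow)^-1
    ventilation             G_V = 1400 W^0.65 / C_OX          [L/d]
    k1  = E_W G_V / W
    k2  = k1 / K_FW,  K_FW = lipid_fraction * Kow (fish-water partition)
    feeding                 G_D = 0.022 W^0.85 e^(0.06 T)     [kg/d]
    diet uptake efficiency  E_D = (3e-7 Kow + 2)^-1
    kE  = 0.125 E_D G_D / W
    kG  = c W^-0.2 with c = 5e-4 (cold-water regime) or 2.51e-3 (warm)
    C_OX = saturation * 468 / (31.6 + T)                      [mg/L]

(W in kg, T in °C.)  The same suite closes the in vivo evaluation: a measured
overall depuration rate kT decomposes as kB = kT - (k2 + kE + kG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import ConfigurationError, InvalidInputError
from .ivive import ChemicalProps, FishPhysiology


@dataclass(frozen=True)
class RateConstantSuite:
    """Coefficients of the default kinetic correlations (all configurable)."""

    gill_a: float = 1.85
    gill_b: float = 155.0
    vent_coeff: float = 1400.0
    vent_exp: float = 0.65
    feed_coeff: float = 0.022
    feed_exp: float = 0.85
    feed_temp_coeff: float = 0.06
    egestion_factor: float = 0.125
    diet_eff_a: float = 3.0e-7
    diet_eff_b: float = 2.0
    growth_cold: float = 5.0e-4
    growth_warm: float = 2.51e-3
    growth_exp: float = -0.2
    ox_sat_num: float = 468.0
    ox_sat_denom: float = 31.6
    #: Optional non-lipid organic-matter contribution to the fish-water
    #: partition coefficient: K_FW = (lipid + nonlipid_sorption * nonlipid_fraction) Kow.
    nonlipid_fraction: float = 0.0
    nonlipid_sorption: float = 0.035

    def __post_init__(self) -> None:
        for name in (
            "gill_a", "gill_b", "vent_coeff", "feed_coeff", "egestion_factor",
            "diet_eff_a", "diet_eff_b", "growth_cold", "growth_warm",
            "ox_sat_num", "ox_sat_denom",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"suite coefficient {name} must be positive")


DEFAULT_SUITE = RateConstantSuite()

#: Growth regime per species: cold-water coefficient for trout, warm for carp.
GROWTH_REGIME = {"trout": "cold", "carp": "warm"}


@dataclass(frozen=True)
class RateConstants:
    """The full rate-constant vector of the mass balance (kB = 0 if absent)."""

    k1: float  # L/kg/d
    k2: float  # 1/d
    kE: float  # 1/d
    kG: float  # 1/d
    kB: float = 0.0  # 1/d

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "kE", "kG"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")

    @property
    def total_elimination(self) -> float:
        """kT = k2 + kE + kG + kB, 1/d."""
        return self.k2 + self.kE + self.kG + self.kB

    def with_kb(self, kb: float) -> "RateConstants":
        return replace(self, kB=kb)


@dataclass(frozen=True)
class BCFPrediction:
    bcf: float  # L/kg wet weight
    rates: RateConstants
    with_biotransformation: bool


@dataclass(frozen=True)
class InVivoKb:
    """Back-calculated in vivo kB; may be negative (then flagged)."""

    kb: float
    distinguishable_from_zero: bool


def dissolved_oxygen(
    temperature: float, saturation: float, suite: RateConstantSuite = DEFAULT_SUITE
) -> float:
    """Dissolved-oxygen concentration (mg/L) at a temperature and % saturation."""
    if not 0.0 <= temperature <= 35.0:
        raise ConfigurationError("temperature outside validated range 0-35 °C")
    if not 0.0 < saturation <= 1.2:
        raise InvalidInputError("saturation must be in (0, 1.2]")
    return saturation * suite.ox_sat_num / (suite.ox_sat_denom + temperature)


def gill_uptake_k1(
    phys: FishPhysiology, chem: ChemicalProps, suite: RateConstantSuite = DEFAULT_SUITE
) -> float:
    """Gill uptake rate constant k1 (L/kg/d) from ventilation and uptake efficiency."""
    c_ox = dissolved_oxygen(phys.temperature, phys.do_saturation, suite)
    if c_ox <= 0:
        raise ConfigurationError("dissolved oxygen must be positive")
    e_w = 1.0 / (suite.gill_a + suite.gill_b / chem.kow)
    g_v = suite.vent_coeff * phys.body_mass**suite.vent_exp / c_ox
    return e_w * g_v / phys.body_mass


def fish_water_partition(
    phys: FishPhysiology, chem: ChemicalProps, suite: RateConstantSuite = DEFAULT_SUITE
) -> float:
    """Fish-water partition coefficient K_FW (L/kg), lipid term plus optional NLOM term."""
    sorbing = phys.lipid_fraction + suite.nonlipid_sorption * suite.nonlipid_fraction
    k_fw = sorbing * chem.kow
    if k_fw <= 0:
        raise ConfigurationError("fish-water partition coefficient must be positive")
    return k_fw


def partition_k2(
    k1: float,
    phys: FishPhysiology,
    chem: ChemicalProps,
    suite: RateConstantSuite = DEFAULT_SUITE,
) -> float:
    """Respiratory elimination k2 = k1 / K_FW (thermodynamic closure), 1/d."""
    if k1 < 0:
        raise InvalidInputError("k1 must be non-negative")
    return k1 / fish_water_partition(phys, chem, suite)


def egestion_kE(
    phys: FishPhysiology, chem: ChemicalProps, suite: RateConstantSuite = DEFAULT_SUITE
) -> float:
    """Fecal egestion rate constant kE (1/d) from feeding rate and diet uptake efficiency."""
    g_d = (
        suite.feed_coeff
        * phys.body_mass**suite.feed_exp
        * math.exp(suite.feed_temp_coeff * phys.temperature)
    )
    e_d = 1.0 / (suite.diet_eff_a * chem.kow + suite.diet_eff_b)
    return suite.egestion_factor * e_d * g_d / phys.body_mass


def growth_kG(
    phys: FishPhysiology,
    regime: str | None = None,
    suite: RateConstantSuite = DEFAULT_SUITE,
) -> float:
    """Growth-dilution rate constant kG = c W^-0.2 (1/d).

    ``regime`` is ``"cold"`` or ``"warm"``; when omitted it is inferred from
    the species (trout -> cold, carp -> warm).
    """
    if regime is None:
        try:
            regime = GROWTH_REGIME[phys.species]
        except KeyError:
            raise ConfigurationError(
                f"no growth regime known for species {phys.species!r}; pass one"
            ) from None
    if regime == "cold":
        c = suite.growth_cold
    elif regime == "warm":
        c = suite.growth_warm
    else:
        raise ConfigurationError(f"unknown growth regime {regime!r}")
    return c * phys.body_mass**suite.growth_exp


def compute_rate_constants(
    phys: FishPhysiology,
    chem: ChemicalProps,
    suite: RateConstantSuite = DEFAULT_SUITE,
    kb: float = 0.0,
    growth_regime: str | None = None,
    kg_override: float | None = None,
) -> RateConstants:
    """Evaluate the whole default suite for one species/chemical scenario.

    ``kg_override`` substitutes a measured growth rate (e.g. from fish
    weights) for the modeled allometric kG.
    """
    k1 = gill_uptake_k1(phys, chem, suite)
    k2 = partition_k2(k1, phys, chem, suite)
    ke = egestion_kE(phys, chem, suite)
    kg = kg_override if kg_override is not None else growth_kG(phys, growth_regime, suite)
    return RateConstants(k1=k1, k2=k2, kE=ke, kG=kg, kB=kb)


def predict_bcf(rates: RateConstants) -> BCFPrediction:
    """Steady-state BCF = k1 / (k2 + kE + kG + kB), L/kg wet weight."""
    denom = rates.total_elimination
    if denom <= 0:
        raise InvalidInputError("total elimination rate must be positive")
    return BCFPrediction(
        bcf=rates.k1 / denom, rates=rates, with_biotransformation=rates.kB > 0
    )


def kb_from_depuration(kT: float, k2: float, kE: float, kG: float) -> InVivoKb:
    """Back-calculate in vivo kB = kT - (k2 + kE + kG).

    A negative result means the measured depuration is slower than the
    modeled non-metabolic elimination; it is returned as-is and flagged as
    not distinguishable from zero, never truncated.
    """
    for name, v in (("kT", kT), ("k2", k2), ("kE", kE), ("kG", kG)):
        if v < 0:
            raise InvalidInputError(f"{name} must be non-negative")
    kb = kT - (k2 + kE + kG)
    return InVivoKb(kb=kb, distinguishable_from_zero=kb > 0)


def kb_uncertainty(kb: float, uf: float) -> tuple[float, float]:
    """95 % probability range (kb/uf, kb*uf) for a multiplicative uncertainty factor."""
    if kb <= 0:
        raise InvalidInputError("kb must be positive for an uncertainty interval")
    if uf < 1:
        raise InvalidInputError("uncertainty factor must be >= 1")
    return (kb / uf, kb * uf)
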