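"""OECD TG 305 aqueous-exposure study evaluation.

Fish are exposed to a (nominally constant) water concentration for an uptake
phase, then transferred to clean water for a depuration phase; whole-body
concentrations are measured on scheduled sampling days (typically 4 fish per
day).  The evaluation computes

* the time-weighted average (TWA) water concentration over the uptake phase,
* the steady-state BCF, mean fish concentration on plateau days / TWA,
* the overall depuration rate constant kT from an exponential fit
  C_f(t) = C_f0 exp(-kT t) to the depuration-phase fish concentrations
  (log-linear OLS, the standard evaluation of the printed exponential form),
* a measured growth rate from ln(weight) vs day, and
* the in vivo biotransformation rate kB = kT - (k2 + kE + kG) via the
  mass-balance suite.

Days are real-valued and counted from the start of the respective phase; the
depuration clock restarts at transfer to clean water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError
from .ivive import ChemicalProps, FishPhysiology
from .massbalance import (
    DEFAULT_SUITE,
    InVivoKb,
    RateConstantSuite,
    compute_rate_constants,
    kb_from_depuration,
)

PHASES = ("uptake", "depuration")


@dataclass(frozen=True)
class WaterSeries:
    """Water-concentration samples of one phase (days from phase start, ng/L)."""

    days: np.ndarray
    concentrations: np.ndarray
    phase: str = "uptake"

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "concentrations", conc)
        if self.phase not in PHASES:
            raise InvalidInputError(f"unknown phase {self.phase!r}")
        if days.size != conc.size or days.ndim != 1:
            raise InvalidInputError("days and concentrations must be 1-D, equal length")
        if np.any(np.diff(days) < 0):
            raise InvalidInputError("days must be non-decreasing")
        if np.any(conc < 0):
            raise InvalidInputError("concentrations must be non-negative")


@dataclass(frozen=True)
class FishSeries:
    """Per-fish whole-body measurements.

    Wraps a DataFrame with columns ``day`` (from phase start), ``phase``,
    ``fish_id``, ``conc_ng_kg`` and ``weight_g``.
    """

    data: pd.DataFrame

    REQUIRED = ("day", "phase", "fish_id", "conc_ng_kg", "weight_g")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"fish series missing columns {missing}")
        if not set(self.data["phase"]).issubset(PHASES):
            raise InvalidInputError("phase must be 'uptake' or 'depuration'")
        if (self.data["conc_ng_kg"] < 0).any():
            raise InvalidInputError("fish concentrations must be non-negative")

    def phase_data(self, phase: str) -> pd.DataFrame:
        return self.data[self.data["phase"] == phase]


@dataclass(frozen=True)
class DepurationFit:
    kT: float  # 1/d
    cf0: float  # ng/kg at depuration start
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class BCFResult:
    bcf_ss: float  # L/kg
    cf_ss_mean: float  # ng/kg
    twa_water: float  # ng/L
    steady_state_days: tuple[float, ...]


def twa_concentration(ws: WaterSeries, window: tuple[float, float] | None = None) -> float:
    """Time-weighted average concentration over a window (default: full series).

    Interval-weighted (trapezoidal) mean; a single sample, or a window of
    zero width, returns the (mean) sampled value.
    """
    if window is None:
        lo, hi = float(ws.days[0]), float(ws.days[-1])
    else:
        lo, hi = window
    mask = (ws.days >= lo) & (ws.days <= hi)
    if not mask.any():
        raise InsufficientDataError("no water samples in window")
    d, c = ws.days[mask], ws.concentrations[mask]
    if d[-1] == d[0]:
        return float(c.mean())
    return float(np.trapezoid(c, d) / (d[-1] - d[0]))


def steady_state_bcf(
    fs: FishSeries, twa: float, plateau_days: list[float] | tuple[float, ...]
) -> BCFResult:
    """BCF_SS: mean of individual fish concentrations on plateau days over TWA."""
    if twa <= 0:
        raise InvalidInputError("TWA water concentration must be positive")
    if len(plateau_days) == 0:
        raise InvalidInputError("plateau_days must be non-empty")
    uptake = fs.phase_data("uptake")
    sel = uptake[uptake["day"].isin(plateau_days)]
    if sel.empty:
        raise InsufficientDataError("no fish sampled on the requested plateau days")
    cf = float(sel["conc_ng_kg"].mean())
    return BCFResult(
        bcf_ss=cf / twa,
        cf_ss_mean=cf,
        twa_water=twa,
        steady_state_days=tuple(sorted(set(float(d) for d in sel["day"]))),
    )


def detect_plateau(fs: FishSeries, alpha: float = 0.05, min_days: int = 3) -> tuple[float, ...]:
    """Auto-detect steady-state days in the uptake phase.

    Returns the longest terminal run of >= ``min_days`` sampling days whose
    day-mean log concentrations show no significant log-linear trend
    (OLS slope p-value >= alpha).  Falls back to the final ``min_days`` days
    when every longer run still trends.
    """
    uptake = fs.phase_data("uptake")
    means = (
        uptake[uptake["conc_ng_kg"] > 0]
        .groupby("day")["conc_ng_kg"]
        .mean()
        .sort_index()
    )
    days = means.index.to_numpy(dtype=float)
    if days.size < min_days:
        raise InsufficientDataError(f"need >= {min_days} uptake sampling days")
    logc = np.log(means.to_numpy())
    best = tuple(days[-min_days:])
    for m in range(days.size, min_days - 1, -1):
        d, y = days[-m:], logc[-m:]
        res = stats.linregress(d, y)
        if np.isnan(res.pvalue) or res.pvalue >= alpha:
            return tuple(float(x) for x in d)
    return tuple(float(x) for x in best)


def fit_depuration(fs: FishSeries) -> DepurationFit:
    """Exponential depuration fit: OLS on ln(C_f) vs days since depuration start.

    kT is minus the slope; C_f0 = exp(intercept).  Individual fish are
    independent observations (no pooling before the log transform); fish with
    non-positive concentrations are excluded with a warning.
    """
    dep = fs.phase_data("depuration")
    pos = dep[dep["conc_ng_kg"] > 0]
    n_dropped = len(dep) - len(pos)
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} non-positive depuration concentrations",
                      stacklevel=2)
    if pos["day"].nunique() < 3:
        raise InsufficientDataError("need >= 3 depuration sampling days with positive means")
    t = pos["day"].to_numpy(dtype=float)
    y = np.log(pos["conc_ng_kg"].to_numpy(dtype=float))
    res = stats.linregress(t, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return DepurationFit(
        kT=-float(res.slope),
        cf0=float(np.exp(res.intercept)),
        r_squared=r2,
        n_points=len(pos),
    )


def growth_rate(fs: FishSeries) -> float:
    """Measured growth-dilution rate: OLS slope of ln(weight) vs study day (1/d).

    Depuration-phase days are offset by the last uptake sampling day so that
    all weights sit on one study clock.
    """
    data = fs.data[fs.data["weight_g"] > 0].copy()
    if data.empty or data["day"].nunique() < 2:
        raise InsufficientDataError("need weights on >= 2 days")
    uptake_end = (
        float(fs.phase_data("uptake")["day"].max()) if "uptake" in set(data["phase"]) else 0.0
    )
    day = np.where(data["phase"] == "depuration", data["day"] + uptake_end, data["day"])
    if np.unique(day).size < 2:
        raise InsufficientDataError("need weights on >= 2 distinct days")
    res = stats.linregress(day.astype(float), np.log(data["weight_g"].to_numpy(dtype=float)))
    return float(res.slope)


@dataclass(frozen=True)
class StudyEvaluation:
    """Bundle of the full TG 305 evaluation for one species/chemical."""

    bcf: BCFResult
    depuration: DepurationFit
    kg_measured: float
    in_vivo_kb: InVivoKb
    k2: float
    kE: float
    kG: float


def analyze_study(
    water: WaterSeries,
    fish: FishSeries,
    phys: FishPhysiology,
    chem: ChemicalProps,
    plateau_days: list[float] | None = None,
    suite: RateConstantSuite = DEFAULT_SUITE,
    use_measured_growth: bool = False,
) -> StudyEvaluation:
    """End-to-end TG 305 evaluation: TWA -> BCF_SS -> kT -> in vivo kB.

    The non-metabolic elimination terms (k2, kE, kG) come from the
    mass-balance suite parameterized with the study physiology; with
    ``use_measured_growth`` the modeled kG is replaced by the slope of
    ln(weight) vs day.
    """
    twa = twa_concentration(water)
    days = tuple(plateau_days) if plateau_days else detect_plateau(fish)
    bcf = steady_state_bcf(fish, twa, list(days))
    dep = fit_depuration(fish)
    kg_meas = growth_rate(fish)
    rates = compute_rate_constants(
        phys, chem, suite, kg_override=max(kg_meas, 0.0) if use_measured_growth else None
    )
    kb = kb_from_depuration(dep.kT, rates.k2, rates.kE, rates.kG)
    return StudyEvaluation(
        bcf=bcf,
        depuration=dep,
        kg_measured=kg_meas,
        in_vivo_kb=kb,
        k2=rates.k2,
        kE=rates.kE,
        kG=rates.kG,
    )
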