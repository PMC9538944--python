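"""Synthetic depletion assays and TG 305 studies with known ground truth.

Every estimator in the package has a forward model here that generates the
kind of data it consumes, so parameter-recovery tests need no external data.
Concentration noise is multiplicative lognormal with unit mean and a
specified coefficient of variation — the convention for analytical-chemistry
scatter, and the form under which log-space regression is unbiased.

A single master seed fans out to independent substreams (one per replicate /
fish / water sample block) via :class:`numpy.random.SeedSequence`, so
enlarging one part of a scenario does not perturb the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depletion import STANDARD_TIMES_H, DepletionTimecourse
from .errors import InvalidInputError
from .tg305 import FishSeries, WaterSeries

#: Default intra-assay noise for MXC-like scenarios (internal standard available).
DEFAULT_DEPLETION_CV = 0.10
#: Higher default scatter for BaP-like scenarios (no internal standard).
BAP_DEPLETION_CV = 0.15


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the requested CV."""
    if cv < 0:
        raise InvalidInputError("noise CV must be non-negative")
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class DepletionScenario:
    """Ground truth for one simulated in vitro run.

    Defaults mirror the assay design: the 8-point 5-240 min sampling grid,
    triplicate live incubations at 2 µM starting substrate, 10 % multiplicative
    noise, and a small constant-rate abiotic loss in the heat-inactivated
    control (2 % of a typical live rate).
    """

    k_true: float = 0.5  # 1/h
    c0: float = 2.0  # µM
    times: tuple[float, ...] = STANDARD_TIMES_H
    n_replicates: int = 3
    noise_cv: float = DEFAULT_DEPLETION_CV
    dead_loss_rate: float = 0.01  # 1/h, abiotic loss in the control
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 0 or self.noise_cv < 0 or self.dead_loss_rate < 0:
            raise InvalidInputError("rates and noise CV must be non-negative")
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")


def simulate_depletion(
    sc: DepletionScenario,
    species: str = "trout",
    chemical: str = "MXC",
    cell_state: str = "fresh",
) -> tuple[list[DepletionTimecourse], DepletionTimecourse]:
    """Simulate one run: live triplicates plus a heat-inactivated control.

    Returns ``(live_replicates, inactivated_control)``.  Identical seeds give
    bitwise-identical output.
    """
    t = np.asarray(sc.times, dtype=float)
    streams = np.random.SeedSequence(sc.seed).spawn(sc.n_replicates + 1)
    live = []
    for r in range(sc.n_replicates):
        rng = np.random.default_rng(streams[r])
        clean = sc.c0 * np.exp(-sc.k_true * t)
        conc = clean * _lognormal_factors(rng, sc.noise_cv, t.size)
        live.append(
            DepletionTimecourse(
                run_id=f"sim-{sc.seed}",
                species=species,
                chemical=chemical,
                cell_state=cell_state,
                condition="live",
                replicate_id=r + 1,
                times=t,
                concentrations=conc,
            )
        )
    rng = np.random.default_rng(streams[-1])
    control = sc.c0 * np.exp(-sc.dead_loss_rate * t)
    control = control * _lognormal_factors(rng, sc.noise_cv, t.size)
    inactivated = DepletionTimecourse(
        run_id=f"sim-{sc.seed}",
        species=species,
        chemical=chemical,
        cell_state=cell_state,
        condition="inactivated",
        replicate_id=1,
        times=t,
        concentrations=control,
    )
    return live, inactivated


@dataclass(frozen=True)
class StudyScenario:
    """Ground truth for one simulated TG 305 study.

    ``kT`` is implied: kT = k2 + kE + kG + kB.  Fish concentrations follow
    the one-compartment solution

        uptake:     C_f(t) = (k1 C_w / kT) (1 - e^(-kT t))
        depuration: C_f(t') = C_f(T_up) e^(-kT t')

    with per-fish lognormal noise; water samples scatter lognormally around
    ``water_mean``; weights grow exponentially at ``kg_weight``.  Defaults
    reproduce the study design: 35 d uptake (sampling days 0, 7, 14, 21, 28,
    31, 35), 35 d depuration (days 4, 10, 21, 35), 4 fish per sampling day,
    water sampled three times per week.
    """

    k1: float = 325.0  # L/kg/d
    k2: float = 0.028  # 1/d
    kE: float = 0.0076  # 1/d
    kG: float = 0.0047  # 1/d
    kB: float = 0.08  # 1/d
    water_mean: float = 7.0  # ng/L
    water_cv: float = 0.20
    uptake_days: float = 35.0
    depuration_days: float = 35.0
    uptake_schedule: tuple[float, ...] = (0.0, 7.0, 14.0, 21.0, 28.0, 31.0, 35.0)
    depuration_schedule: tuple[float, ...] = (4.0, 10.0, 21.0, 35.0)
    fish_per_day: int = 4
    fish_noise_cv: float = 0.15
    initial_weight_g: float = 20.0
    kg_weight: float = 0.005  # 1/d exponential weight growth
    weight_noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "kE", "kG", "kB", "water_mean"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if max(self.uptake_schedule) > self.uptake_days or max(
            self.depuration_schedule
        ) > self.depuration_days:
            raise InvalidInputError("sampling schedules must lie within phase lengths")

    @property
    def kT(self) -> float:
        return self.k2 + self.kE + self.kG + self.kB

    @property
    def plateau_days(self) -> tuple[float, ...]:
        """The final three uptake sampling days (the design's steady-state window)."""
        return tuple(sorted(self.uptake_schedule)[-3:])

    @property
    def true_bcf_ss(self) -> float:
        """Noise-free value of the plateau-mean BCF_SS estimator under this design."""
        cf = np.mean([self.cf_uptake(d) for d in self.plateau_days])
        return float(cf / self.water_mean)

    def cf_uptake(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.k1 * self.water_mean / self.kT * (1.0 - np.exp(-self.kT * np.asarray(t)))

    def cf_depuration(self, t_prime: np.ndarray | float) -> np.ndarray | float:
        c_end = self.cf_uptake(self.uptake_days)
        return c_end * np.exp(-self.kT * np.asarray(t_prime))


def simulate_tg305(sc: StudyScenario) -> tuple[WaterSeries, FishSeries]:
    """Simulate one aqueous-exposure study (uptake-phase water series + fish)."""
    ss_water, ss_fish_up, ss_fish_dep, ss_weight = np.random.SeedSequence(sc.seed).spawn(4)

    water_days = np.arange(0.0, sc.uptake_days + 1e-9, 7.0 / 3.0)
    rng = np.random.default_rng(ss_water)
    water_conc = sc.water_mean * _lognormal_factors(rng, sc.water_cv, water_days.size)
    water = WaterSeries(days=water_days, concentrations=water_conc, phase="uptake")

    rows = []
    fish_counter = 0
    rng_up = np.random.default_rng(ss_fish_up)
    rng_dep = np.random.default_rng(ss_fish_dep)
    rng_w = np.random.default_rng(ss_weight)
    for phase, schedule, rng_c, offset in (
        ("uptake", sc.uptake_schedule, rng_up, 0.0),
        ("depuration", sc.depuration_schedule, rng_dep, sc.uptake_days),
    ):
        for day in schedule:
            clean = sc.cf_uptake(day) if phase == "uptake" else sc.cf_depuration(day)
            noise = _lognormal_factors(rng_c, sc.fish_noise_cv, sc.fish_per_day)
            w_clean = sc.initial_weight_g * np.exp(sc.kg_weight * (day + offset))
            w_noise = _lognormal_factors(rng_w, sc.weight_noise_cv, sc.fish_per_day)
            for i in range(sc.fish_per_day):
                fish_counter += 1
                rows.append(
                    {
                        "day": float(day),
                        "phase": phase,
                        "fish_id": f"F{fish_counter:04d}",
                        "conc_ng_kg": float(clean * noise[i]),
                        "weight_g": float(w_clean * w_noise[i]),
                    }
                )
    return water, FishSeries(pd.DataFrame(rows))


def recovery_report(
    scenarios,
    n_seeds: int = 100,
    master_seed: int = 0,
    estimator=None,
) -> pd.DataFrame:
    """Relative bias and RMSE of recovered parameters over a scenario grid.

    ``scenarios`` is an iterable of :class:`DepletionScenario` or
    :class:`StudyScenario`; each is re-simulated ``n_seeds`` times with seeds
    derived from ``master_seed``, the matching estimator is run, and the
    per-scenario relative bias and relative RMSE of the recovered parameter
    (k for depletion scenarios; kT and BCF_SS for study scenarios) are
    tabulated against the ground truth.
    """
    from dataclasses import replace as _replace

    from .depletion import estimate_clearance
    from .tg305 import fit_depuration, steady_state_bcf, twa_concentration

    if n_seeds < 10:
        raise InvalidInputError("need >= 10 seeds for a recovery report")
    scenarios = list(scenarios)
    if not scenarios:
        raise InvalidInputError("need >= 1 scenario")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_seeds) % (2**31)
    records = []
    for i, sc in enumerate(scenarios):
        if isinstance(sc, DepletionScenario):
            truth = sc.k_true
            est = np.array(
                [
                    (estimator or (lambda l, d: estimate_clearance(l, d).k))(
                        *simulate_depletion(_replace(sc, seed=int(s)))
                    )
                    for s in seeds
                ]
            )
            rel = (est - truth) / truth if truth else est
            records.append(
                {
                    "scenario": i,
                    "kind": "depletion",
                    "parameter": "k",
                    "truth": truth,
                    "rel_bias": float(np.mean(rel)),
                    "median_rel_bias": float(np.median(rel)),
                    "rel_rmse": float(np.sqrt(np.mean(rel**2))),
                    "n_seeds": n_seeds,
                }
            )
        elif isinstance(sc, StudyScenario):
            kts, bcfs = [], []
            for s in seeds:
                water, fish = simulate_tg305(_replace(sc, seed=int(s)))
                kts.append(fit_depuration(fish).kT)
                twa = twa_concentration(water)
                bcfs.append(steady_state_bcf(fish, twa, list(sc.plateau_days)).bcf_ss)
            for name, est_vals, truth in (
                ("kT", np.array(kts), sc.kT),
                ("bcf_ss", np.array(bcfs), sc.true_bcf_ss),
            ):
                rel = (est_vals - truth) / truth
                records.append(
                    {
                        "scenario": i,
                        "kind": "tg305",
                        "parameter": name,
                        "truth": truth,
                        "rel_bias": float(np.mean(rel)),
                        "median_rel_bias": float(np.median(rel)),
                        "rel_rmse": float(np.sqrt(np.mean(rel**2))),
                        "n_seeds": n_seeds,
                    }
                )
        else:
            raise InvalidInputError(f"unknown scenario type {type(sc).__name__}")
    return pd.DataFrame.from_records(records)
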