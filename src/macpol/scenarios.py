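"""The three challenge experiments and the statistical-ensemble layer.

Scenarios
---------
``gram_negative``
    An LPS-carrying (Gram-negative) bacterium is injected at step 0 and
    replicates; the expected outcome is an M1/Th1-polarized response that
    controls the infection.
``vaccine_il4``
    An antigen without LPS (an inactivated vaccine) is injected at step 0
    (no replication); from day 3, daily for a week, IL-4 is injected
    (standing in for basophil/mast-cell input), driving M2 polarization.
``bacterium_il10``
    The Gram-negative infection of the first scenario, but from day 3, daily
    for a week, IL-10 is injected (IL-10 from non-macrophage sources, e.g.
    mast-cell degranulation).  M2 commitment of macrophages then withdraws
    IFNg secretion from the activation loop and, in a seed-dependent fraction
    of replicates, the response is too weak to control the bacterium.

An ensemble is a set of replicates differing only in their seed
(``base_seed + r``); per-step mean and standard deviation of every census
series, and a controlled/dampened outcome label per replicate, summarize it.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import InjectionEvent, SimulationConfig
from .engine import CENSUS_COLUMNS, run, total
from .errors import ConfigurationError

SCENARIO_NAMES = ("gram_negative", "vaccine_il4", "bacterium_il10")

#: Bacterial inoculum (tokens at step 0); large enough to establish an
#: infection against baseline phagocytic/B-cell consumption.
DEFAULT_AG_DOSE = 8000
#: Vaccine bolus; larger than the bacterial inoculum because an inactivated
#: antigen does not replicate and must persist into the IL-4 window.
VACCINE_AG_DOSE = 36000
#: Daily IL-4 dose of the vaccine scenario (tokens/day, days 3..9).
DEFAULT_IL4_DOSE = 16000
#: Calibrated daily IL-10 dose of the dampening scenario (see
#: calibrate_dampening and docs/methods.md for the calibration grid).
DEFAULT_IL10_DOSE = 5000


@dataclass(frozen=True)
class Scenario:
    name: str
    config: SimulationConfig

    def replicate_config(self, seed: int) -> SimulationConfig:
        cfg = copy.deepcopy(self.config)
        cfg.seed = seed
        return cfg


def _daily(species: str, dose: int, start_day: int, n_days: int, spd: int) -> list[InjectionEvent]:
    return [
        InjectionEvent(step=(start_day + d) * spd, species=species, amount=dose)
        for d in range(n_days)
    ]


def gram_negative(ag_dose: int = DEFAULT_AG_DOSE, **overrides) -> Scenario:
    cfg = SimulationConfig(
        injections=[InjectionEvent(step=0, species="Ag", amount=ag_dose, has_lps=True)],
        **overrides,
    )
    return Scenario("gram_negative", cfg)


def vaccine_il4(
    ag_dose: int = VACCINE_AG_DOSE,
    il4_dose: int = DEFAULT_IL4_DOSE,
    start_day: int = 3,
    n_days: int = 7,
    **overrides,
) -> Scenario:
    overrides.setdefault("ag_replication_prob", 0.0)  # inactivated antigen
    spd = overrides.get("steps_per_day", SimulationConfig.model_fields["steps_per_day"].default)
    cfg = SimulationConfig(
        injections=[InjectionEvent(step=0, species="Ag", amount=ag_dose, has_lps=False)]
        + _daily("IL4", il4_dose, start_day, n_days, spd),
        **overrides,
    )
    return Scenario("vaccine_il4", cfg)


def bacterium_il10(
    ag_dose: int = DEFAULT_AG_DOSE,
    il10_dose: int = DEFAULT_IL10_DOSE,
    start_day: int = 3,
    n_days: int = 7,
    **overrides,
) -> Scenario:
    spd = overrides.get("steps_per_day", SimulationConfig.model_fields["steps_per_day"].default)
    cfg = SimulationConfig(
        injections=[InjectionEvent(step=0, species="Ag", amount=ag_dose, has_lps=True)]
        + _daily("IL10", il10_dose, start_day, n_days, spd),
        **overrides,
    )
    return Scenario("bacterium_il10", cfg)


_FACTORIES: dict[str, Callable[..., Scenario]] = {
    "gram_negative": gram_negative,
    "vaccine_il4": vaccine_il4,
    "bacterium_il10": bacterium_il10,
}


def make_scenario(name: str, **kwargs) -> Scenario:
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise ConfigurationError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}") from None
    return factory(**kwargs)


#: Population/lattice overrides for a reduced desk-scale volume with the same
#: agent densities as the default 9^3 volume (used for quick looks and very
#: large ensembles).
REDUCED_SCALE = dict(
    L=7, n_macrophages=235, n_bcells=294, n_h1=294, n_h2=294, n_hr=294, n_steps=800
)


def reduced(name: str, **kwargs) -> Scenario:
    """A scenario at the reduced desk-scale volume (same densities, L=7)."""
    scale = dict(REDUCED_SCALE)
    scale.update({k: kwargs.pop(k) for k in list(kwargs) if k in scale})
    factor = scale["L"] ** 3 / SimulationConfig.model_fields["L"].default ** 3
    kwargs.setdefault("ag_dose", max(1, round(DEFAULT_AG_DOSE * factor)))
    if name == "vaccine_il4":
        kwargs.setdefault("il4_dose", max(1, round(DEFAULT_IL4_DOSE * factor)))
    if name == "bacterium_il10":
        kwargs.setdefault("il10_dose", max(1, round(DEFAULT_IL10_DOSE * factor)))
    return make_scenario(name, **kwargs, **scale)


# ---------------------------------------------------------------------------
# Outcome classification
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class OutcomePolicy:
    """Dampened iff the final antigen count is at least ``ratio`` times the
    antigen count at the census row of the (step-``reference_step``)
    injection; controlled otherwise."""

    reference_step: int = 0
    ratio: float = 1.0


def classify_outcome(ts: pd.DataFrame, policy: OutcomePolicy = OutcomePolicy()) -> str:
    if len(ts) == 0:
        raise ValueError("empty time series")
    ag = total(ts, "Ag")
    reference = float(ag.iloc[policy.reference_step])
    final = float(ag.iloc[-1])
    return "dampened" if final >= policy.ratio * reference else "controlled"


@dataclass
class EnsembleResult:
    scenario_name: str
    seeds: list[int]
    replicates: list[pd.DataFrame]
    mean: pd.DataFrame
    sd: pd.DataFrame
    outcomes: list[str]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def dampened_fraction(self) -> float:
        return dampened_fraction(self)

    def summary(self) -> dict:
        last = [ts.iloc[-1] for ts in self.replicates]
        return {
            "scenario": self.scenario_name,
            "n_replicates": self.n_replicates,
            "dampened_fraction": self.dampened_fraction,
            "final_m1_mean": float(np.mean([total(ts, "M1").iloc[-1] for ts in self.replicates])),
            "final_m2_mean": float(np.mean([total(ts, "M2").iloc[-1] for ts in self.replicates])),
            "final_ag_mean": float(np.mean([total(ts, "Ag").iloc[-1] for ts in self.replicates])),
        }


def run_scenario(
    scenario: Scenario,
    n_replicates: int,
    base_seed: int,
    policy: OutcomePolicy = OutcomePolicy(),
    progress: bool = False,
) -> EnsembleResult:
    """Run a seeded ensemble: replicate r uses seed ``base_seed + r``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = [base_seed + r for r in range(n_replicates)]
    replicates = []
    for s in seeds:
        replicates.append(run(scenario.replicate_config(s)))
        if progress:  # pragma: no cover - cosmetic
            print(f"  replicate seed={s} done", flush=True)
    stack = np.stack([ts[list(CENSUS_COLUMNS)].to_numpy(dtype=float) for ts in replicates])
    mean = pd.DataFrame(stack.mean(axis=0), columns=list(CENSUS_COLUMNS))
    sd = pd.DataFrame(stack.std(axis=0, ddof=0), columns=list(CENSUS_COLUMNS))
    for frame in (mean, sd):
        frame.insert(0, "step", replicates[0]["step"].to_numpy())
    outcomes = [classify_outcome(ts, policy) for ts in replicates]
    return EnsembleResult(scenario.name, seeds, replicates, mean, sd, outcomes)


def dampened_fraction(result: EnsembleResult) -> float:
    """Fraction of replicates in which the antigen was not controlled."""
    return result.outcomes.count("dampened") / len(result.outcomes)


# ---------------------------------------------------------------------------
# Calibration of the IL-10 dose
# ---------------------------------------------------------------------------
def calibrate_dampening(
    doses: Sequence[int],
    n_replicates: int,
    base_seed: int,
    target: float = 0.43,
    reduced_scale: bool = False,
    **scenario_kwargs,
) -> tuple[pd.DataFrame, int]:
    """Grid-search the daily IL-10 dose of ``bacterium_il10``.

    Runs an ensemble per dose level (at most 10 levels) and returns the
    dose-response table and the dose whose dampened fraction is closest to
    ``target``.  Each dose level uses its own seed block so ensembles do not
    share randomness.
    """
    if len(doses) > 10:
        raise ValueError("calibration grid is limited to 10 dose levels")
    rows = []
    for i, dose in enumerate(doses):
        if reduced_scale:
            sc = reduced("bacterium_il10", il10_dose=int(dose), **scenario_kwargs)
        else:
            sc = bacterium_il10(il10_dose=int(dose), **scenario_kwargs)
        res = run_scenario(sc, n_replicates, base_seed + 10_000 * i)
        rows.append({"il10_dose": int(dose), "dampened_fraction": res.dampened_fraction,
                     "n_replicates": n_replicates})
    table = pd.DataFrame(rows)
    best = int(table.loc[(table["dampened_fraction"] - target).abs().idxmin(), "il10_dose"])
    return table, best
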