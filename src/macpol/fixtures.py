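"""Deterministic fixture generators for tests and examples.

Each family builds a small object entirely in memory so parsers, schedulers
and aggregators can be tested without running an experiment.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import CENSUS_COLUMNS
from .grn import RegulatoryNetwork
from .rules import CellAgent, SiteContents


def make_fixture(family: str, rng: np.random.Generator, **kwargs):
    """Build one named fixture family; deterministic given the generator state.

    Families: ``random_network`` (random signed network with the four
    canonical inputs), ``micro_lattice`` (a single prepared site),
    ``timeseries`` (synthetic census with a prescribed antigen trend).
    """
    try:
        builder = _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown fixture family {family!r}") from None
    return builder(rng, **kwargs)


def _random_network(rng: np.random.Generator, n_internal: int = 8) -> RegulatoryNetwork:
    inputs = ["IFNg", "IL10", "IL4", "LPS"]
    internal = [f"G{i}" for i in range(n_internal)]
    nodes = inputs + internal
    roles = {n: "input" for n in inputs} | {n: "internal" for n in internal}
    phen = {n: ("M1" if i % 2 == 0 else "M2") for i, n in enumerate(nodes)}
    activators: dict[str, set[str]] = {}
    inhibitors: dict[str, set[str]] = {}
    for tgt in internal:
        parents = rng.choice(nodes, size=2, replace=False)
        for p in parents:
            if p == tgt:
                continue
            (activators if rng.random() < 0.7 else inhibitors).setdefault(tgt, set()).add(str(p))
    # guarantee the marker nodes exist and have at least one activator
    activators.setdefault(internal[0], set()).add("IFNg")
    activators.setdefault(internal[-1], set()).add("IL4")
    return RegulatoryNetwork(
        nodes=tuple(nodes),
        roles=roles,
        phenotype=phen,
        activators={k: frozenset(v) for k, v in activators.items()},
        inhibitors={k: frozenset(v - activators.get(k, set())) for k, v in inhibitors.items()},
        markers={"M1": internal[0], "M2": internal[-1]},
    )


def _micro_lattice(rng: np.random.Generator, recipe: str = "r1") -> SiteContents:
    """A one-site configuration in which a single known rule firing is forced."""
    recipes = {
        # resting macrophage + one IFNg token: only R1 can fire
        "r1": SiteContents(
            agents=[CellAgent(kind="M", activation="r")], tokens={"IFNg": 1}
        ),
        # presenting type-1-committed macrophage + active Th1: R5 releases IFNg
        "r5": SiteContents(
            agents=[
                CellAgent(kind="M", activation="p", phenotype="M1"),
                CellAgent(kind="H1", activation="a"),
            ],
            tokens={},
        ),
        # presenting B cell + active Th1: R10 duplicates both and releases IFNg+Ab
        "r10": SiteContents(
            agents=[CellAgent(kind="B", activation="p"), CellAgent(kind="H1", activation="a")],
            tokens={},
        ),
        # one antibody + one antigen: R15 annihilates both
        "r15": SiteContents(agents=[], tokens={"Ab": 1, "Ag_lps": 1}),
    }
    try:
        return recipes[recipe]
    except KeyError:
        raise ValueError(f"unknown micro-lattice recipe {recipe!r}") from None


def _timeseries(
    rng: np.random.Generator, n_steps: int = 50, ag_trend: str = "dampened"
) -> pd.DataFrame:
    """Synthetic census whose antigen series grows (dampened) or collapses
    (controlled); other columns are arbitrary small counts."""
    steps = np.arange(n_steps + 1)
    ts = pd.DataFrame(
        rng.integers(0, 5, size=(n_steps + 1, len(CENSUS_COLUMNS))),
        columns=list(CENSUS_COLUMNS),
    )
    if ag_trend == "dampened":
        ag = 100 + 5 * steps
    elif ag_trend == "controlled":
        ag = np.maximum(0, 100 - 10 * steps)
    else:
        raise ValueError(f"unknown ag_trend {ag_trend!r}")
    ts["Ag_lps"] = ag
    ts["Ag_plain"] = 0
    ts.insert(0, "step", steps)
    return ts


_FAMILIES = {
    "random_network": _random_network,
    "micro_lattice": _micro_lattice,
    "timeseries": _timeseries,
}
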