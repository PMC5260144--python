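"""Reactive lattice-gas automaton on a periodic L x L x L lattice.

Each simulation step runs five phases in a fixed order:

1. **reactions** - one random rule order is drawn for the step and the rules
   are applied greedily at every site (rules are strictly local, so sites are
   independent within the phase);
2. **differentiation** - every eligible M0 macrophage (active or presenting)
   clamps the local input vector onto its embedded Boolean network, advances
   it ``k`` synchronous updates, and commits terminally if it lands on the M1
   or M2 attractor;
3. **diffusion** - every agent and every molecule token independently moves
   to one of the six von-Neumann neighbours or stays put, each of the seven
   outcomes equally likely, with periodic wrap - one identical kernel for all
   species ("equal speed");
4. **bookkeeping** - scheduled injections, antigen replication (logistic,
   per-site saturation), molecule decay, and low-rate innate stimulation of
   resting helper cells;
5. **census** - one row of population counts is appended to the time series.

The engine is array-based: agents live in parallel numpy arrays, molecule
counts in per-species integer grids, and macrophage network states as packed
integers advanced through the compiled transition table, so a full default
run (3 000 agents, 800 steps) takes seconds.  A conservation audit is always
on: every change to the census is attributed to a rule firing, a commitment,
an injection, a replication or a decay event, and the predicted per-step
census delta must reconcile exactly with the observed one (diffusion moves
entities but never changes counts).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import InjectionEvent, SimulationConfig
from .errors import AuditError, ConfigurationError
from .grn import CompiledNetwork, RegulatoryNetwork
from .network_io import load_default_network, load_network
from .rng import RngStreams
from .rules import (
    ACT_CODE,
    KIND_CODE,
    SPECIES,
    SPECIES_CODE,
    _KIND_CLASS,
    CellAgent,
    CellPattern,
    ReactionRule,
    RuleParams,
    SiteContents,
    build_rule_table,
)

log = logging.getLogger(__name__)

CELL_COLUMNS = (
    "M0_r", "M0_a", "M0_p",
    "M1_r", "M1_a", "M1_p",
    "M2_r", "M2_a", "M2_p",
    "B_a", "B_p",
    "H1_r", "H1_a", "H2_r", "H2_a", "Hr_r", "Hr_a",
)
TOKEN_COLUMNS = SPECIES  # IFNg, IL4, IL10, Ab, Ag_lps, Ag_plain
CENSUS_COLUMNS = CELL_COLUMNS + TOKEN_COLUMNS

_N_CELL = len(CELL_COLUMNS)
_N_COLS = len(CENSUS_COLUMNS)

S_IFNG, S_IL4, S_IL10, S_AB, S_AGL, S_AGP = range(6)
_CYTOKINES = (S_IFNG, S_IL4, S_IL10)


def cell_class_index(kind: np.ndarray, act: np.ndarray, phen: np.ndarray) -> np.ndarray:
    """Map (kind, activation, phenotype) codes to census column indices."""
    out = np.empty(kind.shape, dtype=np.int64)
    is_m = kind == 0
    out[is_m] = phen[is_m] * 3 + act[is_m]
    is_b = kind == 1
    out[is_b] = 9 + (act[is_b] == 2)
    is_h = kind >= 2
    out[is_h] = 11 + (kind[is_h] - 2) * 2 + (act[is_h] == 1)
    return out


# ---------------------------------------------------------------------------
# Simulation state
# ---------------------------------------------------------------------------
@dataclass
class SimState:
    """Mutable array-of-records state of one replicate."""

    L: int
    kind: np.ndarray        # int8, agent kind code
    act: np.ndarray         # int8, activation code
    phen: np.ndarray        # int8, macrophage phenotype code (0 for others)
    site: np.ndarray        # int64, flat site index in [0, L^3)
    grn: np.ndarray         # uint32, packed network state (macrophages)
    grids: np.ndarray       # int64 (n_species, L^3) token counts
    used: np.ndarray = field(default=None)      # bool, per-step participation
    priority: np.ndarray = field(default=None)  # float64, per-step selection ranks
    headroom: int | None = None                 # remaining lymphocyte births allowed

    @property
    def n_sites(self) -> int:
        return self.L ** 3

    @property
    def n_agents(self) -> int:
        return self.kind.size

    def census(self) -> np.ndarray:
        row = np.zeros(_N_COLS, dtype=np.int64)
        if self.n_agents:
            cls = cell_class_index(self.kind, self.act, self.phen)
            row[:_N_CELL] = np.bincount(cls, minlength=_N_CELL)
        row[_N_CELL:] = self.grids.sum(axis=1)
        if (self.grids < 0).any():
            raise AuditError("negative token count")
        return row

    def append_agents(self, kind, act, phen, site, grn) -> None:
        self.kind = np.concatenate([self.kind, kind.astype(np.int8)])
        self.act = np.concatenate([self.act, act.astype(np.int8)])
        self.phen = np.concatenate([self.phen, phen.astype(np.int8)])
        self.site = np.concatenate([self.site, site.astype(np.int64)])
        self.grn = np.concatenate([self.grn, grn.astype(np.uint32)])
        if self.used is not None:
            # newborns have already reacted (they are products)
            self.used = np.concatenate([self.used, np.ones(kind.size, dtype=bool)])
        if self.priority is not None:
            self.priority = np.concatenate([self.priority, np.full(kind.size, np.inf)])


# ---------------------------------------------------------------------------
# Pattern matching and per-site selection
# ---------------------------------------------------------------------------
def _match_mask(state: SimState, pat: CellPattern) -> np.ndarray:
    kinds = _KIND_CLASS[pat.kind]
    mask = np.isin(state.kind, kinds) if len(kinds) > 1 else (state.kind == kinds[0])
    mask &= state.act == ACT_CODE[pat.activation]
    ph = pat.phenotype
    if ph is not None:
        if ph.startswith("~"):
            mask &= state.phen != int(ph[1])
        else:
            mask &= state.phen == int(ph)
    return mask


def _select_per_site(
    idx: np.ndarray, sites: np.ndarray, quota: np.ndarray, priority: np.ndarray
) -> np.ndarray:
    """Pick, per site, the ``quota[site]`` candidates with smallest priority.

    The priorities are i.i.d. uniform draws refreshed every step, so the
    selection is a uniform random choice among the matching agents."""
    if idx.size == 0:
        return idx
    order = np.lexsort((priority[idx], sites))
    si = sites[order]
    starts = np.r_[0, np.flatnonzero(si[1:] != si[:-1]) + 1]
    counts = np.diff(np.r_[starts, si.size])
    ranks = np.arange(si.size) - np.repeat(starts, counts)
    return idx[order[ranks < quota[si]]]


# ---------------------------------------------------------------------------
# Reaction phase
# ---------------------------------------------------------------------------
def _token_avail(state: SimState, species: str) -> np.ndarray:
    if species == "Ag":
        return state.grids[S_AGL] + state.grids[S_AGP]
    return state.grids[SPECIES_CODE[species]]


def _consume_tokens(
    state: SimState, species: str, n: np.ndarray, rng: np.random.Generator, delta: np.ndarray
) -> None:
    if species == "Ag":
        lps, plain = state.grids[S_AGL], state.grids[S_AGP]
        hot = n > 0
        take_l = np.zeros_like(n)
        if hot.any():
            take_l[hot] = rng.hypergeometric(lps[hot], plain[hot], n[hot])
        state.grids[S_AGL] -= take_l
        state.grids[S_AGP] -= n - take_l
        delta[_N_CELL + S_AGL] -= int(take_l.sum())
        delta[_N_CELL + S_AGP] -= int((n - take_l).sum())
    else:
        code = SPECIES_CODE[species]
        state.grids[code] -= n
        delta[_N_CELL + code] -= int(n.sum())


def _fire_rule(
    state: SimState,
    rule: ReactionRule,
    rng: np.random.Generator,
    staged: np.ndarray,
    delta: np.ndarray,
) -> int:
    S = state.n_sites
    avail: np.ndarray | None = None
    cand: list[np.ndarray] = []
    for pat in rule.cell_reactants:
        idx = np.flatnonzero(_match_mask(state, pat) & ~state.used)
        cand.append(idx)
        cnt = np.bincount(state.site[idx], minlength=S)
        avail = cnt if avail is None else np.minimum(avail, cnt)
    for sp in rule.token_reactants:
        cnt = _token_avail(state, sp)
        avail = cnt.copy() if avail is None else np.minimum(avail, cnt)
    if avail is None or not avail.any():
        return 0
    if rule.probability >= 1.0:
        n_fire = avail
    else:
        n_fire = rng.binomial(avail, rule.probability)
    total = int(n_fire.sum())
    if total == 0:
        return 0
    for pat, prod, idx in zip(rule.cell_reactants, rule.cell_products, cand):
        sel = _select_per_site(idx, state.site[idx], n_fire, state.priority)
        before = cell_class_index(state.kind[sel], state.act[sel], state.phen[sel])
        np.subtract.at(delta, before, 1)
        if prod.kind is not None:
            state.kind[sel] = KIND_CODE[prod.kind]
        state.act[sel] = ACT_CODE[prod.activation]
        if prod.phenotype is not None:
            state.phen[sel] = int(prod.phenotype)
        state.used[sel] = True
        after = cell_class_index(state.kind[sel], state.act[sel], state.phen[sel])
        np.add.at(delta, after, 1)
        if prod.copies > 1:
            # homeostatic cap: the reaction still fires (secretion above),
            # but proliferation saturates once the headroom is exhausted
            for _ in range(prod.copies - 1):
                dup = sel
                if state.headroom is not None:
                    dup = sel[: max(0, state.headroom)]
                    state.headroom -= dup.size
                if dup.size == 0:
                    continue
                state.append_agents(
                    state.kind[dup],
                    state.act[dup],
                    np.zeros(dup.size, dtype=np.int8),
                    state.site[dup],
                    np.zeros(dup.size, dtype=np.uint32),
                )
                born = cell_class_index(
                    state.kind[-dup.size:], state.act[-dup.size:], state.phen[-dup.size:]
                )
                np.add.at(delta, born, 1)
    for sp in rule.token_reactants:
        _consume_tokens(state, sp, n_fire, rng, delta)
    for sp in rule.token_products:
        code = SPECIES_CODE[sp] if sp != "Ag" else S_AGP
        staged[code] += n_fire
        delta[_N_CELL + code] += total
    return total


def apply_rule_phase(
    state: SimState,
    rules: list[ReactionRule],
    order: np.ndarray,
    rng: np.random.Generator,
    delta: np.ndarray,
) -> dict[int, int]:
    """Apply all rules in the given order; returns firing counts by rule id.

    Tokens produced during the phase are staged and merged afterwards, so a
    product token never reacts in the step it was produced."""
    state.used = np.zeros(state.n_agents, dtype=bool)
    state.priority = rng.random(state.n_agents)
    staged = np.zeros_like(state.grids)
    firings: dict[int, int] = {}
    for ri in order:
        rule = rules[int(ri)]
        n = _fire_rule(state, rule, rng, staged, delta)
        if n:
            firings[rule.rule_id] = firings.get(rule.rule_id, 0) + n
    state.grids += staged
    return firings


# ---------------------------------------------------------------------------
# Differentiation phase
# ---------------------------------------------------------------------------
def differentiation_phase(
    state: SimState, cnet: CompiledNetwork, k: int, delta: np.ndarray
) -> tuple[int, int]:
    """Advance eligible M0 macrophages' networks; commit on attractor hit.

    Returns (n committed to M1, n committed to M2)."""
    elig = np.flatnonzero((state.kind == 0) & (state.phen == 0) & (state.act != 0))
    if elig.size == 0:
        return (0, 0)
    p = cnet.input_idx
    ibits = (
        ((state.grids[S_IFNG] > 0).astype(np.uint64) << np.uint64(p[0]))
        | ((state.grids[S_IL10] > 0).astype(np.uint64) << np.uint64(p[1]))
        | ((state.grids[S_IL4] > 0).astype(np.uint64) << np.uint64(p[2]))
        | ((state.grids[S_AGL] > 0).astype(np.uint64) << np.uint64(p[3]))
    )
    s = cnet.apply_input_packed(state.grn[elig].astype(np.uint64), ibits[state.site[elig]])
    table = cnet.table
    s32 = s.astype(np.uint32)
    for _ in range(k):
        s32 = table[s32]
    state.grn[elig] = s32
    m1_mask, m2_mask = _committed_lookup(cnet)
    to_m1 = m1_mask[s32]
    to_m2 = m2_mask[s32]
    state.phen[elig[to_m1]] = 1
    state.phen[elig[to_m2]] = 2
    for sub, new_phen in ((elig[to_m1], 1), (elig[to_m2], 2)):
        if sub.size:
            # commitment preserves activation: M0_x -> M{1,2}_x
            np.subtract.at(delta, 0 * 3 + state.act[sub], 1)
            np.add.at(delta, new_phen * 3 + state.act[sub], 1)
    return int(to_m1.sum()), int(to_m2.sum())


_COMMIT_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _committed_lookup(cnet: CompiledNetwork) -> tuple[np.ndarray, np.ndarray]:
    key = id(cnet)
    if key not in _COMMIT_CACHE:
        _COMMIT_CACHE[key] = cnet.committed_masks()
    return _COMMIT_CACHE[key]


# ---------------------------------------------------------------------------
# Diffusion phase
# ---------------------------------------------------------------------------
_OFFSETS = np.array(
    [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)
_P7 = np.full(7, 1.0 / 7.0)


def move_sites(site: np.ndarray, direction: np.ndarray, L: int) -> np.ndarray:
    """Apply von-Neumann moves (0 = stay) to flat site indices, periodic wrap."""
    x, rem = np.divmod(site, L * L)
    y, z = np.divmod(rem, L)
    off = _OFFSETS[direction]
    x = (x + off[:, 0]) % L
    y = (y + off[:, 1]) % L
    z = (z + off[:, 2]) % L
    return (x * L + y) * L + z


def diffusion_phase(state: SimState, rng: np.random.Generator) -> None:
    L = state.L
    if state.n_agents:
        d = rng.integers(0, 7, state.n_agents)
        state.site = move_sites(state.site, d, L)
    for sp in range(state.grids.shape[0]):
        n = state.grids[sp]
        if not n.any():
            continue
        moves = rng.multinomial(n, _P7)  # (n_sites, 7)
        new = moves[:, 0].copy()
        cube = lambda a: a.reshape(L, L, L)
        for j in range(1, 7):
            dx, dy, dz = _OFFSETS[j]
            shifted = cube(moves[:, j])
            if dx: shifted = np.roll(shifted, dx, axis=0)
            if dy: shifted = np.roll(shifted, dy, axis=1)
            if dz: shifted = np.roll(shifted, dz, axis=2)
            new += shifted.ravel()
        state.grids[sp] = new


# ---------------------------------------------------------------------------
# Bookkeeping phase: injections, replication, decay
# ---------------------------------------------------------------------------
def _inject(
    state: SimState, events: list[InjectionEvent], rng: np.random.Generator, delta: np.ndarray
) -> None:
    for ev in events:
        if ev.species == "Ag":
            code = S_AGL if ev.has_lps else S_AGP
        else:
            code = SPECIES_CODE[ev.species]
        sites = rng.integers(0, state.n_sites, ev.amount)
        state.grids[code] += np.bincount(sites, minlength=state.n_sites)
        delta[_N_CELL + code] += ev.amount


def _replicate_antigen(
    state: SimState, prob: float, site_cap: int, rng: np.random.Generator, delta: np.ndarray
) -> None:
    if prob <= 0:
        return
    for code in (S_AGL, S_AGP):
        n = state.grids[code]
        if not n.any():
            continue
        p_eff = prob * np.clip(1.0 - n / site_cap, 0.0, 1.0)
        births = rng.binomial(n, p_eff)
        state.grids[code] += births
        delta[_N_CELL + code] += int(births.sum())


def _innate_helper_activation(
    state: SimState, prob: float, rng: np.random.Generator, delta: np.ndarray
) -> None:
    """Antigen-independent low-level stimulation of resting helper cells.

    Maintains a small, transient pool of active helpers (they deactivate
    through R13 unless engaged), which is what lets a response bootstrap:
    the first IFNg comes from one of these meeting a presenting B cell."""
    if prob <= 0:
        return
    resting = np.flatnonzero((state.kind >= 2) & (state.act == 0))
    if resting.size == 0:
        return
    sel = resting[rng.random(resting.size) < prob]
    if sel.size == 0:
        return
    before = cell_class_index(state.kind[sel], state.act[sel], state.phen[sel])
    np.subtract.at(delta, before, 1)
    state.act[sel] = 1
    after = cell_class_index(state.kind[sel], state.act[sel], state.phen[sel])
    np.add.at(delta, after, 1)


def _decay(
    state: SimState, cy_half: float, ab_half: float, rng: np.random.Generator, delta: np.ndarray
) -> None:
    for code in range(len(SPECIES)):
        half = cy_half if code in _CYTOKINES else (ab_half if code == S_AB else None)
        if half is None or half <= 0:
            continue  # antigen does not decay
        n = state.grids[code]
        if not n.any():
            continue
        survive = 0.5 ** (1.0 / half)
        kept = rng.binomial(n, survive)
        delta[_N_CELL + code] -= int((n - kept).sum())
        state.grids[code] = kept


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------
@dataclass
class AuditRecord:
    step: int
    firings: dict[int, int]
    committed_m1: int
    committed_m2: int
    predicted: np.ndarray
    observed: np.ndarray

    @property
    def discrepancy(self) -> int:
        return int(np.abs(self.predicted - self.observed).sum())


class Simulation:
    """One seeded replicate of the bioreactor."""

    def __init__(
        self,
        config: SimulationConfig,
        net: RegulatoryNetwork | None = None,
        rules: list[ReactionRule] | None = None,
    ):
        self.config = config
        if net is None:
            net = (
                load_network(config.network_path)
                if config.network_path
                else load_default_network()
            )
        self.net = net
        self.cnet = net.compiled
        if rules is None:
            rules = build_rule_table(
                RuleParams(
                    probabilities=dict(config.rules.probabilities),
                    phenotype_gated_secretion=config.rules.phenotype_gated_secretion,
                    bcell_activates_helpers=config.rules.bcell_activates_helpers,
                    r11_duplicates_h2=config.rules.r11_duplicates_h2,
                    ifng_consumed_on_activation=config.rules.ifng_consumed_on_activation,
                )
            )
        self.rules = rules
        self.rng = RngStreams(config.seed)
        self.audit_log: list[AuditRecord] = []
        self._by_step: dict[int, list[InjectionEvent]] = {}
        for ev in config.injections:
            self._by_step.setdefault(ev.step, []).append(ev)
        self.state = self._init_population()

    # ------------------------------------------------------------------ init
    def _init_population(self) -> SimState:
        cfg = self.config
        counts = [
            (KIND_CODE["M"], cfg.n_macrophages, ACT_CODE["r"]),
            (KIND_CODE["B"], cfg.n_bcells, ACT_CODE["a"]),
            (KIND_CODE["H1"], cfg.n_h1, ACT_CODE["r"]),
            (KIND_CODE["H2"], cfg.n_h2, ACT_CODE["r"]),
            (KIND_CODE["Hr"], cfg.n_hr, ACT_CODE["r"]),
        ]
        n = sum(c for _, c, _ in counts)
        kind = np.concatenate([np.full(c, k, dtype=np.int8) for k, c, _ in counts]) if n else np.empty(0, np.int8)
        act = np.concatenate([np.full(c, a, dtype=np.int8) for _, c, a in counts]) if n else np.empty(0, np.int8)
        S = cfg.L ** 3
        site = self.rng.init.integers(0, S, n) if n else np.empty(0, np.int64)
        state = SimState(
            L=cfg.L,
            kind=kind,
            act=act,
            phen=np.zeros(n, dtype=np.int8),
            site=site.astype(np.int64),
            grn=np.zeros(n, dtype=np.uint32),
            grids=np.zeros((len(SPECIES), S), dtype=np.int64),
            used=np.zeros(n, dtype=bool),
            priority=np.zeros(n, dtype=np.float64),
        )
        if cfg.lymphocyte_expansion_limit is not None:
            lymph0 = cfg.n_bcells + cfg.n_h1 + cfg.n_h2 + cfg.n_hr
            state.headroom = max(0, int(lymph0 * cfg.lymphocyte_expansion_limit) - lymph0)
        if cfg.site_capacity is not None and n:
            occupancy = np.bincount(state.site, minlength=S)
            if occupancy.max() > cfg.site_capacity:
                raise ConfigurationError(
                    f"initial placement exceeds per-site capacity {cfg.site_capacity}"
                )
        # injections scheduled for step 0 are applied before the first census
        delta = np.zeros(_N_COLS, dtype=np.int64)
        _inject(state, self._by_step.get(0, []), self.rng.injection, delta)
        return state

    # ------------------------------------------------------------------ step
    def step(self, t: int) -> tuple[np.ndarray, AuditRecord]:
        state = self.state
        before = state.census()
        delta = np.zeros(_N_COLS, dtype=np.int64)
        order = self.rng.rules.permutation(len(self.rules))
        firings = apply_rule_phase(state, self.rules, order, self.rng.rules, delta)
        n1, n2 = differentiation_phase(state, self.cnet, self.config.k, delta)
        diffusion_phase(state, self.rng.diffusion)
        _inject(state, self._by_step.get(t, []), self.rng.injection, delta)
        _replicate_antigen(
            state, self.config.ag_replication_prob, self.config.ag_site_capacity,
            self.rng.decay, delta,
        )
        _decay(
            state, self.config.cytokine_half_life, self.config.antibody_half_life,
            self.rng.decay, delta,
        )
        _innate_helper_activation(
            state, self.config.helper_innate_activation, self.rng.decay, delta
        )
        observed = state.census()
        record = AuditRecord(t, firings, n1, n2, before + delta, observed)
        if self.config.audit and record.discrepancy:
            raise AuditError(
                f"step {t}: census delta does not reconcile; "
                f"predicted {record.predicted.tolist()} observed {record.observed.tolist()}"
            )
        return observed, record

    # ------------------------------------------------------------------- run
    def run(self) -> pd.DataFrame:
        rows = [self.state.census()]
        for t in range(1, self.config.n_steps + 1):
            row, record = self.step(t)
            rows.append(row)
            self.audit_log.append(record)
            if log.isEnabledFor(logging.DEBUG):
                log.debug("step %d firings=%s commits=(%d,%d)", t, record.firings,
                          record.committed_m1, record.committed_m2)
        ts = pd.DataFrame(rows, columns=list(CENSUS_COLUMNS))
        ts.insert(0, "step", np.arange(len(rows)))
        log.info(
            "run seed=%d: %d steps, final M1=%d M2=%d Ag=%d",
            self.config.seed, self.config.n_steps,
            ts.iloc[-1][["M1_r", "M1_a", "M1_p"]].sum(),
            ts.iloc[-1][["M2_r", "M2_a", "M2_p"]].sum(),
            ts.iloc[-1]["Ag_lps"] + ts.iloc[-1]["Ag_plain"],
        )
        return ts


def run(config: SimulationConfig, net: RegulatoryNetwork | None = None) -> pd.DataFrame:
    """Run one replicate and return its census time series.

    The returned frame has one row per step (row 0 is the initial census,
    after any step-0 injections) and one column per census series; it is
    written to ``config.output_path`` as CSV when that is set."""
    sim = Simulation(config, net=net)
    ts = sim.run()
    if config.output_path:
        ts.to_csv(config.output_path, index=False)
    return ts


# ---------------------------------------------------------------------------
# Census helpers
# ---------------------------------------------------------------------------
def total(ts: pd.DataFrame, what: str) -> pd.Series:
    """Convenience totals over census columns: 'M0'|'M1'|'M2'|'Ag'|'B'|'H1a'|..."""
    groups = {
        "M0": ["M0_r", "M0_a", "M0_p"],
        "M1": ["M1_r", "M1_a", "M1_p"],
        "M2": ["M2_r", "M2_a", "M2_p"],
        "M": [c for c in CELL_COLUMNS if c.startswith("M")],
        "B": ["B_a", "B_p"],
        "H1": ["H1_r", "H1_a"],
        "H2": ["H2_r", "H2_a"],
        "Hr": ["Hr_r", "Hr_a"],
        "Ag": ["Ag_lps", "Ag_plain"],
    }
    if what in groups:
        return ts[groups[what]].sum(axis=1)
    return ts[what]


# ---------------------------------------------------------------------------
# Single-site adapter (object-level surface used by rules.apply_rules_at_site)
# ---------------------------------------------------------------------------
def _site_to_state(site: SiteContents) -> tuple[SimState, list[np.ndarray | None]]:
    n = len(site.agents)
    kind = np.array([KIND_CODE[a.kind] for a in site.agents], dtype=np.int8)
    act = np.array([ACT_CODE[a.activation] for a in site.agents], dtype=np.int8)
    phen = np.array(
        [int(a.phenotype[1]) if a.phenotype else 0 for a in site.agents], dtype=np.int8
    )
    grids = np.zeros((len(SPECIES), 1), dtype=np.int64)
    for sp, cnt in site.tokens.items():
        if cnt < 0:
            raise ValueError(f"negative token count for {sp}")
        grids[SPECIES_CODE[sp], 0] = cnt
    state = SimState(
        L=1,
        kind=kind, act=act, phen=phen,
        site=np.zeros(n, dtype=np.int64),
        grn=np.zeros(n, dtype=np.uint32),
        grids=grids,
        used=np.zeros(n, dtype=bool),
        priority=np.zeros(n, dtype=np.float64),
    )
    keep_grn = [a.grn_state for a in site.agents]
    return state, keep_grn


def apply_rules_single_site(
    site: SiteContents, rules: list[ReactionRule], order: np.ndarray, rng: np.random.Generator
) -> SiteContents:
    state, keep_grn = _site_to_state(site)
    delta = np.zeros(_N_COLS, dtype=np.int64)
    apply_rule_phase(state, list(rules), order, rng, delta)
    kinds = list(KIND_CODE)
    acts = list(ACT_CODE)
    agents = []
    for i in range(state.n_agents):
        k = kinds[state.kind[i]]
        agents.append(
            CellAgent(
                kind=k,
                activation=acts[state.act[i]],
                phenotype=f"M{state.phen[i]}" if k == "M" else None,
                grn_state=keep_grn[i] if i < len(keep_grn) else None,
                site=site.agents[0].site if site.agents else (0, 0, 0),
            )
        )
    tokens = {sp: int(state.grids[SPECIES_CODE[sp], 0]) for sp in SPECIES}
    tokens = {sp: c for sp, c in tokens.items() if c}
    return SiteContents(agents=agents, tokens=tokens)
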