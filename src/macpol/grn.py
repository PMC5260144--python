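"""Signed Boolean gene-regulatory network for macrophage M1/M2 commitment.

The microscopic scale of the model: a signed digraph of genes/receptors with a
synchronous Boolean update map

    x_i(t+1) = ( OR over activating parents x_j(t) ) AND NOT ( OR over inhibiting parents x_j(t) )

A node with no active activating parent becomes (or stays) inactive.  The four
extracellular inputs (IFNg, IL10, IL4, LPS) have no parents; they are clamped
by :func:`apply_input` and held during iteration, representing a persistent
local stimulus.  Commitment is attractor membership: a state that is a fixed
point of the clamped dynamics and expresses the M1 marker (NOS2 by default) is
the M1 attractor for that input regime; Arg1 marks M2.  The committed
attractor depends on which inputs are on (e.g. the IL4-driven and IL10-driven
M2 fixed points differ in the IL10R/STAT3 bits) but, for the bundled network,
each input regime admits at most one fixed point per marker and no fixed point
expresses both markers - so a macrophage can never be both M1- and
M2-committed (the exclusivity property f1 + f2 <= 1).

States are Boolean vectors aligned to the network's node order; internally the
dynamics is compiled to bitmask operations over packed integer states, with a
full transition table over the 2^|N| state space for networks small enough to
enumerate.  The table doubles as the brute-force fixed-point oracle.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np

from .errors import AlignmentError, ConfigurationError, EnumerationLimitError, NetworkFormatError

#: Largest node count for which the full 2^n transition table is built.
ENUMERATION_LIMIT = 22

#: Fixed order of the input vector, mirroring I = (IFNg, IL10, IL4, LPS).
INPUT_ORDER = ("IFNg", "IL10", "IL4", "LPS")


class InputVector(NamedTuple):
    """Extracellular stimulus seen by one macrophage at one lattice site."""

    IFNg: bool
    IL10: bool
    IL4: bool
    LPS: bool


class AttractorLabel(enum.Enum):
    M1_COMMITTED = "M1_committed"
    M2_COMMITTED = "M2_committed"
    UNCOMMITTED = "uncommitted"


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Signed Boolean regulatory network.

    Parameters
    ----------
    nodes:
        Total, fixed node order; states are bit-vectors in this order.
    roles:
        node -> {"input", "receptor", "internal"}.
    phenotype:
        node -> {"M1", "M2"}; which polarization branch the node belongs to.
    activators / inhibitors:
        node -> set of parent node names (E+ / E-).
    markers:
        phenotype -> marker node whose activity identifies the committed
        attractor ({"M1": "NOS2", "M2": "Arg1"} for the bundled network).
    """

    nodes: tuple[str, ...]
    roles: Mapping[str, str]
    phenotype: Mapping[str, str]
    activators: Mapping[str, frozenset[str]]
    inhibitors: Mapping[str, frozenset[str]]
    markers: Mapping[str, str]
    _compiled: dict = field(default_factory=dict, compare=False, repr=False, hash=False)

    def __post_init__(self) -> None:
        names = set(self.nodes)
        if len(names) != len(self.nodes):
            raise NetworkFormatError("duplicate node names")
        for mapping, kind in ((self.activators, "activator"), (self.inhibitors, "inhibitor")):
            for target, parents in mapping.items():
                if target not in names:
                    raise NetworkFormatError(f"unknown {kind} target node {target!r}")
                missing = set(parents) - names
                if missing:
                    raise NetworkFormatError(f"unknown parent(s) {sorted(missing)} of {target!r}")
        for inp in self.input_nodes:
            if self.activators.get(inp) or self.inhibitors.get(inp):
                raise NetworkFormatError(f"input node {inp!r} must have no parents")
        missing_inputs = set(INPUT_ORDER) - {n for n in self.nodes if self.roles.get(n) == "input"}
        if missing_inputs:
            raise NetworkFormatError(f"missing required input node(s): {sorted(missing_inputs)}")
        for phen in ("M1", "M2"):
            marker = self.markers.get(phen)
            if marker is None or marker not in names:
                raise NetworkFormatError(f"missing or unknown {phen} marker node")
        if self.markers["M1"] == self.markers["M2"]:
            raise ConfigurationError("M1 and M2 marker nodes must differ")

    # ------------------------------------------------------------------ meta
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def input_nodes(self) -> tuple[str, ...]:
        """The four clamped inputs in canonical I order."""
        return INPUT_ORDER

    @property
    def phenotype_tag(self) -> dict[str, str]:
        """node -> {"input", "receptor", "M1", "M2"} (inputs/receptors win)."""
        out = {}
        for n in self.nodes:
            role = self.roles.get(n, "internal")
            out[n] = role if role in ("input", "receptor") else self.phenotype.get(n, "internal")
        return out

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise NetworkFormatError(f"unknown node {node!r}") from None

    # -------------------------------------------------------------- compiled
    @property
    def compiled(self) -> "CompiledNetwork":
        if "c" not in self._compiled:
            self._compiled["c"] = CompiledNetwork(self)
        return self._compiled["c"]

    def zero_state(self) -> np.ndarray:
        return np.zeros(self.n_nodes, dtype=np.uint8)


class CompiledNetwork:
    """Bitmask-compiled dynamics of a :class:`RegulatoryNetwork`.

    For each node i, ``act_mask[i]``/``inh_mask[i]`` hold the bitmasks of its
    activating/inhibiting parents; the synchronous map over a packed state s is

        bit_i' = (s & act_mask[i] != 0) and (s & inh_mask[i] == 0)

    with parentless input nodes holding their current bit.  When the network
    has at most :data:`ENUMERATION_LIMIT` nodes a full transition table
    ``T[s]`` is built (1 MiB of uint32 for the 18-node bundled network), which
    makes per-agent iteration in the lattice engine a table lookup and turns
    fixed-point enumeration into ``T == arange``.
    """

    def __init__(self, net: RegulatoryNetwork):
        self.net = net
        n = net.n_nodes
        if n > 63:
            raise EnumerationLimitError(f"network with {n} nodes exceeds packed-state capacity")
        self.n = n
        self.act_mask = np.zeros(n, dtype=np.uint64)
        self.inh_mask = np.zeros(n, dtype=np.uint64)
        idx = {name: i for i, name in enumerate(net.nodes)}
        for target, parents in net.activators.items():
            for p in parents:
                self.act_mask[idx[target]] |= np.uint64(1 << idx[p])
        for target, parents in net.inhibitors.items():
            for p in parents:
                self.inh_mask[idx[target]] |= np.uint64(1 << idx[p])
        self.input_idx = np.array([idx[name] for name in INPUT_ORDER], dtype=np.int64)
        self.input_mask = np.uint64(0)
        for i in self.input_idx:
            self.input_mask |= np.uint64(1 << int(i))
        self.m1_bit = np.uint64(1 << idx[net.markers["M1"]])
        self.m2_bit = np.uint64(1 << idx[net.markers["M2"]])
        self._table: np.ndarray | None = None
        self._fixed: np.ndarray | None = None

    # ------------------------------------------------------------ packing
    def pack(self, state: np.ndarray) -> int:
        state = np.asarray(state)
        if state.shape != (self.n,):
            raise AlignmentError(f"state of length {state.shape} does not align with {self.n} nodes")
        return int(np.sum(state.astype(np.uint64) << np.arange(self.n, dtype=np.uint64)))

    def unpack(self, packed: int) -> np.ndarray:
        return ((int(packed) >> np.arange(self.n)) & 1).astype(np.uint8)

    # ------------------------------------------------------------ dynamics
    def step_packed(self, states: np.ndarray) -> np.ndarray:
        """Synchronous update of an array of packed states (inputs held)."""
        states = np.asarray(states, dtype=np.uint64)
        out = states & self.input_mask  # inputs hold their value
        one = np.uint64(1)
        for i in range(self.n):
            if np.uint64(1 << i) & self.input_mask:
                continue
            if self.act_mask[i] == 0:
                continue  # no activating parent: bit stays 0
            on = ((states & self.act_mask[i]) != 0) & ((states & self.inh_mask[i]) == 0)
            out |= on.astype(np.uint64) << np.uint64(i)
        return out

    def apply_input_packed(self, states: np.ndarray, input_bits: np.ndarray | int) -> np.ndarray:
        """Overwrite the four input bits of packed states with ``input_bits``."""
        states = np.asarray(states, dtype=np.uint64)
        return (states & ~self.input_mask) | np.asarray(input_bits, dtype=np.uint64)

    def pack_input(self, I: InputVector) -> np.uint64:
        bits = np.uint64(0)
        for name, val in zip(INPUT_ORDER, I):
            if val:
                bits |= np.uint64(1 << int(self.input_idx[INPUT_ORDER.index(name)]))
        return bits

    # --------------------------------------------------------------- table
    @property
    def table(self) -> np.ndarray:
        """Full transition table T over all 2^n packed states."""
        if self._table is None:
            if self.n > ENUMERATION_LIMIT:
                raise EnumerationLimitError(
                    f"network with {self.n} nodes exceeds the enumeration limit "
                    f"of {ENUMERATION_LIMIT} (2^{self.n} states)"
                )
            all_states = np.arange(1 << self.n, dtype=np.uint64)
            self._table = self.step_packed(all_states).astype(np.uint32)
        return self._table

    @property
    def fixed_mask(self) -> np.ndarray:
        """Boolean mask over all 2^n states: is this state a fixed point?"""
        if self._fixed is None:
            self._fixed = self.table == np.arange(1 << self.n, dtype=np.uint32)
        return self._fixed

    def committed_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """(is_M1_attractor, is_M2_attractor) over all 2^n packed states."""
        states = np.arange(1 << self.n, dtype=np.uint64)
        fixed = self.fixed_mask
        m1 = fixed & ((states & self.m1_bit) != 0)
        m2 = fixed & ((states & self.m2_bit) != 0)
        return m1, m2


# ---------------------------------------------------------------------------
# Boolean-vector operations (object-level API)
# ---------------------------------------------------------------------------

def _check_aligned(state: np.ndarray, net: RegulatoryNetwork) -> np.ndarray:
    state = np.asarray(state, dtype=np.uint8)
    if state.shape != (net.n_nodes,):
        raise AlignmentError(
            f"state of shape {state.shape} does not align with the {net.n_nodes}-node network"
        )
    return state


def boolean_update(state: np.ndarray, net: RegulatoryNetwork) -> np.ndarray:
    """One synchronous application of the Boolean map F.

    Every non-input node becomes active iff at least one activating parent is
    active and no inhibiting parent is active; input nodes hold their value
    (they change only through :func:`apply_input`).  Pure function: the new
    vector is computed entirely from the old one.
    """
    state = _check_aligned(state, net)
    c = net.compiled
    return c.unpack(int(c.step_packed(np.array([c.pack(state)]))[0]))


def apply_input(state: np.ndarray, I: InputVector, net: RegulatoryNetwork) -> np.ndarray:
    """Return a copy of ``state`` with the four input bits overwritten by I."""
    state = _check_aligned(state, net).copy()
    c = net.compiled
    for pos, val in zip(c.input_idx, I):
        state[pos] = 1 if val else 0
    return state


def iterate(state: np.ndarray, I: InputVector, k: int, net: RegulatoryNetwork) -> np.ndarray:
    """F applied k times to ``state ∧ I`` with the inputs clamped at I throughout.

    Clamping is automatic because input nodes hold their value under F; the
    stimulus persists for the whole k-step burst.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    c = net.compiled
    s = np.array([c.pack(apply_input(state, I, net))], dtype=np.uint64)
    for _ in range(k):
        s = c.step_packed(s)
    return c.unpack(int(s[0]))


def enumerate_fixed_points(net: RegulatoryNetwork, I: InputVector) -> list[np.ndarray]:
    """Exact set of fixed points of the clamped dynamics under input I.

    Brute force over all internal-node configurations with the input bits
    clamped at I: returns every state x with F(x ∧ I) = x ∧ I, in increasing
    packed order.  Refuses (with the size) for networks above the enumeration
    limit.  This is the oracle that validates the committed attractors.
    """
    c = net.compiled
    table = c.table  # raises EnumerationLimitError when too large
    states = np.arange(1 << c.n, dtype=np.uint64)
    bits = c.pack_input(I)
    mask = c.fixed_mask & ((states & c.input_mask) == bits)
    return [c.unpack(int(s)) for s in states[mask]]


def classify(state: np.ndarray, net: RegulatoryNetwork) -> AttractorLabel:
    """Label a state as M1-committed, M2-committed, or uncommitted.

    A state is committed iff it is a fixed point of the clamped dynamics under
    its own input bits and its marker gene (NOS2 for M1, Arg1 for M2) is
    active.  For a validated network no fixed point carries both markers, so
    at most one committed label can ever fire (f1 + f2 <= 1).
    """
    state = _check_aligned(state, net)
    c = net.compiled
    s = np.uint64(c.pack(state))
    if int(c.step_packed(np.array([s]))[0]) != int(s):
        return AttractorLabel.UNCOMMITTED
    m1 = bool(s & c.m1_bit)
    m2 = bool(s & c.m2_bit)
    if m1 and m2:  # impossible for a validated network; fail loudly, never silently
        raise ConfigurationError("state is a fixed point expressing both markers")
    if m1:
        return AttractorLabel.M1_COMMITTED
    if m2:
        return AttractorLabel.M2_COMMITTED
    return AttractorLabel.UNCOMMITTED


# ---------------------------------------------------------------------------
# Validation and reporting
# ---------------------------------------------------------------------------

def all_input_vectors() -> list[InputVector]:
    return [
        InputVector(bool(b >> 3 & 1), bool(b >> 2 & 1), bool(b >> 1 & 1), bool(b & 1))
        for b in range(16)
    ]


@dataclass
class ValidationReport:
    ok: bool
    messages: list[str]
    x1: np.ndarray | None = None
    x2: np.ndarray | None = None


def validate_network(net: RegulatoryNetwork, k_converge: int | None = None) -> ValidationReport:
    """Exhaustively validate the commitment structure of a network.

    Checks, by brute-force enumeration over every input vector:

    * no fixed point expresses both the M1 and the M2 marker;
    * each input vector admits at most one M1-marked and at most one M2-marked
      fixed point (uniqueness of the committed attractor per regime);
    * the M1-inducing regime (IFNg and LPS on) and the M2-inducing regime
      (IL4 on alone) reach distinct committed fixed points X1 != X2 from the
      all-zero state;
    * the all-zero state is a fixed point with all inputs off.
    """
    msgs: list[str] = []
    c = net.compiled
    try:
        c.table
    except EnumerationLimitError as exc:
        return ValidationReport(False, [str(exc)])
    states = np.arange(1 << c.n, dtype=np.uint64)
    fixed = c.fixed_mask
    both = fixed & ((states & c.m1_bit) != 0) & ((states & c.m2_bit) != 0)
    if both.any():
        msgs.append(f"{int(both.sum())} fixed point(s) express both markers")
    for I in all_input_vectors():
        bits = c.pack_input(I)
        sel = fixed & ((states & c.input_mask) == bits)
        n_m1 = int((sel & ((states & c.m1_bit) != 0)).sum())
        n_m2 = int((sel & ((states & c.m2_bit) != 0)).sum())
        if n_m1 > 1:
            msgs.append(f"input {tuple(I)}: {n_m1} M1-marked fixed points (not unique)")
        if n_m2 > 1:
            msgs.append(f"input {tuple(I)}: {n_m2} M2-marked fixed points (not unique)")
    if k_converge is None:
        k_converge = 2 * c.n
    zero = net.zero_state()
    x1 = iterate(zero, InputVector(IFNg=True, IL10=False, IL4=False, LPS=True), k_converge, net)
    x2 = iterate(zero, InputVector(IFNg=False, IL10=False, IL4=True, LPS=False), k_converge, net)
    if classify(x1, net) is not AttractorLabel.M1_COMMITTED:
        msgs.append("M1-inducing regime (IFNg+LPS) does not reach an M1-marked fixed point from zero")
    if classify(x2, net) is not AttractorLabel.M2_COMMITTED:
        msgs.append("M2-inducing regime (IL4) does not reach an M2-marked fixed point from zero")
    if np.array_equal(x1, x2):
        msgs.append("X1 == X2: committed attractors do not differ")
    z = c.pack(zero)
    if int(c.table[z]) != z:
        msgs.append("all-zero state with all inputs off is not a fixed point")
    return ValidationReport(not msgs, msgs, x1=x1, x2=x2)


def attractor_report(net: RegulatoryNetwork) -> "pd.DataFrame":
    """One row per (input vector, fixed point) with its commitment label.

    Cyclic attractors are not enumerated here (only fixed points are), but the
    number of states not converging to any fixed point under each clamped
    regime is reported in the ``n_nonconverging`` column, so limit cycles are
    detected and reported rather than silently classified.
    """
    import pandas as pd

    c = net.compiled
    rows = []
    for I in all_input_vectors():
        fps = enumerate_fixed_points(net, I)
        n_noncvg = _count_nonconverging(c, I)
        for fp in fps:
            rows.append(
                {
                    "IFNg": int(I.IFNg),
                    "IL10": int(I.IL10),
                    "IL4": int(I.IL4),
                    "LPS": int(I.LPS),
                    "fixed_point": "".join(map(str, fp)),
                    "active_nodes": ",".join(n for n, b in zip(net.nodes, fp) if b),
                    "label": classify(fp, net).value,
                    "n_nonconverging": n_noncvg,
                }
            )
    return pd.DataFrame(rows)


def _count_nonconverging(c: CompiledNetwork, I: InputVector, max_steps: int | None = None) -> int:
    """Number of start states (under clamped I) whose trajectory never reaches
    a fixed point within 2^n steps, i.e. states on or draining into a limit cycle."""
    if max_steps is None:
        max_steps = 1 << min(c.n, 20)
    states = np.arange(1 << c.n, dtype=np.uint32)
    bits = np.uint32(c.pack_input(I))
    mask32 = np.uint32(c.input_mask)
    cur = (states & ~mask32) | bits
    table = c.table
    fixed = c.fixed_mask
    # doubling the table: after ceil(log2(max_steps)) squarings, cur = T^(2^m)(start)
    t = table
    steps = 1
    while steps < max_steps:
        t = t[t]
        steps *= 2
    landed = t[cur]
    return int((~fixed[landed]).sum())
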