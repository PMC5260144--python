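"""Mesoscopic reaction rules: stochastic local interactions between immune
cells and molecule tokens co-located on one lattice site.

The rule set is data, not code: each :class:`ReactionRule` pairs reactant
patterns with product terms and a firing probability (all 1 by default), and
the whole table serializes to a human-readable tab-separated text format so a
modified rule set can be loaded without code changes.

Pattern grammar (one term):

* cells: ``KIND[PHENO]^ACT`` with KIND in {M, B, H1, H2, Hr, H, APC},
  ACT in {r, a, p}.  ``H`` matches any helper class, ``APC`` any presenting
  antigen-presenting cell (macrophage or B cell).  The optional PHENO suffix
  (macrophages only) is ``0``/``1``/``2`` for an exact phenotype or ``~1`` /
  ``~2`` for "not committed to that phenotype": ``M~2^p`` is any presenting
  macrophage that is not M2-committed.
* molecule tokens: ``IFNg``, ``IL4``, ``IL10``, ``Ab``, ``Ag`` (either
  antigen variant), ``Ag_lps``, ``Ag_plain``.
* an integer prefix is a stoichiometric count (``2 B^p``); ``0`` alone is the
  empty product.

Cell products map positionally onto cell reactants: the matched agent is
transformed to the product's activation (and phenotype/kind where the product
names one explicitly); a count of 2 additionally creates one fresh agent of
the product class at the same site (proliferation), inheriting nothing beyond
kind and activation.

Within one simulation step every entity takes part in at most one firing:
reactants (including catalytic ones appearing unchanged among the products)
are marked used, so a presenting-cell/helper pair reacts at most once per
step and disjoint matches never share an entity.
"""
from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import RuleFormatError
from .grn import AttractorLabel, InputVector, RegulatoryNetwork, classify, iterate

# --------------------------------------------------------------------- codes
KINDS = ("M", "B", "H1", "H2", "Hr")
ACTIVATIONS = ("r", "a", "p")
PHENOTYPES = ("M0", "M1", "M2")
SPECIES = ("IFNg", "IL4", "IL10", "Ab", "Ag_lps", "Ag_plain")

KIND_CODE = {k: i for i, k in enumerate(KINDS)}
ACT_CODE = {a: i for i, a in enumerate(ACTIVATIONS)}
SPECIES_CODE = {s: i for i, s in enumerate(SPECIES)}

#: kind-classes a pattern kind can match (agent kinds, by code)
_KIND_CLASS = {
    "M": (0,),
    "B": (1,),
    "H1": (2,),
    "H2": (3,),
    "Hr": (4,),
    "H": (2, 3, 4),
    "APC": (0, 1),
}

_CELL_RE = re.compile(r"^(APC|H1|H2|Hr|H|M|B)(~?[012])?\^([rap])$")


# ------------------------------------------------------------------ patterns
@dataclass(frozen=True)
class CellPattern:
    kind: str                      # M, B, H1, H2, Hr, H, APC
    activation: str                # r, a, p
    phenotype: str | None = None   # None, "0","1","2","~1","~2" (macrophages)

    def __post_init__(self):
        if self.kind not in _KIND_CLASS:
            raise RuleFormatError(f"unknown cell kind {self.kind!r}")
        if self.activation not in ACT_CODE:
            raise RuleFormatError(f"unknown activation {self.activation!r}")
        if self.phenotype is not None and self.kind not in ("M", "APC"):
            raise RuleFormatError("phenotype constraints apply to macrophages (or APC) only")
        if self.kind == "APC" and self.phenotype is not None and not self.phenotype.startswith("~"):
            raise RuleFormatError("APC phenotype constraints must be negative (~1 / ~2)")
        if self.kind == "B" and self.activation == "r":
            raise RuleFormatError("B cells have no resting state (only B^a and B^p)")

    def text(self) -> str:
        ph = self.phenotype or ""
        return f"{self.kind}{ph}^{self.activation}"


@dataclass(frozen=True)
class CellProduct:
    activation: str
    kind: str | None = None        # None: preserve the matched agent's kind
    phenotype: str | None = None   # digit: set; None: preserve
    copies: int = 1

    def text(self, reactant: CellPattern) -> str:
        kind = self.kind if self.kind is not None else reactant.kind
        ph = self.phenotype if self.phenotype is not None else (reactant.phenotype or "")
        base = f"{kind}{ph}^{self.activation}"
        return f"{self.copies} {base}" if self.copies != 1 else base


@dataclass(frozen=True)
class ReactionRule:
    """One stochastic local reaction ``reactants --(p)--> products``."""

    rule_id: int
    cell_reactants: tuple[CellPattern, ...]
    cell_products: tuple[CellProduct, ...]
    token_reactants: tuple[str, ...]
    token_products: tuple[str, ...]
    probability: float = 1.0

    def __post_init__(self):
        if len(self.cell_products) != len(self.cell_reactants):
            raise RuleFormatError(
                f"rule {self.rule_id}: cell products must map 1:1 onto cell reactants"
            )
        if not (0.0 <= self.probability <= 1.0):
            raise RuleFormatError(f"rule {self.rule_id}: probability outside [0,1]")
        for sp in self.token_reactants + self.token_products:
            if sp not in SPECIES and sp != "Ag":
                raise RuleFormatError(f"rule {self.rule_id}: unknown species {sp!r}")
        # reactant cell patterns must be pairwise disjoint so greedy matching
        # with a single pre-count per pattern is sound
        for i, a in enumerate(self.cell_reactants):
            for b in self.cell_reactants[i + 1:]:
                if set(_KIND_CLASS[a.kind]) & set(_KIND_CLASS[b.kind]):
                    raise RuleFormatError(
                        f"rule {self.rule_id}: overlapping cell reactant patterns "
                        f"{a.text()} and {b.text()}"
                    )

    def text(self) -> str:
        lhs = [p.text() for p in self.cell_reactants] + list(self.token_reactants)
        rhs = [p.text(r) for p, r in zip(self.cell_products, self.cell_reactants)]
        rhs += list(self.token_products)
        lhs_s = " + ".join(lhs) if lhs else "0"
        rhs_s = " + ".join(rhs) if rhs else "0"
        return f"{lhs_s} -> {rhs_s}"


# --------------------------------------------------------------- text format
def _parse_term(term: str, rule_id: int) -> tuple[int, str, CellPattern | None]:
    term = term.strip()
    count = 1
    m = re.match(r"^(\d+)\s+(.*)$", term)
    if m:
        count = int(m.group(1))
        term = m.group(2)
    cm = _CELL_RE.match(term)
    if cm:
        return count, "cell", CellPattern(cm.group(1), cm.group(3), cm.group(2))
    if term in SPECIES or term == "Ag":
        return count, "token", None
    raise RuleFormatError(f"rule {rule_id}: cannot parse term {term!r}")


def parse_rule(rule_id: int, equation: str, probability: float) -> ReactionRule:
    if "->" not in equation:
        raise RuleFormatError(f"rule {rule_id}: missing '->' in {equation!r}")
    lhs_s, rhs_s = equation.split("->", 1)

    def terms(side: str) -> list[str]:
        side = side.strip()
        return [] if side == "0" else [t for t in side.split(" + ") if t.strip()]

    cell_re: list[CellPattern] = []
    tok_re: list[str] = []
    for t in terms(lhs_s):
        count, kind, pat = _parse_term(t, rule_id)
        if kind == "cell":
            if count != 1:
                raise RuleFormatError(f"rule {rule_id}: cell reactant counts must be 1")
            cell_re.append(pat)
        else:
            tok_re.extend([t.strip().split()[-1]] * count)
    cell_pr: list[CellProduct] = []
    tok_pr: list[str] = []
    for t in terms(rhs_s):
        count, kind, pat = _parse_term(t, rule_id)
        if kind == "cell":
            cell_pr.append(pat_to_product(pat, count, cell_re, len(cell_pr), rule_id))
        else:
            tok_pr.extend([t.strip().split()[-1]] * count)
    return ReactionRule(rule_id, tuple(cell_re), tuple(cell_pr), tuple(tok_re), tuple(tok_pr), probability)


def pat_to_product(
    pat: CellPattern, count: int, reactants: Sequence[CellPattern], pos: int, rule_id: int
) -> CellProduct:
    if pos >= len(reactants):
        raise RuleFormatError(f"rule {rule_id}: more cell products than cell reactants")
    reac = reactants[pos]
    kind = None if pat.kind == reac.kind else pat.kind
    phen = pat.phenotype if (pat.phenotype or "").isdigit() else None
    return CellProduct(activation=pat.activation, kind=kind, phenotype=phen, copies=count)


def rules_to_text(rules: Iterable[ReactionRule]) -> str:
    lines = ["# Reaction rules (macpol rule-table format v1): id<TAB>equation<TAB>probability"]
    for r in rules:
        lines.append(f"{r.rule_id}\t{r.text()}\t{r.probability:g}")
    return "\n".join(lines) + "\n"


def load_rules(path_or_text: str | Path, *, is_text: bool = False) -> list[ReactionRule]:
    text = str(path_or_text) if is_text else Path(path_or_text).read_text(encoding="utf-8")
    rules = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise RuleFormatError(f"line {lineno}: expected 'id<TAB>equation<TAB>p'")
        rules.append(parse_rule(int(parts[0]), parts[1], float(parts[2])))
    if not rules:
        raise RuleFormatError("no rules found")
    return rules


def rule_table_hash(rules: Iterable[ReactionRule]) -> str:
    return hashlib.sha256(rules_to_text(rules).encode("utf-8")).hexdigest()


# ------------------------------------------------------------- default table
@dataclass(frozen=True)
class RuleParams:
    """Knobs of the default rule table.

    ``probabilities`` overrides per-rule firing probabilities (default: all 1).
    ``phenotype_gated_secretion`` restricts IFNg release on Th1 contact to
    non-M2 macrophages and IL-4 release on Th2 contact to non-M1 macrophages
    (a committed phenotype stops secreting the opposing branch's cytokine);
    switching it off restores the phenotype-blind forms.
    ``bcell_activates_helpers`` lets presenting B cells activate resting
    helpers alongside presenting macrophages; the default keeps the
    macrophage-only form, which routes all helper activation through
    presenting macrophages.
    ``r11_duplicates_h2`` makes the Th2-driven B-cell reaction duplicate the
    Th2 helper; off reproduces the literal form in which the Th2 helper
    converts into two active Th1 helpers.
    ``ifng_consumed_on_activation`` destroys the IFNg token that activates a
    macrophage; the default treats it as catalytic (one token can activate at
    most one macrophage per step and is removed by decay, not by signalling),
    without which large-scale macrophage activation cannot be sustained.
    """

    probabilities: dict[int, float] = field(default_factory=dict)
    phenotype_gated_secretion: bool = True
    bcell_activates_helpers: bool = False
    r11_duplicates_h2: bool = True
    ifng_consumed_on_activation: bool = False


def build_rule_table(params: RuleParams | None = None) -> list[ReactionRule]:
    """The 15 default reactions R1-R15 of the bioreactor."""
    params = params or RuleParams()
    g = params.phenotype_gated_secretion
    r5_m = "M~2^p" if g else "M^p"
    r6_m = "M~1^p" if g else "M^p"
    r11_h = "H2^a" if params.r11_duplicates_h2 else "H1^a"
    if params.bcell_activates_helpers:
        r12_apc = "APC~2^p" if g else "APC^p"
    else:
        r12_apc = "M~2^p" if g else "M^p"
    r1 = "M^r + IFNg -> M^a" if params.ifng_consumed_on_activation else "M^r + IFNg -> M^a + IFNg"
    eqs = {
        1: r1,
        2: "M^a + Ag -> M^p",
        3: "M^p -> M^a",
        4: "M^a -> M^r",
        5: f"{r5_m} + H1^a -> {r5_m} + H1^a + IFNg",
        6: f"{r6_m} + H2^a -> {r6_m} + H2^a + IL4",
        7: "M2^p + Hr^a -> M2^p + Hr^a + IL10",
        8: "B^a + Ag -> B^p",
        9: "B^p -> B^a",
        10: "B^p + H1^a -> 2 B^p + 2 H1^a + IFNg + Ab",
        11: f"B^p + H2^a -> 2 B^p + 2 {r11_h} + IL4 + Ab",
        12: f"H^r + {r12_apc} -> H^a + {r12_apc}",
        13: "H^a -> H^r",
        14: "H1^a + B^p -> H1^a + B^p + IFNg",
        15: "Ab + Ag -> 0",
    }
    return [
        parse_rule(i, eq, params.probabilities.get(i, 1.0)) for i, eq in sorted(eqs.items())
    ]


# ----------------------------------------------------- object-level surfaces
@dataclass
class CellAgent:
    """One immune cell.  Macrophages carry a phenotype and an embedded
    network state; committed macrophages (M1/M2) are terminally
    differentiated and their network state never changes again."""

    kind: str                               # M, B, H1, H2, Hr
    activation: str                         # r, a, p
    phenotype: str | None = None            # M0/M1/M2, macrophages only
    grn_state: np.ndarray | None = None     # macrophages only
    site: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.kind == "B" and self.activation == "r":
            raise ValueError("B cells are never resting")
        if self.kind == "M":
            if self.phenotype is None:
                self.phenotype = "M0"
            if self.phenotype not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {self.phenotype!r}")
        elif self.phenotype is not None or self.grn_state is not None:
            raise ValueError("phenotype/grn_state are macrophage-only fields")


@dataclass
class SiteContents:
    """Multiset of entities on one lattice site."""

    agents: list[CellAgent] = field(default_factory=list)
    tokens: dict[str, int] = field(default_factory=dict)

    def count(self, species: str) -> int:
        if species == "Ag":
            return self.tokens.get("Ag_lps", 0) + self.tokens.get("Ag_plain", 0)
        return self.tokens.get(species, 0)


def apply_rules_at_site(
    site: SiteContents,
    rules: Sequence[ReactionRule],
    rng: np.random.Generator,
) -> SiteContents:
    """Run one reaction phase on a single site's contents.

    The rules are shuffled with ``rng``, then applied greedily in that order;
    each firing succeeds with the rule's probability, and every participating
    entity takes part in at most one firing.  This is the same kernel the
    lattice engine runs, executed on a one-site lattice.
    """
    from . import engine  # local import: engine depends on this module

    for sp, n in site.tokens.items():
        if n < 0:
            raise ValueError(f"negative token count for {sp}")
    order = rng.permutation(len(rules))
    return engine.apply_rules_single_site(site, rules, order, rng)


def local_input_vector(local: SiteContents) -> InputVector:
    """The GRN input seen at a site: each bit is 'any such token present',
    with LPS meaning an LPS-bearing antigen token."""
    return InputVector(
        IFNg=local.count("IFNg") > 0,
        IL10=local.count("IL10") > 0,
        IL4=local.count("IL4") > 0,
        LPS=local.count("Ag_lps") > 0,
    )


def differentiation_update(
    m: CellAgent,
    local: SiteContents,
    net: RegulatoryNetwork,
    k: int = 1,
    rng: np.random.Generator | None = None,
) -> CellAgent:
    """Give one undifferentiated macrophage its per-step chance to commit.

    Applies only to M0 macrophages in the active or presenting state: the
    local input vector is clamped onto the embedded network state, the Boolean
    dynamics is advanced ``k`` synchronous steps, and if the resulting state
    is the M1 (resp. M2) attractor the macrophage terminally differentiates;
    otherwise it stays M0 and retains the advanced state.  Commitment is
    absorbing: committed macrophages are returned unchanged.  ``rng`` is
    accepted for interface symmetry; the update is deterministic.
    """
    if m.kind != "M":
        raise ValueError("differentiation_update applies to macrophages only")
    if m.phenotype != "M0" or m.activation == "r":
        return m
    state = m.grn_state if m.grn_state is not None else net.zero_state()
    I = local_input_vector(local)
    new_state = iterate(state, I, k, net)
    label = classify(new_state, net)
    phenotype = {
        AttractorLabel.M1_COMMITTED: "M1",
        AttractorLabel.M2_COMMITTED: "M2",
        AttractorLabel.UNCOMMITTED: "M0",
    }[label]
    return replace(m, phenotype=phenotype, grn_state=new_state)
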