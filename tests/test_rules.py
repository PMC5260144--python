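"""Reaction-rule table: construction, serialization, single-site semantics."""
import numpy as np
import pytest
from scipy import stats

from macpol import (
    CellAgent,
    RuleParams,
    SiteContents,
    apply_rules_at_site,
    build_rule_table,
    load_rules,
    rules_to_text,
)
from macpol.errors import RuleFormatError
from macpol.fixtures import make_fixture
from macpol.rules import parse_rule


def census(site):
    out = {}
    for a in site.agents:
        key = f"{a.kind}{a.phenotype or ''}^{a.activation}"
        out[key] = out.get(key, 0) + 1
    return out


class TestRuleTable:
    def test_fifteen_rules_with_unit_probability(self, rules):
        assert [r.rule_id for r in rules] == list(range(1, 16))
        assert all(r.probability == 1.0 for r in rules)

    def test_serialization_round_trip(self, rules):
        text = rules_to_text(rules)
        again = load_rules(text, is_text=True)
        assert again == rules

    def test_probability_override(self):
        table = build_rule_table(RuleParams(probabilities={10: 0.25}))
        assert next(r for r in table if r.rule_id == 10).probability == 0.25

    def test_literal_variants(self):
        literal = build_rule_table(
            RuleParams(
                phenotype_gated_secretion=False,
                bcell_activates_helpers=False,
                r11_duplicates_h2=False,
            )
        )
        by_id = {r.rule_id: r.text() for r in literal}
        assert by_id[5] == "M^p + H1^a -> M^p + H1^a + IFNg"
        assert by_id[11] == "B^p + H2^a -> 2 B^p + 2 H1^a + IL4 + Ab"
        assert by_id[12] == "H^r + M^p -> H^a + M^p"

    def test_malformed_rule_rejected(self):
        with pytest.raises(RuleFormatError):
            parse_rule(99, "M^r + IFNg M^a", 1.0)
        with pytest.raises(RuleFormatError):
            parse_rule(99, "M^r + Unknown -> M^a", 1.0)
        with pytest.raises(RuleFormatError):
            parse_rule(99, "M^r -> M^a", 2.0)


class TestSingleSiteSemantics:
    def test_empty_site_unchanged(self, rules, rng):
        out = apply_rules_at_site(SiteContents(), rules, rng)
        assert out.agents == [] and out.tokens == {}

    def test_macrophage_activation_keeps_catalytic_ifng(self, rules, rng):
        site = make_fixture("micro_lattice", rng, recipe="r1")
        out = apply_rules_at_site(site, rules, rng)
        assert census(out) == {"MM0^a": 1}
        assert out.tokens.get("IFNg", 0) == 1  # catalytic by default

    def test_macrophage_activation_can_consume_ifng(self, rng):
        literal = build_rule_table(RuleParams(ifng_consumed_on_activation=True))
        site = make_fixture("micro_lattice", rng, recipe="r1")
        out = apply_rules_at_site(site, literal, rng)
        assert census(out) == {"MM0^a": 1}
        assert out.tokens.get("IFNg", 0) == 0

    def test_presenting_m1_with_th1_releases_ifng(self, rules, rng):
        # rule 5 in isolation (in the full table, R3/R13 may pre-empt the pair)
        r5 = [r for r in rules if r.rule_id == 5]
        site = make_fixture("micro_lattice", rng, recipe="r5")
        out = apply_rules_at_site(site, r5, rng)
        assert out.tokens.get("IFNg", 0) == 1
        assert census(out) == {"MM1^p": 1, "H1^a": 1}

    def test_presenting_m2_with_th1_is_gated(self, rules, rng):
        site = SiteContents(
            agents=[
                CellAgent(kind="M", activation="p", phenotype="M2"),
                CellAgent(kind="H1", activation="a"),
            ]
        )
        out = apply_rules_at_site(site, rules, rng)
        assert out.tokens.get("IFNg", 0) == 0

    def test_bcell_th1_duplication(self, rules, rng):
        r10 = [r for r in rules if r.rule_id == 10]
        site = make_fixture("micro_lattice", rng, recipe="r10")
        out = apply_rules_at_site(site, r10, rng)
        assert census(out) == {"B^p": 2, "H1^a": 2}
        assert out.tokens.get("IFNg") == 1 and out.tokens.get("Ab") == 1

    def test_antibody_neutralizes_antigen(self, rules, rng):
        site = make_fixture("micro_lattice", rng, recipe="r15")
        out = apply_rules_at_site(site, rules, rng)
        assert out.tokens == {}

    def test_phagocytosis_consumes_antigen(self, rules, rng):
        site = SiteContents(
            agents=[CellAgent(kind="M", activation="a")], tokens={"Ag_lps": 1}
        )
        out = apply_rules_at_site(site, rules, rng)
        assert census(out) == {"MM0^p": 1}
        assert out.tokens.get("Ag_lps", 0) == 0

    def test_each_entity_fires_at_most_once(self):
        # M^r + 2 IFNg with the literal consuming rule: R1 fires once,
        # exactly one token is consumed, and the freshly activated macrophage
        # cannot be deactivated again in the same step
        literal = build_rule_table(RuleParams(ifng_consumed_on_activation=True))
        for seed in range(40):
            site = SiteContents(
                agents=[CellAgent(kind="M", activation="r")], tokens={"IFNg": 2}
            )
            out = apply_rules_at_site(site, literal, np.random.default_rng(seed))
            assert census(out) == {"MM0^a": 1}
            assert out.tokens.get("IFNg") == 1

    def test_negative_counts_rejected(self, rules, rng):
        with pytest.raises(ValueError):
            apply_rules_at_site(SiteContents(tokens={"Ab": -1}), rules, rng)


def test_rule_order_shuffle_is_fair(rules):
    """Each rule is equally likely to be evaluated first at a site."""
    n = 15 * 400
    firsts = np.zeros(15, dtype=int)
    rng = np.random.default_rng(7)
    for _ in range(n // 15 * 15 // 15):  # 400 shuffles
        firsts[rng.permutation(15)[0]] += 1
    chi2 = stats.chisquare(firsts)
    assert chi2.pvalue > 0.001
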