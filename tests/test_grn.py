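"""Boolean network dynamics: the update map, clamping, iteration and
commitment classification."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from macpol import (
    AlignmentError,
    AttractorLabel,
    InputVector,
    apply_input,
    boolean_update,
    classify,
    iterate,
    validate_network,
)

I_M1 = InputVector(IFNg=True, IL10=False, IL4=False, LPS=True)
I_M2 = InputVector(IFNg=False, IL10=False, IL4=True, LPS=False)
I_OFF = InputVector(False, False, False, False)


def state_with(net, *active):
    s = net.zero_state()
    for name in active:
        s[net.index(name)] = 1
    return s


def active_nodes(net, s):
    return {n for n, b in zip(net.nodes, s) if b}


class TestBooleanUpdate:
    def test_zero_state_is_invariant(self, net):
        z = net.zero_state()
        assert np.array_equal(boolean_update(z, net), z)

    def test_single_receptor_propagates_one_level(self, net):
        # IFNgR active without its ligand: STAT1 switches on, IFNgR decays
        s = state_with(net, "IFNgR")
        nxt = boolean_update(s, net)
        assert active_nodes(net, nxt) == {"STAT1"}

    def test_inhibition_beats_activation(self, net):
        # NF-kB has TLR4 as activator but STAT3 among its inhibitors
        s = state_with(net, "TLR4", "STAT3")
        nxt = boolean_update(s, net)
        assert nxt[net.index("NF-kB")] == 0

    def test_input_nodes_hold_their_value(self, net):
        s = state_with(net, "IFNg", "IL4")
        nxt = boolean_update(s, net)
        assert nxt[net.index("IFNg")] == 1 and nxt[net.index("IL4")] == 1

    def test_misaligned_state_raises(self, net):
        with pytest.raises(AlignmentError):
            boolean_update(np.zeros(5, dtype=np.uint8), net)

    def test_update_is_pure_and_deterministic(self, net, rng):
        s = (rng.random(net.n_nodes) < 0.5).astype(np.uint8)
        copy = s.copy()
        a = boolean_update(s, net)
        b = boolean_update(s, net)
        assert np.array_equal(a, b)
        assert np.array_equal(s, copy)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**18 - 1))
    def test_monotone_absence(self, packed):
        """A node with no active activating parent is inactive next step."""
        net = _NET
        c = net.compiled
        s = c.unpack(packed)
        nxt = boolean_update(s, net)
        for i, name in enumerate(net.nodes):
            if name in net.input_nodes:
                continue
            parents = net.activators.get(name, frozenset())
            if not any(s[net.index(p)] for p in parents):
                assert nxt[i] == 0


# hypothesis can't take fixtures in @given tests; module-level default network
from macpol import load_default_network  # noqa: E402

_NET = load_default_network()


class TestApplyInputAndIterate:
    def test_zero_state_zero_input(self, net):
        z = net.zero_state()
        assert np.array_equal(apply_input(z, I_OFF, net), z)

    def test_single_input_forced(self, net):
        out = apply_input(net.zero_state(), InputVector(True, False, False, False), net)
        assert active_nodes(net, out) == {"IFNg"}

    def test_non_input_bits_untouched(self, net):
        s = state_with(net, "STAT6")
        out = apply_input(s, InputVector(False, False, True, False), net)
        assert active_nodes(net, out) == {"STAT6", "IL4"}

    def test_k_must_be_positive(self, net):
        with pytest.raises(ValueError):
            iterate(net.zero_state(), I_M1, 0, net)

    def test_fixed_point_is_invariant_under_iterate(self, net):
        x1 = iterate(net.zero_state(), I_M1, 12, net)
        for k in (1, 3, 7):
            assert np.array_equal(iterate(x1, I_M1, k, net), x1)

    def test_m1_stimulus_reaches_nos2_attractor(self, net):
        x1 = iterate(net.zero_state(), I_M1, 6, net)
        assert x1[net.index("NOS2")] == 1
        assert classify(x1, net) is AttractorLabel.M1_COMMITTED

    def test_m2_stimulus_reaches_arg1_attractor(self, net):
        x2 = iterate(net.zero_state(), I_M2, 6, net)
        assert x2[net.index("Arg1")] == 1
        assert classify(x2, net) is AttractorLabel.M2_COMMITTED

    def test_inputs_clamped_throughout(self, net):
        # after one step the stimulus is still on: IL4 bit survives k=5
        out = iterate(net.zero_state(), I_M2, 5, net)
        assert out[net.index("IL4")] == 1


class TestClassify:
    def test_x1_x2_distinct_labels(self, net):
        rep = validate_network(net)
        assert rep.ok, rep.messages
        assert classify(rep.x1, net) is AttractorLabel.M1_COMMITTED
        assert classify(rep.x2, net) is AttractorLabel.M2_COMMITTED
        assert not np.array_equal(rep.x1, rep.x2)

    def test_zero_state_uncommitted(self, net):
        assert classify(net.zero_state(), net) is AttractorLabel.UNCOMMITTED

    def test_transient_state_uncommitted(self, net):
        # one step into the M1 trajectory: not yet a fixed point
        s = iterate(net.zero_state(), I_M1, 1, net)
        assert classify(s, net) is AttractorLabel.UNCOMMITTED
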