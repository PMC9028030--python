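"""Masking-field chunking: habituation, masking, stability, round trips."""

import numpy as np
import pytest

from songmem import chunking as ck
from songmem.working_memory import WMGradient, rehearse


class TestHabituativeGate:
    def test_recovery_to_full_transmitter_without_signal(self):
        gate = ck.HabituativeGate(z=0.1, recovery=0.5, depletion=1.0)
        for _ in range(2000):
            gate = ck.habituate_step(gate, 0.0, 0.01)
        assert gate.z == pytest.approx(1.0, abs=1e-3)

    def test_equilibrium_matches_closed_form(self):
        gate = ck.HabituativeGate(recovery=0.1, depletion=1.0)
        z = gate
        for _ in range(20000):
            z = ck.habituate_step(z, 0.1, 0.01)
        assert z.z == pytest.approx(0.5, abs=1e-3)  # delta/(delta + rho S)

    def test_equilibrium_decreases_with_signal(self):
        gate = ck.HabituativeGate(recovery=0.1, depletion=1.0)
        eqs = [gate.equilibrium(S) for S in (0.0, 0.1, 0.5, 2.0)]
        assert all(a > b for a, b in zip(eqs, eqs[1:]))

    def test_bounds_preserved(self):
        gate = ck.HabituativeGate(z=1.0, recovery=0.01, depletion=50.0)
        for _ in range(100):
            gate = ck.habituate_step(gate, 10.0, 0.05)
            assert 0.0 <= gate.z <= 1.0


class TestRecognitionAndMasking:
    def test_whole_word_masks_its_subwords(self, word_network, store):
        net, ids = word_network
        C, winner = ck.chunk_activation(store("MYSELF"), net)
        assert net.field_.labels[winner] == "MYSELF"
        assert C[ids["MYSELF"]] > C[ids["MY"]]

    def test_subword_alone_selects_subword(self, word_network, store):
        net, _ = word_network
        _, winner = ck.chunk_activation(store("MY"), net)
        assert net.field_.labels[winner] == "MY"

    def test_empty_working_memory_has_no_winner(self, word_network):
        net, _ = word_network
        empty = WMGradient(activities={}, presentation_order=[], capacity=1.0)
        _, winner = ck.chunk_activation(empty, net)
        assert winner is None

    @pytest.mark.parametrize("prefix", ["MY", "MYS", "MYSE", "MYSEL"])
    def test_strict_prefixes_activate_longest_contained_chunk(
            self, word_network, store, prefix):
        net, _ = word_network
        _, winner = ck.chunk_activation(store(prefix), net)
        assert net.field_.labels[winner] == "MY"


class TestLearningStability:
    def test_first_pattern_commits_one_chunk(self, store):
        net = ck.ChunkNetwork()
        cid = ck.learn(store("ABC"), net)
        assert len(net.field_.scales) == 1
        _, winner = ck.chunk_activation(store("ABC"), net)
        assert winner == cid

    def test_learning_longer_word_does_not_recode_shorter(self, store):
        net = ck.ChunkNetwork()
        c_my = ck.learn(store("MY"), net, label="MY")
        before = dict(net.filter.weights[c_my])
        ck.learn(store("MYSELF"), net, label="MYSELF")
        after = net.filter.weights[c_my]
        assert max(abs(before[c] - after[c]) for c in before) < 1e-6
        _, winner = ck.chunk_activation(store("MY"), net)
        assert winner == c_my

    def test_interleaved_replay_keeps_all_labels(self, store):
        net = ck.ChunkNetwork()
        schedule = ["MY", "MYSELF", "MY", "SELF", "MYSELF", "ELF", "MY"]
        for word in schedule:
            ck.learn(store(word), net, label=word)
        for word in ("MY", "SELF", "ELF", "MYSELF"):
            _, winner = ck.chunk_activation(store(word), net)
            assert net.field_.labels[winner] == word

    def test_repeated_training_converges(self, store):
        net = ck.ChunkNetwork()
        cid = ck.learn(store("ABC"), net)
        w1 = dict(net.filter.weights[cid])
        ck.learn(store("ABC"), net)
        w2 = net.filter.weights[cid]
        assert max(abs(w1[c] - w2[c]) for c in w1) < 1e-9

    def test_weights_bounded_in_unit_interval(self, word_network):
        net, _ = word_network
        for W in list(net.filter.weights.values()) + list(net.expectation.weights.values()):
            assert all(0.0 <= v <= 1.0 for v in W.values())

    def test_capacity_exhaustion_raises(self, store):
        net = ck.ChunkNetwork()
        net.field_.capacity = 1
        ck.learn(store("AB"), net)
        with pytest.raises(ck.ChunkCapacityError):
            ck.learn(store("CD"), net)


class TestExpectationReadout:
    def test_readout_reproduces_training_order(self, store, wm_params_topdown):
        net = ck.ChunkNetwork()
        cid = ck.learn(store("ABC"), net)
        g = ck.readout_expectation(cid, net, volition=True)
        trace = rehearse(g, wm_params_topdown)
        assert [e[0] for e in trace.events] == ["A", "B", "C"]

    def test_readout_preserves_stored_ratios(self, store):
        net = ck.ChunkNetwork()
        stored = store("ABC")
        cid = ck.learn(stored, net)
        g = ck.readout_expectation(cid, net, volition=True)
        x_in = stored.activity_vector()
        x_out = np.array([g.activities[c] for c in stored.presentation_order])
        ratios_in = x_in / x_in[0]
        ratios_out = x_out / x_out[0]
        assert np.allclose(ratios_in, ratios_out, atol=1e-3)

    def test_without_volition_expectation_only_primes(self, store):
        net = ck.ChunkNetwork()
        cid = ck.learn(store("ABC"), net)
        g = ck.readout_expectation(cid, net, volition=False)
        assert max(g.activities.values()) < net.firing_threshold

    def test_uncommitted_chunk_raises(self):
        net = ck.ChunkNetwork()
        with pytest.raises(KeyError):
            ck.readout_expectation(99, net)


def test_habituation_gates_reduce_repeated_drive(store):
    """Driving the same winner repeatedly depletes its bottom-up gates."""
    net = ck.ChunkNetwork()
    cid = ck.learn(store("ABC"), net)
    g = store("ABC")
    first, _ = ck.chunk_activation(g, net, update_gates=True, dt=2.0)
    for _ in range(20):
        ck.chunk_activation(g, net, update_gates=True, dt=2.0)
    later, _ = ck.chunk_activation(g, net)
    assert later[cid] < first[cid]


def test_network_serializes_to_versioned_dict(word_network):
    net, _ = word_network
    d = net.to_dict()
    assert d["schema_version"] == 1
    assert {c["label"] for c in d["chunks"].values()} == {"MY", "SELF", "ELF", "MYSELF"}
    my = next(c for c in d["chunks"].values() if c["label"] == "MY")
    assert my["scale"] == 2


def test_model_file_round_trip(word_network, store, tmp_path):
    net, _ = word_network
    path = tmp_path / "chunks.json"
    net.save(path)
    net2 = ck.ChunkNetwork.load(path)
    for word in ("MY", "SELF", "ELF", "MYSELF"):
        _, winner = ck.chunk_activation(store(word), net2)
        assert net2.field_.labels[winner] == word
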