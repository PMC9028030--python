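"""Item-Order-Rank working memory: gradients, spans, recall phenomena."""

import numpy as np
import pytest

from songmem import working_memory as wm
from songmem.working_memory import (ItemSequence, WMGradient, WMParams,
                                    gradient_shape, immediate_span,
                                    last_item_rebound, present_sequence,
                                    rehearse, serial_position_curve,
                                    transient_span)


class TestStorage:
    def test_short_list_stores_primacy_gradient(self, wm_params):
        g = present_sequence(ItemSequence(list("ABC")), wm_params)
        x = g.activity_vector()
        assert np.all(np.diff(x) < 0) and np.all(x > 0)
        assert gradient_shape(g) == "primacy"

    def test_empty_sequence_gives_empty_gradient(self, wm_params):
        g = present_sequence(ItemSequence([]), wm_params)
        assert len(g) == 0 and g.total_activity == 0.0

    def test_repeated_items_occupy_rank_hypercolumns(self, wm_params):
        g = present_sequence(ItemSequence(list("ABAC")), wm_params)
        assert g.presentation_order == [("A", 1), ("B", 1), ("A", 2), ("C", 1)]
        assert np.all(np.diff(g.activity_vector()) < 0)

    def test_rank_of_kth_occurrence_is_k(self, wm_params):
        seq = list("ABACBDAAB")
        g = present_sequence(ItemSequence(seq), wm_params)
        seen: dict = {}
        for tok, (cell_tok, rank) in zip(seq, g.presentation_order):
            seen[tok] = seen.get(tok, 0) + 1
            assert cell_tok == tok and rank == seen[tok]

    def test_vocabulary_error_outside_alphabet(self):
        params = WMParams(alphabet=("A", "B"))
        with pytest.raises(wm.VocabularyError):
            present_sequence(ItemSequence(list("ABX")), params)

    def test_ltm_invariance_ratios_preserved(self, wm_params):
        """Storing a new item leaves ratios of earlier activities unchanged."""
        prev_ratios = None
        for L in range(2, 8):
            g = present_sequence(ItemSequence([f"t{i}" for i in range(L)]),
                                 wm_params)
            x = g.activity_vector()
            ratios = x[0] / x[1:L - 1] if L > 2 else np.array([])
            if prev_ratios is not None and ratios.size:
                n = prev_ratios.size
                assert np.allclose(ratios[:n], prev_ratios, rtol=1e-3)
            prev_ratios = x[0] / x[1:]

    def test_normalization_total_bounded_per_item_shrinks(self, wm_params):
        totals, means = [], []
        for L in range(1, 12):
            g = present_sequence(ItemSequence([f"t{i}" for i in range(L)]),
                                 wm_params)
            totals.append(g.total_activity)
            means.append(g.total_activity / L)
        assert np.all(np.diff(totals) > 0)
        assert max(totals) < wm_params.shunting.B
        assert np.all(np.diff(means) < 0)


class TestGradientShape:
    @pytest.mark.parametrize("acts, expected", [
        ((0.5, 0.3, 0.2), "primacy"),
        ((0.5, 0.2, 0.4), "bowed"),
        ((0.1, 0.2, 0.4), "recency"),
        ((0.3, 0.3, 0.3), "flat"),
    ])
    def test_classification(self, acts, expected):
        order = [(f"t{i}", 1) for i in range(len(acts))]
        g = WMGradient(activities=dict(zip(order, acts)),
                       presentation_order=order, capacity=1.0,
                       drives=dict(zip(order, acts)))
        assert gradient_shape(g) == expected

    def test_long_list_bows(self, wm_params):
        g = present_sequence(ItemSequence([f"t{i}" for i in range(9)]),
                             wm_params)
        assert gradient_shape(g) == "bowed"


class TestRehearsal:
    def test_primacy_gradient_recalled_in_order(self, wm_params):
        g = present_sequence(ItemSequence(list("ABC")), wm_params)
        trace = rehearse(g, wm_params)
        assert [e[0] for e in trace.events] == ["A", "B", "C"]
        lat = [e[2] for e in trace.events]
        assert np.all(np.diff(lat) > 0)

    def test_recall_is_complete_and_without_repeats(self, wm_params):
        seq = list("ABACBD")
        g = present_sequence(ItemSequence(seq), wm_params)
        trace = rehearse(g, wm_params)
        cells = [(e[0], e[1]) for e in trace.events]
        assert sorted(cells) == sorted(g.presentation_order)
        assert len(set(cells)) == len(cells)

    def test_bowed_gradient_recalls_ends_first(self, wm_params):
        g = present_sequence(ItemSequence([f"t{i}" for i in range(9)]),
                             wm_params)
        trace = rehearse(g, wm_params)
        first_two = {e[0] for e in trace.events[:2]}
        assert "t0" in first_two  # list start recalled earliest
        # the last recalled items are interior ones
        x = g.activity_vector()
        interior_min = int(np.argmin(x))
        assert trace.events[-1][0] == f"t{interior_min}"

    def test_exact_tie_broken_by_presentation_index(self, wm_params):
        order = [("A", 1), ("B", 1)]
        g = WMGradient(activities={("A", 1): 0.3, ("B", 1): 0.3},
                       presentation_order=order, capacity=1.0,
                       drives={("A", 1): 0.5, ("B", 1): 0.5})
        trace = rehearse(g, wm_params)
        assert [e[0] for e in trace.events] == ["A", "B"]

    def test_last_item_rebounds_after_penultimate_readout(self, wm_params):
        g = present_sequence(ItemSequence(list("ABCD")), wm_params)
        trace = last_item_rebound(g, wm_params)
        stored = g.activities[g.presentation_order[-1]]
        assert max(trace[1:]) > stored
        assert trace[-1] > trace[0]  # freed from inhibition at the end

    def test_two_item_rebound(self, wm_params):
        g = present_sequence(ItemSequence(list("AB")), wm_params)
        trace = last_item_rebound(g, wm_params)
        assert trace[-1] > trace[0]

    def test_single_item_trace_monotone(self, wm_params):
        g = present_sequence(ItemSequence(["A"]), wm_params)
        trace = last_item_rebound(g, wm_params)
        assert len(trace) == 1


class TestSpans:
    def test_transient_span_is_four(self, wm_params):
        assert transient_span(wm_params) == 4

    def test_immediate_span_is_seven(self, wm_params_topdown):
        assert immediate_span(wm_params_topdown) == 7

    def test_top_down_support_never_shrinks_the_span(self, wm_params):
        base = transient_span(wm_params)
        for lam in (0.2, 0.5, 1.0, 2.0, 5.0):
            assert wm._span(wm_params.with_top_down(lam)) >= base

    def test_zero_support_reduces_to_transient_span(self, wm_params):
        assert wm._span(wm_params.with_top_down(0.0)) == transient_span(wm_params)

    def test_span_monotone_in_input_intensity(self, wm_params):
        """Stronger item inputs load the field faster: span cannot grow."""
        from dataclasses import replace
        spans = [wm._span(replace(wm_params, input_intensity=I))
                 for I in (0.25, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(spans, spans[1:]))


@pytest.fixture(scope="module")
def curve():
    params = WMParams(noise_sigma=0.02, recall_threshold=0.08,
                      rehearsal_fade=0.88, seed=3)
    return serial_position_curve(12, 400, params)


class TestSerialPositionCurve:
    def test_recall_probability_is_u_shaped(self, curve):
        rp = curve["recall_prob"]
        assert np.all((0 <= rp) & (rp <= 1))
        ends = 0.5 * (rp[0] + rp[-1])
        middle = rp[4:8].mean()
        assert ends > middle + 0.2

    def test_transpositions_are_local(self, curve):
        sp = curve["swap_prob"]
        assert sp[1] > sp[3]

    def test_noise_free_recall_is_deterministic(self):
        params = WMParams(noise_sigma=0.0)
        res = serial_position_curve(5, 3, params)
        assert np.all(res["recall_prob"] == 1.0)
        assert all(v == 0.0 for v in res["swap_prob"].values())


def test_gradient_csv_round_trip(tmp_path, wm_params):
    g = present_sequence(ItemSequence(list("ABAC")), wm_params)
    df = wm.gradient_to_frame(g)
    path = tmp_path / "gradient.csv"
    df.to_csv(path, index=False)
    import pandas as pd

    back = pd.read_csv(path)
    assert list(back["token"]) == ["A", "B", "A", "C"]
    assert list(back["rank"]) == [1, 1, 2, 1]
    assert np.allclose(back["activity"], g.activity_vector())
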