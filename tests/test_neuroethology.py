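"""Behavioral-sequence summaries, dyad chi-square, flowchart export."""

import json
import math

import numpy as np
import pytest
from scipy import stats

from kindlekit.neuroethology import (
    BehaviorSequence,
    bouts,
    build_flowchart,
    dyad_interactions,
    dyad_interactions_pooled,
    export_flowchart,
    flowchart_from_json,
    parse_dot,
    summarize,
    summarize_pooled,
    to_dot,
    to_json,
    validate_flowchart_json,
)

CATS = {"A": "exploratory", "B": "grooming", "C": "limbic", "D": "other", "X": "other"}


def seq_of(codes):
    return BehaviorSequence.from_codes(codes)


# --- summaries ------------------------------------------------------------


def test_single_bout_summary():
    s = summarize(seq_of(["A", "A", "A"]))
    assert s.frequency == {"A": 1}
    assert s.mean_duration_s == {"A": 3.0}
    assert s.proportional_time == {"A": 1.0}


def test_summary_hand_enumerated():
    s = summarize(seq_of(["A", "A", "B", "A"]))
    assert s.frequency == {"A": 2, "B": 1}
    assert s.mean_duration_s["A"] == pytest.approx(1.5)
    assert s.mean_duration_s["B"] == pytest.approx(1.0)
    assert sum(s.proportional_time.values()) == pytest.approx(1.0)


def test_alternating_closed_form():
    s = summarize(seq_of(["A", "B"] * 150))
    assert s.frequency == {"A": 150, "B": 150}
    assert s.mean_duration_s == {"A": 1.0, "B": 1.0}


def test_gapless_coding_enforced():
    with pytest.raises(ValueError, match="gapless"):
        BehaviorSequence("a", 1, "PRE", events=((0, "A"), (2, "B")))


def test_summary_invariant_to_split_at_bout_boundary():
    codes = ["A", "A", "B", "C", "C", "C", "A", "B", "B"]
    whole = summarize(seq_of(codes))
    parts = [
        BehaviorSequence.from_codes(codes[:3]),
        BehaviorSequence.from_codes(codes[3:], t0=3),
    ]
    pooled = summarize_pooled(parts)
    assert pooled.frequency == whole.frequency
    assert pooled.mean_duration_s == whole.mean_duration_s
    assert pooled.proportional_time == whole.proportional_time


# --- dyads ----------------------------------------------------------------


def test_two_bout_dyad_is_degenerate():
    dyads = dyad_interactions(seq_of(["A", "B"]))
    assert len(dyads) == 1
    d = dyads[0]
    assert (d.pre_code, d.post_code) == ("A", "B")
    assert math.isnan(d.chi2)
    assert not d.significant


def test_fewer_than_two_bouts_gives_empty_list():
    assert dyad_interactions(seq_of(["A", "A", "A"])) == []


def test_constructed_dyad_reaches_closed_form_twenty():
    """8 exclusive A->B transitions among 20 give chi2 = 20 ([[8,0],[0,12]])."""
    bout_chain = ["A", "B", "A", "B", "A", "B"] + ["C", "A", "B"] * 5
    dyads = {((d.pre_code, d.post_code)): d for d in dyad_interactions(seq_of(bout_chain))}
    d = dyads[("A", "B")]
    assert d.observed == 8
    assert d.chi2 == pytest.approx(20.0)
    assert d.log_chi2 == pytest.approx(math.log10(20.0))
    assert d.significant


def test_observed_transitions_sum_to_bout_count_minus_one(rng):
    codes = [str(c) for c in rng.integers(0, 4, size=120)]
    seq = seq_of(codes)
    dyads = dyad_interactions(seq)
    assert sum(d.observed for d in dyads) == len(bouts(seq)) - 1


def _bruteforce_dyads(seq):
    """Independent contingency oracle: explicit 2x2 per ordered pair."""
    runs = [b.code for b in bouts(seq)]
    transitions = list(zip(runs, runs[1:]))
    out = {}
    for a in set(runs):
        for b in set(runs):
            table = np.zeros((2, 2), dtype=int)
            for (x, y) in transitions:
                table[0 if x == a else 1, 0 if y == b else 1] += 1
            if table[0].sum() == 0:
                continue  # pair never starts from a
            if table[0, 0] == 0:
                continue  # only observed pairs are reported
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                out[(a, b)] = float("nan")
            else:
                chi2, _, _, _ = stats.chi2_contingency(table, correction=False)
                out[(a, b)] = chi2
    return out


@pytest.mark.parametrize("seed", range(8))
def test_dyad_chi2_matches_bruteforce_contingency(seed):
    rng = np.random.default_rng(seed)
    n_codes = int(rng.integers(2, 6))
    codes = [str(c) for c in rng.integers(0, n_codes, size=int(rng.integers(5, 31)))]
    seq = seq_of(codes)
    if len(bouts(seq)) > 30:
        codes = codes[:30]
        seq = seq_of(codes)
    oracle = _bruteforce_dyads(seq)
    mine = {(d.pre_code, d.post_code): d.chi2 for d in dyad_interactions(seq)}
    assert set(mine) == set(oracle)
    for pair, expected in oracle.items():
        if math.isnan(expected):
            assert math.isnan(mine[pair])
        else:
            assert mine[pair] == pytest.approx(expected)


def test_significance_requires_attraction():
    """A strongly *avoided* pairing has large chi2 but draws no arrow."""
    # A never goes to B although both are common
    bout_chain = ["A", "C", "B", "D"] * 10
    dyads = {(d.pre_code, d.post_code): d for d in dyad_interactions(seq_of(bout_chain))}
    d = dyads[("C", "B")]
    assert d.significant  # attraction: C -> B always
    assert ("A", "B") not in dyads  # never observed, never reported


def test_permutation_abolishes_structure(rng):
    """Shuffling bout order drives the flag rate to the nominal level.

    Uses a glossary-sized (8-code) alphabet: the 2x2-from-margins dyad
    table ignores that self-transitions are structurally impossible, a bias
    that shrinks as the alphabet grows and stays within the nominal bound
    at ethogram-realistic code counts.
    """
    run_codes = [c for c in "ABCDEFGH" for _ in range(20)]
    n_sig = 0
    n_dyads = 0
    for _ in range(60):
        perm = list(run_codes)
        rng.shuffle(perm)
        collapsed = [perm[0]] + [c for prev, c in zip(perm, perm[1:]) if c != prev]
        dyads = dyad_interactions(seq_of(collapsed))
        n_sig += sum(d.significant for d in dyads)
        n_dyads += len(dyads)
    assert n_sig / n_dyads < 0.10


def test_bonferroni_flag_is_stricter():
    bout_chain = ["A", "B", "C"] * 10
    plain = dyad_interactions(seq_of(bout_chain))
    strict = dyad_interactions(seq_of(bout_chain), bonferroni=True)
    assert sum(d.significant for d in strict) <= sum(d.significant for d in plain)


def test_pooled_dyads_do_not_cross_animal_boundaries():
    # each animal only ever shows A->B; pooling must not invent B->A
    seqs = [seq_of(["A", "B"]), seq_of(["B", "A"])]
    pooled = dyad_interactions_pooled(seqs)
    observed = {(d.pre_code, d.post_code): d.observed for d in pooled}
    assert observed == {("A", "B"): 1, ("B", "A"): 1}


# --- flowcharts -----------------------------------------------------------


def _graph():
    seq = seq_of(["A", "B", "A", "B", "A", "B"] + ["C", "A", "B"] * 5)
    summary = summarize(seq)
    dyads = dyad_interactions(seq)
    return build_flowchart({"PRE": summary}, {"PRE": dyads}, CATS)


def test_flowchart_edges_only_for_significant_dyads():
    g = _graph()
    assert {(e.pre_code, e.post_code) for e in g.edges} == {
        (d.pre_code, d.post_code)
        for d in dyad_interactions(seq_of(["A", "B", "A", "B", "A", "B"] + ["C", "A", "B"] * 5))
        if d.significant
    }
    assert all(any(n.code == e.pre_code for n in g.nodes) for e in g.edges)


def test_flowchart_empty_dyads_gives_nodes_only():
    g = build_flowchart({"PRE": summarize(seq_of(["A", "A", "B"]))}, {}, CATS)
    assert len(g.nodes) == 2 and g.edges == ()


def test_flowchart_missing_category_names_the_code():
    with pytest.raises(ValueError, match="'B'"):
        build_flowchart({"PRE": summarize(seq_of(["A", "B"]))}, {}, {"A": "other"})


def test_flowchart_cells_follow_protocol_order():
    summary = summarize(seq_of(["A", "B"]))
    g = build_flowchart({"POST": summary, "PRE": summary}, {}, CATS)
    assert g.periods == ("PRE", "POST")


def test_dot_round_trip_is_lossless():
    g = _graph()
    assert parse_dot(to_dot(g)) == g
    assert to_dot(parse_dot(to_dot(g))) == to_dot(g)


def test_json_round_trip_and_schema():
    g = _graph()
    text = to_json(g)
    validate_flowchart_json(text)
    assert flowchart_from_json(text) == g


def test_schema_rejects_malformed_payload():
    bad = json.dumps({"periods": [], "nodes": [{"code": "A"}], "edges": []})
    with pytest.raises(ValueError, match="required"):
        validate_flowchart_json(bad)


def test_export_formats(tmp_path):
    g = _graph()
    for fmt, suffix in (("DOT", ".dot"), ("JSON", ".json"), ("SVG", ".svg")):
        path = export_flowchart(g, tmp_path / f"fc{suffix}", fmt)
        assert path.exists() and path.stat().st_size > 0
    with pytest.raises(ValueError, match="format"):
        export_flowchart(g, tmp_path / "fc.xyz", "XYZ")
    assert "<svg" in (tmp_path / "fc.svg").read_text()
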