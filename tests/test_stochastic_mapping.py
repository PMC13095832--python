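"""Stochastic character maps: invariants and distributional correctness."""

import numpy as np
import pytest
from scipy.stats import chisquare

import cutevo as cv
from cutevo.errors import ValidationError
from cutevo.stochastic_mapping import sample_history
from oracles import n_real_transitions, random_tip_vectors, random_tree, rejection_branch_history

LABELS3 = ("dicot", "grass", "dicot_grass")
LABELS2 = ("dicot", "grass")


def test_zero_length_branch_paths():
    model = cv.MkModel(LABELS2, 1.0)
    rng = np.random.default_rng(0)
    assert cv.sample_branch_history(0, 0, 0.0, model, rng) == [(0, 0.0)]
    with pytest.raises(ValidationError):
        cv.sample_branch_history(0, 1, 0.0, model, rng)


def test_forced_endpoints_have_a_transition(rng):
    model = cv.MkModel(LABELS3, 0.5)
    for _ in range(200):
        segs = cv.sample_branch_history(0, 2, 1.0, model, rng)
        assert segs[0][0] == 0 and segs[-1][0] == 2
        assert n_real_transitions(segs) >= 1
        assert sum(d for _, d in segs) == pytest.approx(1.0, abs=1e-9)
        assert all(d >= 0 for _, d in segs)


def test_uniformization_matches_rejection_mean_transitions(rng):
    """k=2, q=1, t=1, endpoints 0->1: mean transition count agrees."""
    model = cv.MkModel(LABELS2, 1.0)
    n = 20_000
    uni = np.array(
        [
            n_real_transitions(cv.sample_branch_history(0, 1, 1.0, model, rng))
            for _ in range(n)
        ]
    )
    rej = np.array(
        [
            n_real_transitions(rejection_branch_history(0, 1, 1.0, model, rng))
            for _ in range(n)
        ]
    )
    se = np.sqrt(uni.var() / n + rej.var() / n)
    assert abs(uni.mean() - rej.mean()) <= 3 * se


def test_uniformization_vs_rejection_distribution_chisquare(rng):
    model = cv.MkModel(LABELS3, 0.6)
    n = 20_000
    uni = [n_real_transitions(cv.sample_branch_history(0, 0, 1.5, model, rng)) for _ in range(n)]
    rej = [n_real_transitions(rejection_branch_history(0, 0, 1.5, model, rng)) for _ in range(n)]
    top = max(max(uni), max(rej))
    f_uni = np.bincount(uni, minlength=top + 1).astype(float)
    f_rej = np.bincount(rej, minlength=top + 1).astype(float)
    keep = (f_uni + f_rej) >= 10
    f_exp = f_rej[keep] * f_uni[keep].sum() / f_rej[keep].sum()
    stat, p = chisquare(f_uni[keep], f_exp)
    assert p > 0.01


def test_joint_node_states_deterministic_and_tip_consistent(ten_tip_instance):
    tree, vectors, model = ten_tip_instance
    s1 = cv.sample_joint_node_states(tree, vectors, model, np.random.default_rng(4))
    s2 = cv.sample_joint_node_states(tree, vectors, model, np.random.default_rng(4))
    assert s1 == s2
    for tip in tree.tips():
        assert vectors[tip.label][s1[tip.id]] == 1.0


def test_joint_root_frequencies_match_asr(ten_tip_instance):
    tree, vectors, model = ten_tip_instance
    recon = cv.marginal_asr_rerooting(tree, vectors, model)
    expected = recon.prob(tree.root.id)
    rng = np.random.default_rng(8)
    n = 4000
    counts = np.zeros(model.k)
    from cutevo.mk_model import pruning_log_likelihood

    partials = pruning_log_likelihood(tree, vectors, model).partials
    for _ in range(n):
        s = cv.sample_joint_node_states(tree, vectors, model, rng, partials)
        counts[s[tree.root.id]] += 1
    freq = counts / n
    se = np.sqrt(expected * (1 - expected) / n)
    assert np.all(np.abs(freq - expected) <= 3 * se + 1e-12)


def test_low_rate_monomorphic_gives_zero_transitions():
    tree = cv.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    vecs = {lab: np.array([0.0, 1.0, 0.0]) for lab in "ABCD"}
    model = cv.MkModel(LABELS3, 1e-9)
    histories = cv.stochastic_map(tree, vecs, model, 1, seed=3)
    assert histories[0].n_transitions() == 0
    assert all(s == 1 for s in histories[0].node_states.values())


def test_history_invariants_over_many_maps(ten_tip_instance):
    tree, vectors, model = ten_tip_instance
    histories = cv.stochastic_map(tree, vectors, model, 300, seed=21)
    for h in histories:
        h.validate(tree)
        summ = cv.summarize_map(h)
        assert summ.total_dwell_time == pytest.approx(
            tree.total_branch_length, rel=1e-9
        )
        assert summ.transitions_into.sum() == summ.n_transitions == h.n_transitions()


def test_same_seed_byte_identical_simmap(ten_tip_instance):
    tree, vectors, model = ten_tip_instance
    h1 = cv.stochastic_map(tree, vectors, model, 5, seed=77)
    h2 = cv.stochastic_map(tree, vectors, model, 5, seed=77)
    for a, b in zip(h1, h2):
        assert cv.write_simmap(tree, a) == cv.write_simmap(tree, b)
    h3 = cv.stochastic_map(tree, vectors, model, 5, seed=78)
    assert any(
        cv.write_simmap(tree, a) != cv.write_simmap(tree, c) for a, c in zip(h1, h3)
    )


def test_unseeded_map_request_errors(ten_tip_instance):
    tree, vectors, model = ten_tip_instance
    with pytest.raises(ValidationError, match="seed"):
        cv.stochastic_map(tree, vectors, model, 2, seed=None)


def test_summarize_map_hand_built():
    tree = cv.parse_newick("(A:1,B:2);")
    a = next(n for n in tree.tips() if n.label == "A")
    b = next(n for n in tree.tips() if n.label == "B")
    h = cv.CharacterHistory(
        state_labels=LABELS2,
        node_states={tree.root.id: 0, a.id: 1, b.id: 1},
        branch_segments={
            a.id: [(0, 0.5), (1, 0.5)],
            b.id: [(0, 1.2), (1, 0.8)],
        },
    )
    summ = cv.summarize_map(h)
    assert summ.transition_counts[0, 1] == 2
    assert summ.transition_counts[1, 0] == 0
    assert summ.dwell_times == pytest.approx([1.7, 1.3])
    assert summ.transitions_into.tolist() == [0, 2]


def test_long_branch_dwell_fractions_stationary(rng):
    """Unconditioned long-branch forward paths dwell ~uniformly (ER)."""
    from cutevo.synthetic_data import forward_branch_path

    model = cv.MkModel(LABELS3, 1.0)
    t = 50.0
    n = 400
    fractions = np.zeros(3)
    for _ in range(n):
        for s, d in forward_branch_path(0, t, model, rng):
            fractions[s] += d
    fractions /= n * t
    # SE of a dwell fraction over n long branches is small; allow 3x empirical
    assert np.all(np.abs(fractions - 1 / 3) < 0.02)


def test_expected_transitions_approach_rate_times_length(rng):
    """Unconditioned branches: E[#transitions] -> (k-1) q t."""
    from cutevo.synthetic_data import forward_branch_path

    model = cv.MkModel(LABELS3, 0.4)
    t = 2.5
    n = 4000
    counts = np.array(
        [n_real_transitions(forward_branch_path(0, t, model, rng)) for _ in range(n)]
    )
    expected = (model.k - 1) * model.q * t
    se = counts.std() / np.sqrt(n)
    assert abs(counts.mean() - expected) <= 3 * se
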