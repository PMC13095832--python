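"""Marginal ancestral-state reconstruction: two-pass vs literal re-rooting."""

import itertools

import numpy as np
import pytest

import cutevo as cv
from cutevo.errors import ValidationError
from oracles import random_tip_vectors, random_tree

LABELS3 = ("dicot", "grass", "dicot_grass")


def max_entry_diff(r1, r2):
    return max(
        float(np.max(np.abs(r1.prob(nid) - r2.prob(nid)))) for nid in r1.node_probs
    )


def test_root_marginal_matches_single_pruning_pass(rng):
    tree = random_tree(rng, 9, depth_scale=2.0)
    vecs = random_tip_vectors(rng, tree, 3)
    model = cv.MkModel(LABELS3, 0.5)
    recon = cv.marginal_asr_rerooting(tree, vecs, model)
    res = cv.pruning_log_likelihood(tree, vecs, model)
    w = model.pi * res.partials[tree.root.id]
    np.testing.assert_allclose(recon.prob(tree.root.id), w / w.sum(), atol=1e-12)


def test_star_tree_central_node_vs_enumeration():
    """3-tip star, k=2, tips (0,0,1): brute-force the central marginal."""
    tree = cv.parse_newick("(A:1,B:1,C:1);")
    model = cv.MkModel(("x", "y"), 0.4)
    tips = {"A": 0, "B": 0, "C": 1}
    vecs = {lab: np.eye(2)[s] for lab, s in tips.items()}
    P = model.transition_matrix(1.0)
    joint = np.array(
        [0.5 * P[s, tips["A"]] * P[s, tips["B"]] * P[s, tips["C"]] for s in range(2)]
    )
    expected = joint / joint.sum()
    recon = cv.marginal_asr_rerooting(tree, vecs, model)
    np.testing.assert_allclose(recon.prob(tree.root.id), expected, atol=1e-12)
    direct = cv.marginal_asr_direct(tree, vecs, model)
    np.testing.assert_allclose(direct.prob(tree.root.id), expected, atol=1e-12)


def test_low_rate_limit_all_dicot():
    tree = cv.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    vecs = {lab: np.array([1.0, 0.0, 0.0]) for lab in "ABCD"}
    model = cv.MkModel(LABELS3, 1e-8)
    recon = cv.marginal_asr_rerooting(tree, vecs, model)
    for node in tree.internal_nodes():
        np.testing.assert_allclose(recon.prob(node.id), [1, 0, 0], atol=1e-6)


def test_two_tip_symmetric_internal_is_half():
    tree = cv.parse_newick("(A:1,B:1);")
    vecs = {"A": np.array([1.0, 0.0]), "B": np.array([0.0, 1.0])}
    recon = cv.marginal_asr_rerooting(tree, vecs, cv.MkModel(("x", "y"), 0.7))
    np.testing.assert_allclose(recon.prob(tree.root.id), [0.5, 0.5], atol=1e-12)


def test_rerooting_vs_direct_small_battery():
    rng = np.random.default_rng(11)
    for _ in range(25):
        n = int(rng.integers(4, 30))
        tree = random_tree(rng, n, depth_scale=float(rng.uniform(0.5, 3)))
        k = int(rng.integers(2, 4))
        vecs = random_tip_vectors(rng, tree, k)
        model = cv.MkModel(tuple(f"s{j}" for j in range(k)), float(rng.uniform(0.05, 2)))
        r1 = cv.marginal_asr_rerooting(tree, vecs, model)
        r2 = cv.marginal_asr_direct(tree, vecs, model)
        assert max_entry_diff(r1, r2) <= 1e-8


def test_all_vectors_are_simplices(rng):
    tree = random_tree(rng, 15, depth_scale=1.5)
    vecs = random_tip_vectors(rng, tree, 3, p_ambiguous=0.3)
    recon = cv.marginal_asr_rerooting(tree, vecs, cv.MkModel(LABELS3, 0.4))
    for nid, p in recon.node_probs.items():
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((p >= 0) & (p <= 1))


def test_known_tip_marginal_is_indicator(rng):
    tree = random_tree(rng, 8, depth_scale=1.0)
    vecs = random_tip_vectors(rng, tree, 3, p_ambiguous=0.0)
    recon = cv.marginal_asr_rerooting(tree, vecs, cv.MkModel(LABELS3, 0.3))
    for tip in tree.tips():
        np.testing.assert_allclose(recon.prob(tip.id), vecs[tip.label], atol=1e-12)


def test_single_known_tip_rest_ambiguous(rng):
    tree = random_tree(rng, 6, depth_scale=1.0)
    vecs = {lab: np.ones(3) for lab in tree.tip_labels()}
    vecs[tree.tip_labels()[0]] = np.array([0.0, 1.0, 0.0])
    recon = cv.marginal_asr_rerooting(tree, vecs, cv.MkModel(LABELS3, 0.2))
    for p in recon.node_probs.values():
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p >= 0)


def test_state_label_permutation_equivariance(rng):
    tree = random_tree(rng, 10, depth_scale=1.5)
    base_states = {lab: int(i % 3) for i, lab in enumerate(tree.tip_labels())}
    for perm in itertools.permutations(range(3)):
        labels = tuple(LABELS3[j] for j in perm)
        vecs = {}
        for lab, s in base_states.items():
            v = np.zeros(3)
            v[labels.index(LABELS3[s])] = 1.0
            vecs[lab] = v
        recon = cv.marginal_asr_rerooting(tree, vecs, cv.MkModel(labels, 0.5))
        if perm == (0, 1, 2):
            ref = {nid: p.copy() for nid, p in recon.node_probs.items()}
            ref_labels = labels
        else:
            for nid, p in recon.node_probs.items():
                for j, lab in enumerate(labels):
                    assert p[j] == pytest.approx(
                        ref[nid][ref_labels.index(lab)], abs=1e-10
                    )


def test_nonreversible_prior_refused(rng):
    tree = random_tree(rng, 5)
    vecs = random_tip_vectors(rng, tree, 3, p_ambiguous=0.0)
    model = cv.MkModel(LABELS3, 0.5, root_prior=(0.6, 0.3, 0.1))
    with pytest.raises(ValidationError, match="reversible"):
        cv.marginal_asr_rerooting(tree, vecs, model)
    with pytest.raises(ValidationError, match="reversible"):
        cv.marginal_asr_direct(tree, vecs, model)


def test_summarize_asr_report():
    recon = cv.AncestralReconstruction(
        node_probs={
            0: np.array([0.83, 0.10, 0.07]),
            1: np.array([1 / 3, 1 / 3, 1 / 3]),
        },
        q_used=0.1,
        state_labels=LABELS3,
    )
    df = cv.summarize_asr(recon, threshold=0.8)
    row0 = df[df.node_id == 0].iloc[0]
    assert row0["modal"] == "dicot"
    assert row0["prob"] == pytest.approx(0.83)
    assert bool(row0["supported"]) and not bool(row0["tie"])
    row1 = df[df.node_id == 1].iloc[0]
    assert bool(row1["tie"]) and row1["modal"] == "dicot"  # tie broken by order
    df_hi = cv.summarize_asr(recon, threshold=1.01)
    assert not df_hi["supported"].any()


def test_root_state_recovery_rate():
    """With kq*depth <= 1 the true root state is usually the modal one."""
    rng = np.random.default_rng(5150)
    hits = 0
    n_rep = 40
    for _ in range(n_rep):
        tree = cv.simulate_bd_tree(50, 1.0, 0.0, rng, scale_root_age=1.0)
        model = cv.MkModel(LABELS3, 0.25)  # kq*depth = 0.75
        scen = cv.simulate_mk_history(tree, model, rng)
        vecs = {
            lab: np.eye(3)[LABELS3.index(s)] for lab, s in scen.tip_states.items()
        }
        recon = cv.marginal_asr_rerooting(tree, vecs, model)
        modal = LABELS3[int(np.argmax(recon.prob(tree.root.id)))]
        hits += modal == scen.true_root_state
    assert hits / n_rep >= 0.8
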