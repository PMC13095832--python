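"""Independent reference implementations used to verify the package.

These are deliberately brute-force and share no code with the production
paths: exhaustive enumeration over internal-state assignments for the
likelihood, dense grid search for the rate fit, and forward-simulation
rejection sampling for endpoint-conditioned paths.
"""

from __future__ import annotations

import itertools

import numpy as np

from cutevo.mk_model import MkModel
from cutevo.tree_io import Chronogram


def enumeration_log_likelihood(tree: Chronogram, tip_vectors, model: MkModel) -> float:
    """Likelihood by explicit summation over all internal-node states.

    L = sum over assignments s of pi_{s_root} * prod_branches P_{s_par s_child}(t)
    with tip states marginalized through their observation vectors.
    """
    k = model.k
    pi = model.pi
    internals = [n for n in tree.nodes if not n.is_tip]
    tips = tree.tips()
    P = {n.id: model.transition_matrix(n.length or 0.0)
         for n in tree.nodes if n is not tree.root}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        states = {n.id: s for n, s in zip(internals, assign)}
        w = pi[states[tree.root.id]]
        for n in internals:
            if n is tree.root:
                continue
            w *= P[n.id][states[n.parent.id], states[n.id]]
        for tip in tips:
            v = np.asarray(tip_vectors[tip.label], dtype=float)
            w *= float(P[tip.id][states[tip.parent.id], :] @ v)
        total += w
    return float(np.log(total))


def grid_search_q(tree, tip_vectors, state_labels, q_lo, q_hi, n_grid=10_000):
    """Dense log-spaced grid argmax of the pruning likelihood over q."""
    from cutevo.mk_model import pruning_log_likelihood

    grid = np.exp(np.linspace(np.log(q_lo), np.log(q_hi), n_grid))
    best_q, best_ll = None, -np.inf
    for q in grid:
        ll = pruning_log_likelihood(
            tree, tip_vectors, MkModel(tuple(state_labels), q)
        ).log_likelihood
        if ll > best_ll:
            best_q, best_ll = q, ll
    return best_q, best_ll


def forward_path(state: int, t: float, model: MkModel, rng):
    """Unconditioned forward CTMC path; independent of the package's sampler."""
    k = model.k
    Q = model.Q
    segs = []
    elapsed = 0.0
    while True:
        rate = -Q[state, state]
        wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        if elapsed + wait >= t:
            segs.append((state, t - elapsed))
            return segs
        segs.append((state, wait))
        elapsed += wait
        probs = Q[state].copy()
        probs[state] = 0.0
        probs = probs / probs.sum()
        state = int(rng.choice(k, p=probs))


def rejection_branch_history(s_a, s_b, t, model, rng, max_tries=1_000_000):
    """Endpoint-conditioned path by forward simulation + rejection."""
    for _ in range(max_tries):
        segs = forward_path(s_a, t, model, rng)
        if segs[-1][0] == s_b:
            merged = []
            for s, d in segs:
                if merged and merged[-1][0] == s:
                    merged[-1] = (s, merged[-1][1] + d)
                else:
                    merged.append((s, d))
            return merged
    raise RuntimeError("rejection sampler exhausted its tries")


def n_real_transitions(segs) -> int:
    return len(segs) - 1


def random_tree(rng, n_tips: int, depth_scale: float = 1.0) -> Chronogram:
    """Random ultrametric tree via the package's birth-death simulator."""
    from cutevo.synthetic_data import simulate_bd_tree

    return simulate_bd_tree(
        n_tips, birth_rate=1.0, death_rate=0.2, rng=rng, scale_root_age=depth_scale
    )


def random_tip_vectors(rng, tree, k: int, p_ambiguous: float = 0.1):
    """Random indicator tips with an occasional all-ones ambiguous tip."""
    out = {}
    for tip in tree.tips():
        if rng.random() < p_ambiguous:
            out[tip.label] = np.ones(k)
        else:
            v = np.zeros(k)
            v[rng.integers(k)] = 1.0
            out[tip.label] = v
    return out
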