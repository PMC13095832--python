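"""Marginal ancestral-state reconstruction by the re-rooting method.

For a time-reversible Mk model whose root prior equals the stationary
distribution, the marginal posterior of the state at any node n can be read
off as the root marginal of the tree re-rooted at n.  Two implementations
ship:

* :func:`marginal_asr_rerooting` — the production path: a single postorder
  (inside) pass reusing the pruning partials, followed by a preorder
  (outside) pass, O(n) total.  For node n with inside vector D_n and outside
  vector E_n the marginal is  pi_s D_n(s) E_n(s) / sum_s' pi_s' D_n(s') E_n(s').
* :func:`marginal_asr_direct` — the verification oracle: for every node,
  literally re-root the tree there and run an independent likelihood pass
  over the re-rooted topology, O(n^2) total.  No code is shared with the
  outside pass.

Marginals are reported for internal nodes and tips alike; at a tip with a
known state the marginal is that state's indicator, while tips observed
ambiguously (social parasite, unknown) get a genuinely reconstructed
("imputed") distribution conditional on the rest of the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mk_model import MkModel, pruning_log_likelihood, _prepare_tip_vectors
from .tree_io import Chronogram


@dataclass
class AncestralReconstruction:
    """Per-node marginal state probabilities at a fixed rate."""

    node_probs: dict[int, np.ndarray]
    q_used: float
    state_labels: tuple[str, ...]

    def prob(self, node_id: int) -> np.ndarray:
        return self.node_probs[node_id]


def _require_reversible(model: MkModel) -> None:
    if not model.is_reversible():
        raise ValidationError(
            "the re-rooting method requires a time-reversible model with the "
            "root prior equal to the stationary distribution (ER + uniform "
            "prior satisfies this)"
        )


def marginal_asr_rerooting(
    tree: Chronogram, tip_vectors, model: MkModel
) -> AncestralReconstruction:
    """Marginal ASR at every node via the inside-outside two-pass algorithm."""
    _require_reversible(model)
    k = model.k
    pi = model.pi
    res = pruning_log_likelihood(tree, tip_vectors, model)
    inside = res.partials

    P_cache: dict[float, np.ndarray] = {}

    def P(t: float) -> np.ndarray:
        got = P_cache.get(t)
        if got is None:
            got = model.transition_matrix(t)
            P_cache[t] = got
        return got

    # child messages m_{n<-c}(s) = sum_s' P_{ss'}(t_c) D_c(s')
    messages: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node is tree.root:
            continue
        messages[node.id] = P(node.length or 0.0) @ inside[node.id]

    outside: dict[int, np.ndarray] = {tree.root.id: np.ones(k)}
    for node in tree.preorder():
        e_n = outside[node.id]
        for child in node.children:
            # combine the outside of n with the messages of child's siblings
            g = e_n.copy()
            for sib in node.children:
                if sib is not child:
                    g = g * messages[sib.id]
            e_c = P(child.length or 0.0).T @ (pi * g)
            # under reversibility pi_s' E_c(s') = sum_s pi_s g(s) P_{s s'}(t);
            # divide pi back out so E stays the outside conditional likelihood
            e_c = e_c / pi
            m = e_c.max()
            outside[child.id] = e_c / m if m > 0 else e_c

    node_probs: dict[int, np.ndarray] = {}
    for node in tree.nodes:
        w = pi * inside[node.id] * outside[node.id]
        total = w.sum()
        if total <= 0:
            raise ValidationError(f"zero marginal likelihood at node {node.id}")
        node_probs[node.id] = w / total
    return AncestralReconstruction(
        node_probs=node_probs, q_used=model.q, state_labels=model.state_labels
    )


def marginal_asr_direct(
    tree: Chronogram, tip_vectors, model: MkModel
) -> AncestralReconstruction:
    """Literal re-root-and-recompute marginal ASR (O(n^2) oracle).

    Builds an undirected adjacency view of the tree and, for every node,
    evaluates the conditional likelihood of the whole tree hanging from that
    node by depth-first traversal — i.e. the pruning pass of the re-rooted
    tree — then normalizes pi_s L_n(s).  Intended for trees of a few hundred
    tips at most.
    """
    _require_reversible(model)
    k = model.k
    pi = model.pi
    vecs = _prepare_tip_vectors(tree, tip_vectors, k)

    # adjacency: node id -> list of (neighbor id, branch length)
    adj: dict[int, list[tuple[int, float]]] = {n.id: [] for n in tree.nodes}
    obs: dict[int, np.ndarray] = {}
    for node in tree.nodes:
        obs[node.id] = vecs.get(node.id, np.ones(k))
        if node.parent is not None:
            t = node.length or 0.0
            adj[node.id].append((node.parent.id, t))
            adj[node.parent.id].append((node.id, t))

    P_cache: dict[float, np.ndarray] = {}

    def P(t: float) -> np.ndarray:
        got = P_cache.get(t)
        if got is None:
            got = model.transition_matrix(t)
            P_cache[t] = got
        return got

    def subtree_lik(node_id: int, came_from: int | None) -> np.ndarray:
        """Scaled conditional likelihood of everything beyond node_id."""
        d = obs[node_id].copy()
        for nbr, t in adj[node_id]:
            if nbr == came_from:
                continue
            d = d * (P(t) @ subtree_lik(nbr, node_id))
        m = d.max()
        return d / m if m > 0 else d

    node_probs: dict[int, np.ndarray] = {}
    for node in tree.nodes:
        w = pi * subtree_lik(node.id, None)
        total = w.sum()
        if total <= 0:
            raise ValidationError(f"zero marginal likelihood at node {node.id}")
        node_probs[node.id] = w / total
    return AncestralReconstruction(
        node_probs=node_probs, q_used=model.q, state_labels=model.state_labels
    )


def summarize_asr(
    recon: AncestralReconstruction,
    threshold: float = 0.8,
    tree: Chronogram | None = None,
    ages: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Per-node modal-state report.

    Columns: node_id, (age if available), P_<state>..., modal, prob,
    supported (prob >= threshold), tie (exact argmax tie, broken by
    state-label order).
    """
    rows = []
    labels = recon.state_labels
    tips = {n.id for n in tree.tips()} if tree is not None else set()
    for node_id in sorted(recon.node_probs):
        p = recon.node_probs[node_id]
        best = int(np.argmax(p))  # argmax takes the first index on ties
        tie = bool(np.sum(p == p[best]) > 1)
        row: dict = {"node_id": node_id}
        if ages is not None:
            row["age"] = ages.get(node_id)
        for i, lab in enumerate(labels):
            row[f"P_{lab}"] = p[i]
        row["modal"] = labels[best]
        row["prob"] = p[best]
        row["supported"] = bool(p[best] >= threshold)
        row["tie"] = tie
        if tree is not None:
            row["is_tip"] = node_id in tips
        rows.append(row)
    return pd.DataFrame(rows)
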