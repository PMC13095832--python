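"""Stochastic character mapping: conditioned CTMC histories on the tree.

A stochastic map is one complete realization of the trait's history
consistent with the observed tip states under the fitted Mk model.  It is
sampled in two stages:

1. **Joint node states** — the root state is drawn proportional to
   pi_s D_root(s) (D = pruning partials), then each child's state is drawn
   preorder proportional to P_{parent,s}(t) D_child(s).  Tips with known
   states receive them with probability one.
2. **Endpoint-conditioned branch paths** — on every branch the piecewise-
   constant state path between the sampled endpoint states is drawn by
   uniformization: a dominating Poisson process at rate Lambda = max|Q_ii|
   proposes candidate jump epochs, the number of candidate jumps is drawn
   from the endpoint-conditioned mixture, and jump states follow the
   uniformized chain R = I + Q/Lambda bridged between the endpoints.
   Virtual (self) jumps are invisible: consecutive equal-state segments are
   merged.  Uniformization has bounded cost even when the endpoint pair is
   improbable, unlike rejection sampling.

Reproducibility: ``stochastic_map`` takes a single root seed; history i uses
the i-th spawn of ``numpy.random.SeedSequence(seed)``, so results are
independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np

from .errors import ValidationError
from .mk_model import MkModel, pruning_log_likelihood
from .tree_io import Chronogram


@dataclass
class CharacterHistory:
    """One sampled trait history on a tree.

    ``branch_segments`` maps child-node id -> ordered ``(state_index,
    duration)`` segments running from the parent end to the child end;
    ``node_states`` maps node id -> state index.
    """

    state_labels: tuple[str, ...]
    node_states: dict[int, int]
    branch_segments: dict[int, list[tuple[int, float]]]
    seed: int | None = None

    def n_transitions(self) -> int:
        return sum(len(segs) - 1 for segs in self.branch_segments.values())

    def validate(self, tree: Chronogram, tol: float = 1e-9) -> None:
        """Check segment sums and endpoint consistency against a tree."""
        for node in tree.nodes:
            if node is tree.root:
                continue
            segs = self.branch_segments.get(node.id)
            if not segs:
                raise ValidationError(f"no segments for branch {node.id}")
            total = sum(d for _, d in segs)
            blen = node.length or 0.0
            if abs(total - blen) > tol * max(1.0, blen):
                raise ValidationError(
                    f"branch {node.id}: segments sum to {total!r}, length {blen!r}"
                )
            if segs[0][0] != self.node_states[node.parent.id]:
                raise ValidationError(f"branch {node.id}: start state mismatch")
            if segs[-1][0] != self.node_states[node.id]:
                raise ValidationError(f"branch {node.id}: end state mismatch")


@dataclass
class MapSummary:
    """Transition counts and dwell times of one history."""

    state_labels: tuple[str, ...]
    transition_counts: np.ndarray  # k x k, zero diagonal
    dwell_times: np.ndarray  # length k

    @property
    def transitions_into(self) -> np.ndarray:
        return self.transition_counts.sum(axis=0)

    @property
    def total_dwell_time(self) -> float:
        return float(self.dwell_times.sum())

    @property
    def n_transitions(self) -> int:
        return int(self.transition_counts.sum())


def sample_joint_node_states(
    tree: Chronogram,
    tip_vectors,
    model: MkModel,
    rng: np.random.Generator,
    partials: dict[int, np.ndarray] | None = None,
) -> dict[int, int]:
    """Draw one joint assignment of states to all nodes given the tips."""
    if not isinstance(rng, np.random.Generator):
        raise ValidationError(
            "pass a seeded numpy Generator (e.g. np.random.default_rng(seed))"
        )
    if partials is None:
        partials = pruning_log_likelihood(tree, tip_vectors, model).partials
    pi = model.pi
    P_cache: dict[float, np.ndarray] = {}

    def P(t: float) -> np.ndarray:
        got = P_cache.get(t)
        if got is None:
            got = model.transition_matrix(t)
            P_cache[t] = got
        return got

    states: dict[int, int] = {}
    w = pi * partials[tree.root.id]
    states[tree.root.id] = int(rng.choice(model.k, p=w / w.sum()))
    for node in tree.preorder():
        s_parent = states[node.id]
        for child in node.children:
            w = P(child.length or 0.0)[s_parent] * partials[child.id]
            states[child.id] = int(rng.choice(model.k, p=w / w.sum()))
    return states


_MAX_JUMPS = 10_000


def sample_branch_history(
    s_a: int,
    s_b: int,
    t: float,
    model: MkModel,
    rng: np.random.Generator,
) -> list[tuple[int, float]]:
    """Endpoint-conditioned CTMC path on [0, t] from s_a to s_b.

    Returns merged ``(state, duration)`` segments.  Uses uniformization with
    dominating rate Lambda = max_i |Q_ii| = (k-1) q for the ER model.
    """
    if t < 0:
        raise ValidationError(f"negative branch duration {t}")
    if t == 0:
        if s_a != s_b:
            raise ValidationError("zero-length branch cannot change state")
        return [(s_a, 0.0)]
    k = model.k
    Q = model.Q
    lam = float(np.max(-np.diag(Q)))
    R = np.eye(k) + Q / lam
    p_ab = model.transition_matrix(t)[s_a, s_b]
    if p_ab <= 0:
        raise ValidationError("endpoint pair has zero transition probability")

    # number of candidate jumps n ~ Poisson(lam t) weighted by R^n[a,b]/p_ab
    log_pois0 = -lam * t
    u = rng.random()
    acc = 0.0
    R_pows = [np.eye(k)]
    n = 0
    while True:
        r_ab = R_pows[n][s_a, s_b]
        if r_ab > 0:
            log_w = log_pois0 + n * log(lam * t) - lgamma(n + 1) + log(r_ab)
            acc += np.exp(log_w) / p_ab
            if u <= acc:
                break
        n += 1
        if n > _MAX_JUMPS:  # numerically exhausted tail; take current n
            break
        R_pows.append(R_pows[-1] @ R)

    if n == 0:
        return [(s_a, t)]
    # bridge the uniformized chain through n jumps
    states = [s_a]
    for i in range(1, n):
        w = R[states[-1], :] * R_pows[n - i][:, s_b]
        states.append(int(rng.choice(k, p=w / w.sum())))
    states.append(s_b)
    times = np.sort(rng.random(n)) * t
    # build segments, merging virtual (self) jumps
    bounds = np.concatenate(([0.0], times, [t]))
    segments: list[tuple[int, float]] = []
    for s, t0, t1 in zip(states, bounds[:-1], bounds[1:]):
        if segments and segments[-1][0] == s:
            segments[-1] = (s, segments[-1][1] + (t1 - t0))
        else:
            segments.append((s, t1 - t0))
    return segments


def sample_history(
    tree: Chronogram,
    tip_vectors,
    model: MkModel,
    rng: np.random.Generator,
    partials: dict[int, np.ndarray] | None = None,
) -> CharacterHistory:
    """One full stochastic map: joint node states + branch paths."""
    node_states = sample_joint_node_states(tree, tip_vectors, model, rng, partials)
    branch_segments: dict[int, list[tuple[int, float]]] = {}
    for node in tree.preorder():
        for child in node.children:
            branch_segments[child.id] = sample_branch_history(
                node_states[node.id],
                node_states[child.id],
                child.length or 0.0,
                model,
                rng,
            )
    return CharacterHistory(
        state_labels=model.state_labels,
        node_states=node_states,
        branch_segments=branch_segments,
    )


def stochastic_map(
    tree: Chronogram,
    tip_vectors,
    model: MkModel,
    nsim: int,
    seed: int,
) -> list[CharacterHistory]:
    """Sample ``nsim`` independent stochastic maps.

    History i uses substream i of ``SeedSequence(seed)``, so the result is
    reproducible from ``(seed, inputs)`` and independent of evaluation order.
    """
    if nsim < 1:
        raise ValidationError(f"nsim must be >= 1, got {nsim}")
    if seed is None:
        raise ValidationError("a seed is required for reproducible mapping")
    partials = pruning_log_likelihood(tree, tip_vectors, model).partials
    histories = []
    for i, child_seq in enumerate(np.random.SeedSequence(seed).spawn(nsim)):
        rng = np.random.default_rng(child_seq)
        h = sample_history(tree, tip_vectors, model, rng, partials)
        h.seed = seed
        histories.append(h)
    return histories


def relabel_history(
    history: CharacterHistory, state_labels: tuple[str, ...]
) -> CharacterHistory:
    """Re-index a history onto a common state-label ordering.

    Needed when histories parsed from separate SIMMAP strings collected
    their labels in different first-seen orders.
    """
    missing = set(history.state_labels) - set(state_labels)
    if missing:
        raise ValidationError(f"history uses labels not in target: {sorted(missing)}")
    remap = {i: state_labels.index(s) for i, s in enumerate(history.state_labels)}
    return CharacterHistory(
        state_labels=tuple(state_labels),
        node_states={nid: remap[s] for nid, s in history.node_states.items()},
        branch_segments={
            nid: [(remap[s], d) for s, d in segs]
            for nid, segs in history.branch_segments.items()
        },
        seed=history.seed,
    )


def summarize_map(history: CharacterHistory) -> MapSummary:
    """Transition-count matrix and per-state dwell times of one history."""
    k = len(history.state_labels)
    counts = np.zeros((k, k))
    dwell = np.zeros(k)
    for segs in history.branch_segments.values():
        prev = None
        for s, d in segs:
            dwell[s] += d
            if prev is not None and prev != s:
                counts[prev, s] += 1
            prev = s
    return MapSummary(
        state_labels=history.state_labels, transition_counts=counts, dwell_times=dwell
    )
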