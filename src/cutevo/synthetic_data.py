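"""Synthetic chronograms and trait histories with known ground truth.

The study's dated phylogeny comes from a Bayesian divergence-time analysis
whose posterior tree is not part of this package's inputs; every analysis
stage is therefore exercised on simulated stand-ins that share the
statistical structure the method assumes:

* :func:`simulate_bd_tree` — forward birth-death simulation from a crown
  pair, with extinct lineages pruned, conditioned on a fixed number of
  extant tips, optionally rescaled to a target root age.  Output is always
  ultrametric.
* :func:`simulate_mk_history` — forward CTMC simulation of the trait down
  every branch, recording the complete true history and the tip states.
* :func:`study_scenario` — the frozen test scenario emulating the empirical
  regime: 34 tips, root age 16.72 time units (Ma), three cutting states
  with tip frequencies close to the compiled table's included species
  (21 dicot : 9 grass : 3 dicot-grass among 33 classifiable tips), plus one
  tip masked as an ambiguous social-parasite analog.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .mk_model import MkModel
from .stochastic_mapping import CharacterHistory
from .tree_io import Chronogram, Node, write_newick

#: Frozen defaults of the study scenario (tips, root age in Ma, ER rate per Ma).
STUDY_N_TIPS = 34
STUDY_ROOT_AGE = 16.72
STUDY_Q = 0.03
STUDY_SEED = 20260407
STUDY_STATE_LABELS = ("dicot", "grass", "dicot_grass")
#: Included-species composition the scenario emulates (33 classifiable tips).
STUDY_TARGET_COUNTS = {"dicot": 21, "grass": 9, "dicot_grass": 3}
STUDY_GENUS = "Simulatta"


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class SyntheticScenario:
    """A simulated tree + trait history with full ground truth."""

    tree: Chronogram
    true_history: CharacterHistory
    tip_states: dict[str, str]  # true tip-end states
    true_q: float
    true_root_state: str
    seed: int | None = None
    observed_states: dict[str, str] | None = None  # with parasite masking
    parasite_tip: str | None = None

    @property
    def state_labels(self) -> tuple[str, ...]:
        return self.true_history.state_labels


def simulate_bd_forward(
    birth_rate: float,
    death_rate: float,
    t_stop: float,
    rng,
    start: int = 1,
) -> int:
    """Number of extant lineages at ``t_stop`` of a forward birth-death run.

    Starts from ``start`` lineages; may return 0 (clade extinction).  Used
    for distributional checks (e.g. Yule growth E[N(t)] = e^{lambda t}).
    """
    rng = _as_rng(rng)
    n = start
    t = 0.0
    while n > 0:
        rate = n * (birth_rate + death_rate)
        t += rng.exponential(1.0 / rate)
        if t >= t_stop:
            break
        if rng.random() < birth_rate / (birth_rate + death_rate):
            n += 1
        else:
            n -= 1
    return n


class _Lineage:
    __slots__ = ("parent", "birth_time", "end_time", "children", "alive")

    def __init__(self, parent, birth_time):
        self.parent = parent
        self.birth_time = birth_time
        self.end_time = None
        self.children = []
        self.alive = True


def simulate_bd_tree(
    n_tips: int,
    birth_rate: float,
    death_rate: float = 0.0,
    rng=None,
    scale_root_age: float | None = None,
    max_retries: int = 1000,
) -> Chronogram:
    """Simulate an ultrametric extant-only birth-death tree with ``n_tips``.

    Forward simulation from a crown pair; the run stops shortly after the
    moment the extant count first reaches ``n_tips`` (uniformly within the
    waiting time to the next event, so no zero-length terminal branches),
    and all extinct lineages are pruned.  Runs in which the clade dies or
    fewer than two extant tips remain are resimulated up to ``max_retries``.
    """
    if n_tips < 2:
        raise ValidationError(f"n_tips must be >= 2, got {n_tips}")
    if not (birth_rate > death_rate >= 0):
        raise ValidationError(
            f"need birth_rate > death_rate >= 0, got {birth_rate}, {death_rate}"
        )
    rng = _as_rng(rng)
    for _ in range(max_retries):
        tree = _simulate_bd_once(n_tips, birth_rate, death_rate, rng)
        if tree is not None:
            if scale_root_age is not None:
                _rescale(tree, scale_root_age)
            return tree
    raise ValidationError(
        f"birth-death simulation failed to reach {n_tips} extant tips in "
        f"{max_retries} attempts"
    )


def _simulate_bd_once(n_tips, birth_rate, death_rate, rng) -> Chronogram | None:
    root = _Lineage(None, 0.0)
    left, right = _Lineage(root, 0.0), _Lineage(root, 0.0)
    root.children = [left, right]
    root.alive = False
    root.end_time = 0.0
    active = [left, right]
    t = 0.0
    total_rate = birth_rate + death_rate
    while len(active) < n_tips:
        if not active:
            return None
        t += rng.exponential(1.0 / (len(active) * total_rate))
        lin = active[rng.integers(len(active))]
        if rng.random() < birth_rate / total_rate:
            lin.alive = False
            lin.end_time = t
            kids = [_Lineage(lin, t), _Lineage(lin, t)]
            lin.children = kids
            active.remove(lin)
            active.extend(kids)
        else:
            lin.alive = False
            lin.end_time = t
            active.remove(lin)
    # stop strictly inside the waiting time to the next event
    delta = rng.exponential(1.0 / (len(active) * total_rate))
    t_stop = t + rng.random() * delta
    for lin in active:
        lin.end_time = t_stop

    def build(lin: _Lineage) -> Node | None:
        if not lin.children:
            if not lin.alive:
                return None
            node = Node(length=lin.end_time - lin.birth_time)
            return node
        kids = [build(c) for c in lin.children]
        kids = [kid for kid in kids if kid is not None]
        if not kids:
            return None
        if len(kids) == 1:  # suppress dead-sibling unifurcation
            kid = kids[0]
            kid.length += lin.end_time - lin.birth_time
            return kid
        node = Node(length=lin.end_time - lin.birth_time)
        for kid in kids:
            node.add_child(kid)
        return node

    root_node = build(root)
    if root_node is None or root_node.is_tip:
        return None
    root_node.length = None
    tree = Chronogram(root_node)
    if tree.n_tips < 2:
        return None
    for i, tip in enumerate(tree.tips(), start=1):
        tip.label = f"t{i:03d}"
    return tree


def _rescale(tree: Chronogram, root_age: float) -> None:
    current = tree.root_age
    if current <= 0:
        raise ValidationError("cannot rescale a zero-height tree")
    factor = root_age / current
    for node in tree.nodes:
        if node.length is not None:
            node.length *= factor


def forward_branch_path(
    state: int, t: float, model: MkModel, rng
) -> list[tuple[int, float]]:
    """Unconditioned forward CTMC path on [0, t] from ``state``.

    Under ER the holding rate is (k-1)q in every state and the jump target
    is uniform over the other states.
    """
    rng = _as_rng(rng)
    k = model.k
    rate = (k - 1) * model.q
    segments: list[tuple[int, float]] = []
    elapsed = 0.0
    while True:
        wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        if elapsed + wait >= t:
            segments.append((state, t - elapsed))
            return segments
        segments.append((state, wait))
        elapsed += wait
        nxt = rng.integers(k - 1)
        state = nxt if nxt < state else nxt + 1


def simulate_mk_history(
    tree: Chronogram,
    model: MkModel,
    rng,
    root_state: str | None = None,
    seed: int | None = None,
) -> SyntheticScenario:
    """Forward-simulate the trait down every branch of a tree."""
    rng = _as_rng(rng)
    labels = model.state_labels
    if root_state is None:
        root_idx = int(rng.choice(model.k, p=model.pi))
    else:
        root_idx = labels.index(root_state)
    node_states: dict[int, int] = {tree.root.id: root_idx}
    branch_segments: dict[int, list[tuple[int, float]]] = {}
    for node in tree.preorder():
        s = node_states[node.id]
        for child in node.children:
            segs = forward_branch_path(s, child.length or 0.0, model, rng)
            branch_segments[child.id] = segs
            node_states[child.id] = segs[-1][0]
    history = CharacterHistory(
        state_labels=labels, node_states=node_states, branch_segments=branch_segments
    )
    tip_states = {tip.label: labels[node_states[tip.id]] for tip in tree.tips()}
    return SyntheticScenario(
        tree=tree,
        true_history=history,
        tip_states=tip_states,
        true_q=model.q,
        true_root_state=labels[root_idx],
        seed=seed,
    )


def study_scenario(seed: int = STUDY_SEED) -> SyntheticScenario:
    """The frozen study-scale scenario (34 tips, root age 16.72, 3 states).

    The trait simulation is retried on successive RNG substreams until the
    realized tip-state counts fall within +-30% of the empirical included-
    species composition, so the scenario's data regime matches the study's
    regardless of the seed.  One dicot tip is then masked as an ambiguous
    social-parasite analog (``observed_states``); the true states are kept
    in ``tip_states``.
    """
    seq = np.random.SeedSequence(seed)
    tree_seq, *trait_seqs = seq.spawn(1 + 512)
    tree = simulate_bd_tree(
        STUDY_N_TIPS,
        birth_rate=0.25,
        death_rate=0.05,
        rng=np.random.default_rng(tree_seq),
        scale_root_age=STUDY_ROOT_AGE,
    )
    for i, tip in enumerate(tree.tips(), start=1):
        tip.label = f"{STUDY_GENUS}_sp{i:02d}"
    model = MkModel(STUDY_STATE_LABELS, STUDY_Q)
    target_total = sum(STUDY_TARGET_COUNTS.values())  # 33 classifiable tips
    scenario = None
    for trait_seq in trait_seqs:
        cand = simulate_mk_history(
            tree, model, np.random.default_rng(trait_seq), root_state="dicot", seed=seed
        )
        counts = {s: 0 for s in STUDY_STATE_LABELS}
        for s in cand.tip_states.values():
            counts[s] += 1
        scale = (STUDY_N_TIPS - 1) / target_total  # one tip becomes the parasite
        ok = all(
            0.7 * target * scale <= counts[s] <= 1.3 * target * scale + 1
            for s, target in STUDY_TARGET_COUNTS.items()
        )
        if ok:
            scenario = cand
            break
    if scenario is None:  # pragma: no cover - would need a pathological seed
        raise ValidationError("no trait simulation matched the study composition")
    # mask the first dicot tip (tip-label order) as the parasite analog
    parasite = next(
        lab for lab in sorted(scenario.tip_states) if scenario.tip_states[lab] == "dicot"
    )
    observed = dict(scenario.tip_states)
    observed[parasite] = "parasite"
    scenario.observed_states = observed
    scenario.parasite_tip = parasite
    return scenario


def scenario_tip_vectors(scenario: SyntheticScenario) -> dict[str, np.ndarray]:
    """Tip likelihood vectors from a scenario's observed states."""
    labels = scenario.state_labels
    index = {s: i for i, s in enumerate(labels)}
    observed = scenario.observed_states or scenario.tip_states
    out: dict[str, np.ndarray] = {}
    for tip, s in observed.items():
        if s in index:
            v = np.zeros(len(labels))
            v[index[s]] = 1.0
        else:  # parasite/unknown: ambiguous
            v = np.ones(len(labels))
        out[tip] = v
    return out


def write_scenario(scenario: SyntheticScenario, outdir) -> dict[str, Path]:
    """Write tree.nwk, traits.csv and truth.json for a scenario."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(write_newick(scenario.tree) + "\n")
    traits_path = outdir / "traits.csv"
    observed = scenario.observed_states or scenario.tip_states
    raw_map = {"dicot": "Dicot", "grass": "Grass", "dicot_grass": "Dicot-Grass",
               "parasite": "Parasite", "unknown": "?"}
    lines = ["genus,species,cutting_preference,in_phylogeny,refs"]
    for tip in sorted(observed):
        genus, _, species = tip.partition("_")
        lines.append(f"{genus},{species},{raw_map[observed[tip]]},Included,")
    traits_path.write_text("\n".join(lines) + "\n")
    truth_path = outdir / "truth.json"
    truth = {
        "true_q": scenario.true_q,
        "true_root_state": scenario.true_root_state,
        "seed": scenario.seed,
        "parasite_tip": scenario.parasite_tip,
        "tip_states": scenario.tip_states,
        "n_transitions": scenario.true_history.n_transitions(),
    }
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {"tree": tree_path, "traits": traits_path, "truth": truth_path}
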