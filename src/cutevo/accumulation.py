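"""Trait accumulation through time from stochastic character maps.

For each sampled history the absolute timings of transitions *into* each
state are extracted, binned on a uniform grid of forward-time points
spanning root (t_f = 0) to present (t_f = root age), and the cumulative
counts averaged across simulations.  The study protocol uses 100 maps and a
200-point grid; the resulting curves show when in the clade's history each
cutting strategy accumulated.

The statistic is "mean cumulative number of transitions into state s by
time t".  A closely related quantity — the number of live branches sitting
in state s at time t — is provided separately as
:func:`standing_lineage_curves`; it counts lineages, not events, and is not
the accumulation statistic.

Binning convention: events falling exactly on a grid point count at that
point (closed on the left of each grid interval).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stochastic_mapping import CharacterHistory, summarize_map
from .tree_io import Chronogram, node_ages

DEFAULT_GRID_SIZE = 200


@dataclass(frozen=True)
class TransitionEvent:
    """A single state change on a branch, timed in forward time from root."""

    branch_id: int
    time_forward: float
    from_state: str
    to_state: str


@dataclass
class AccumulationCurve:
    """Mean cumulative transitions-into-state on a uniform forward-time grid."""

    grid: np.ndarray  # forward time, increasing, grid[0]=0, grid[-1]=root_age
    mean_curves: dict[str, np.ndarray]
    nsim: int
    root_age: float
    per_sim: dict[str, np.ndarray] | None = None  # state -> (nsim, grid) matrix

    @property
    def grid_size(self) -> int:
        return len(self.grid)

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(self.mean_curves)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_forward": self.grid, "age": self.root_age - self.grid})
        for s, v in self.mean_curves.items():
            df[s] = v
        return df


def _branch_start_forward(tree: Chronogram) -> dict[int, float]:
    ages = node_ages(tree)
    root_age = ages[tree.root.id]
    return {
        node.id: root_age - ages[node.parent.id]
        for node in tree.nodes
        if node is not tree.root
    }


def extract_transitions(
    history: CharacterHistory, tree: Chronogram
) -> list[TransitionEvent]:
    """All state-change events of a history, sorted by forward time."""
    history.validate(tree)
    starts = _branch_start_forward(tree)
    labels = history.state_labels
    events: list[TransitionEvent] = []
    for branch_id, segs in history.branch_segments.items():
        t = starts[branch_id]
        for (s_prev, dur), (s_next, _) in zip(segs[:-1], segs[1:]):
            t += dur
            events.append(
                TransitionEvent(
                    branch_id=branch_id,
                    time_forward=t,
                    from_state=labels[s_prev],
                    to_state=labels[s_next],
                )
            )
    events.sort(key=lambda e: e.time_forward)
    return events


def _check_histories(histories, tree: Chronogram) -> tuple[str, ...]:
    if not histories:
        raise ValidationError("need at least one history")
    labels = histories[0].state_labels
    for h in histories:
        if h.state_labels != labels:
            raise ValidationError("histories carry different state labels")
        h.validate(tree)  # also rejects histories from a different tree
    return labels


def accumulation_curves(
    histories: list[CharacterHistory],
    tree: Chronogram,
    grid_size: int = DEFAULT_GRID_SIZE,
    keep_per_sim: bool = False,
) -> AccumulationCurve:
    """Mean cumulative transitions-into-state across histories.

    For each history and state, the count of transition events into that
    state with forward time <= grid point (inclusive); the curve is the mean
    of these step functions across histories.
    """
    if grid_size < 2:
        raise ValidationError(f"grid_size must be >= 2, got {grid_size}")
    labels = _check_histories(histories, tree)
    root_age = tree.root_age
    grid = np.linspace(0.0, root_age, grid_size)
    nsim = len(histories)
    per_sim = {s: np.zeros((nsim, grid_size)) for s in labels}
    for i, h in enumerate(histories):
        events = extract_transitions(h, tree)
        times: dict[str, list[float]] = {s: [] for s in labels}
        for e in events:
            times[e.to_state].append(e.time_forward)
        for s in labels:
            ts = np.asarray(times[s])
            per_sim[s][i] = np.searchsorted(ts, grid, side="right")
    mean_curves = {s: per_sim[s].mean(axis=0) for s in labels}
    return AccumulationCurve(
        grid=grid,
        mean_curves=mean_curves,
        nsim=nsim,
        root_age=root_age,
        per_sim=per_sim if keep_per_sim else None,
    )


def standing_lineage_curves(
    histories: list[CharacterHistory],
    tree: Chronogram,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> AccumulationCurve:
    """Mean number of live branches in each state at each grid time.

    Secondary statistic: counts lineages possessing the trait at time t
    rather than cumulative transition events.  Not monotone in general.
    """
    if grid_size < 2:
        raise ValidationError(f"grid_size must be >= 2, got {grid_size}")
    labels = _check_histories(histories, tree)
    root_age = tree.root_age
    grid = np.linspace(0.0, root_age, grid_size)
    starts = _branch_start_forward(tree)
    nsim = len(histories)
    acc = {s: np.zeros(grid_size) for s in labels}
    for h in histories:
        for branch_id, segs in h.branch_segments.items():
            t0 = starts[branch_id]
            t = t0
            for s_idx, dur in segs:
                # branch occupies state s on [t, t+dur); closed at branch end
                lo = np.searchsorted(grid, t, side="left")
                hi = np.searchsorted(grid, t + dur, side="right")
                acc[labels[s_idx]][lo:hi] += 1.0
                t += dur
    mean_curves = {s: v / nsim for s, v in acc.items()}
    return AccumulationCurve(
        grid=grid, mean_curves=mean_curves, nsim=nsim, root_age=root_age
    )


def export_curves(curve: AccumulationCurve) -> str:
    """Render a curve as TSV text (time_forward, age, one column per state)."""
    df = curve.to_frame()
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    return buf.getvalue()


def read_curves(source) -> AccumulationCurve:
    """Read back a TSV produced by :func:`export_curves`."""
    df = pd.read_csv(source, sep="\t")
    states = [c for c in df.columns if c not in ("time_forward", "age")]
    grid = df["time_forward"].to_numpy()
    return AccumulationCurve(
        grid=grid,
        mean_curves={s: df[s].to_numpy() for s in states},
        nsim=0,
        root_age=float(grid[-1]),
    )


def plot_curves(curve: AccumulationCurve, path, colors: dict[str, str] | None = None):
    """Save a simple accumulation plot (age axis, present at the right)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for s, v in curve.mean_curves.items():
        kwargs = {"color": colors[s]} if colors and s in colors else {}
        ax.plot(curve.root_age - curve.grid, v, label=s, **kwargs)
    ax.set_xlabel("age (time before present)")
    ax.set_ylabel("mean cumulative transitions into state")
    ax.invert_xaxis()
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
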