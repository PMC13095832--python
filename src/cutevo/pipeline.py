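"""End-to-end analysis pipeline: traits -> fit -> ASR -> maps -> curves.

``run_pipeline`` drives the whole workflow from a :class:`RunConfig` and
writes five artifacts into the output directory:

* ``fit.tsv``        — fitted ER rate, log-likelihood, tips used
* ``nodes.tsv``      — per-node marginal state probabilities (ASR report)
* ``maps.nex``       — the stochastic maps, SIMMAP-annotated, NEXUS container
* ``curves.tsv``     — trait-accumulation curves on the forward-time grid
* ``curves.png``     — rendered accumulation plot
* ``manifest.json``  — inputs' checksums, seed, parameters, package version

Identical config + seed reproduces byte-identical text outputs; every stage
communicates with the next only through these files' in-memory equivalents,
and each stage failure is reported with the stage name.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .accumulation import accumulation_curves, export_curves, plot_curves
from .ancestral_states import marginal_asr_rerooting, summarize_asr
from .errors import PipelineStageError
from .mk_model import MkModel, fit_er_rate
from .stochastic_mapping import stochastic_map
from .trait_data import (
    ANALYSIS_STATES,
    DEFAULT_PARASITE_SPECIES,
    load_trait_table,
    tip_state_vectors,
)
from .tree_io import node_ages, prune_to_taxa, read_newick, write_simmap

log = logging.getLogger("cutevo")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults follow the study setup)."""

    tree: str
    traits: str
    outdir: str
    states: tuple[str, ...] = ANALYSIS_STATES
    nsim: int = 100
    grid_size: int = 200
    seed: int = 42
    asr_threshold: float = 0.8
    include_unknown: bool = False

    def __post_init__(self):
        if self.nsim < 1:
            raise ValueError("nsim must be >= 1")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if not self.states or len(set(self.states)) != len(self.states):
            raise ValueError("states must be nonempty and unique")
        self.states = tuple(self.states)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a flat key-value YAML config; kwargs override file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("=== stage %s ===", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run config: %s", asdict(config))
    log.info("seed: %d", config.seed)

    @_stage("trait_data")
    def load_traits():
        table = load_trait_table(config.traits)
        return table

    @_stage("tree")
    def load_tree():
        tree = read_newick(config.tree)
        tree.validate_ultrametric()
        return tree

    @_stage("align")
    def align(table, tree):
        usable = set(table.analysis_tip_labels(config.include_unknown))
        keep = [lab for lab in tree.tip_labels() if lab in usable]
        if len(keep) < len(tree.tip_labels()):
            tree = prune_to_taxa(tree, keep)
        vectors = tip_state_vectors(
            table, tree, include_unknown=config.include_unknown
        )
        return tree, vectors

    @_stage("fit")
    def fit(tree, vectors):
        res = fit_er_rate(tree, vectors, config.states)
        out = outdir / "fit.tsv"
        out.write_text(
            "q_hat\tlogL\tn_tips_used\n"
            f"{res.q_hat:.10g}\t{res.log_likelihood:.10g}\t{res.n_tips_used}\n"
        )
        return res

    @_stage("asr")
    def asr(tree, vectors, model):
        recon = marginal_asr_rerooting(tree, vectors, model)
        ages = node_ages(tree)
        df = summarize_asr(recon, config.asr_threshold, tree=tree, ages=ages)
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False, float_format="%.10g")
        (outdir / "nodes.tsv").write_text(buf.getvalue())
        return recon

    @_stage("simmap")
    def simmap(tree, vectors, model):
        histories = stochastic_map(tree, vectors, model, config.nsim, config.seed)
        lines = ["#NEXUS", "BEGIN TREES;"]
        for i, h in enumerate(histories, start=1):
            lines.append(f"    TREE map_{i} = {write_simmap(tree, h)}")
        lines.append("END;")
        (outdir / "maps.nex").write_text("\n".join(lines) + "\n")
        return histories

    @_stage("accumulate")
    def accumulate(histories, tree):
        curve = accumulation_curves(histories, tree, config.grid_size)
        (outdir / "curves.tsv").write_text(export_curves(curve))
        plot_curves(curve, outdir / "curves.png")
        return curve

    table = load_traits()
    tree = load_tree()
    tree, vectors = align(table, tree)
    fit_res = fit(tree, vectors)
    model = MkModel(config.states, fit_res.q_hat)
    asr(tree, vectors, model)
    histories = simmap(tree, vectors, model)
    accumulate(histories, tree)

    deterministic_outputs = ["fit.tsv", "nodes.tsv", "maps.nex", "curves.tsv"]
    manifest = {
        "package": "cutevo",
        "version": __version__,
        "config": asdict(config),
        "inputs": {
            "tree": _sha256(config.tree),
            "traits": _sha256(config.traits),
        },
        "outputs": {name: _sha256(outdir / name) for name in deterministic_outputs},
        "q_hat": fit_res.q_hat,
        "log_likelihood": fit_res.log_likelihood,
        "n_tips_used": fit_res.n_tips_used,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
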