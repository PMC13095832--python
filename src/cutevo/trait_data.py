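"""Cutting-preference trait table: ingestion, normalization, summaries.

Leaf-cutting ants (*Acromyrmex*, *Amoimyrmex*, *Atta*) are classified by the
plant substrate their colonies predominantly harvest: dicot leaves, grasses,
or a mixed dicot-grass diet.  The compiled species-level table ships with the
package as a CSV fixture; this module normalizes its free-text annotations
("Dicot", "Grass?", "Dicot?-Grass", "?") into a clean categorical state plus
an uncertainty flag, and converts species records into the per-tip state
likelihood vectors consumed by the Mk-model machinery.

Conventions
-----------
* Question-marked annotations ("Grass?") resolve to the stated state with
  ``uncertain=True``; they count toward that state in summaries.
* ``unknown`` is reserved for cells that are exactly "?" or empty: no
  preference is documented at all.
* Social parasites (by default *Acromyrmex ameliae*) get the bookkeeping
  state ``parasite``; in likelihood computations they are treated as fully
  ambiguous observations (all-ones vector) rather than as a fourth Markov
  state, which would be unestimable from a single tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

DICOT = "dicot"
GRASS = "grass"
DICOT_GRASS = "dicot_grass"
UNKNOWN = "unknown"
PARASITE = "parasite"

#: The three states that enter the Mk model.
ANALYSIS_STATES: tuple[str, ...] = (DICOT, GRASS, DICOT_GRASS)

#: All bookkeeping states a record may carry.
ALL_STATES: tuple[str, ...] = (DICOT, GRASS, DICOT_GRASS, UNKNOWN, PARASITE)

#: Species treated as social parasites (genus, species), lower-case.
DEFAULT_PARASITE_SPECIES: frozenset[tuple[str, str]] = frozenset(
    {("acromyrmex", "ameliae")}
)

BUILTIN_FIXTURE = "table1"

_REQUIRED_COLUMNS = ("genus", "species", "cutting_preference", "in_phylogeny", "refs")

# Token -> (state, uncertain).  Keys are lower-case, whitespace-stripped.
_ANNOTATION_MAP = {
    "dicot": (DICOT, False),
    "grass": (GRASS, False),
    "dicot-grass": (DICOT_GRASS, False),
    "grass-dicot": (DICOT_GRASS, False),
    "dicot?": (DICOT, True),
    "grass?": (GRASS, True),
    "dicot?-grass": (DICOT_GRASS, True),
    "dicot-grass?": (DICOT_GRASS, True),
    "?": (UNKNOWN, False),
    "": (UNKNOWN, False),
    # canonical state names map to themselves (idempotence)
    "dicot_grass": (DICOT_GRASS, False),
    "unknown": (UNKNOWN, False),
    "parasite": (PARASITE, False),
}


@dataclass(frozen=True)
class TraitRecord:
    """One species row of the cutting-preference table."""

    genus: str
    species: str
    raw_annotation: str
    state: str
    uncertain: bool
    in_phylogeny: bool
    refs: tuple[str, ...] = ()

    @property
    def tip_label(self) -> str:
        """Newick-safe ``Genus_species`` label."""
        return f"{self.genus}_{self.species}"


@dataclass
class TraitTable:
    """Ordered collection of :class:`TraitRecord` plus the analysis states."""

    records: list[TraitRecord]
    state_labels: tuple[str, ...] = ANALYSIS_STATES

    def __post_init__(self):
        if len(set(self.state_labels)) != len(self.state_labels):
            raise ValidationError("state_labels contains duplicates")
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.genus.lower(), rec.species.lower())
            if key in seen:
                raise ValidationError(
                    f"duplicate (genus, species) pair: {rec.genus} {rec.species}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def lookup(self, genus: str, species: str) -> TraitRecord | None:
        key = (genus.lower(), species.lower())
        for rec in self.records:
            if (rec.genus.lower(), rec.species.lower()) == key:
                return rec
        return None

    def lookup_tip(self, label: str) -> TraitRecord | None:
        """Match a ``Genus_species`` tip label, case-insensitively."""
        genus, _, species = label.partition("_")
        if not species:
            return None
        return self.lookup(genus, species)

    def analysis_tip_labels(self, include_unknown: bool = False) -> list[str]:
        """Tip labels of records usable in phylogenetic analysis.

        Records flagged ``in_phylogeny`` whose state is one of the analysis
        states or ``parasite`` (ambiguous tip).  ``unknown`` species are
        excluded unless ``include_unknown`` is set.
        """
        out = []
        for rec in self.records:
            if not rec.in_phylogeny:
                continue
            if rec.state == UNKNOWN and not include_unknown:
                continue
            out.append(rec.tip_label)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genus": [r.genus for r in self.records],
                "species": [r.species for r in self.records],
                "raw_annotation": [r.raw_annotation for r in self.records],
                "state": [r.state for r in self.records],
                "uncertain": [r.uncertain for r in self.records],
                "in_phylogeny": [r.in_phylogeny for r in self.records],
                "refs": [",".join(r.refs) for r in self.records],
            }
        )


def normalize_annotation(raw: str) -> tuple[str, bool]:
    """Map a verbatim table cell to ``(state, uncertain)``.

    Case-insensitive.  A trailing or embedded "?" marks the preference as not
    well documented but still resolves to the stated state; a bare "?" (or an
    empty cell) means no preference is documented at all.
    """
    token = "" if raw is None else str(raw).strip().lower()
    try:
        return _ANNOTATION_MAP[token]
    except KeyError:
        raise ValidationError(f"unrecognized cutting-preference annotation: {raw!r}")


def fixture_path() -> Path:
    """Filesystem path of the packaged trait-table CSV."""
    return Path(
        resources.files("cutevo").joinpath("data/table1_cutting_preferences.csv")
    )


def load_trait_table(
    source: str | Path = BUILTIN_FIXTURE,
    *,
    parasite_species: frozenset[tuple[str, str]] | set[tuple[str, str]]
    | None = None,
    state_labels: tuple[str, ...] = ANALYSIS_STATES,
) -> TraitTable:
    """Read a cutting-preference CSV into a normalized :class:`TraitTable`.

    Parameters
    ----------
    source
        Path to a CSV with columns ``genus, species, cutting_preference,
        in_phylogeny, refs``, or the builtin fixture name ``"table1"``.
    parasite_species
        ``(genus, species)`` pairs (lower-case) overridden to the ``parasite``
        state regardless of their annotation.  Defaults to the known social
        parasite *Acromyrmex ameliae*.
    """
    if parasite_species is None:
        parasite_species = DEFAULT_PARASITE_SPECIES
    path = fixture_path() if str(source) == BUILTIN_FIXTURE else Path(source)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"trait table {path} is missing column '{col}'")
    records: list[TraitRecord] = []
    for _, row in df.iterrows():
        genus = row["genus"].strip()
        species = row["species"].strip()
        raw = row["cutting_preference"]
        if (genus.lower(), species.lower()) in parasite_species:
            state, uncertain = PARASITE, False
        else:
            state, uncertain = normalize_annotation(raw)
        refs = tuple(tok.strip() for tok in row["refs"].split(",") if tok.strip())
        in_phy = row["in_phylogeny"].strip().lower() in {"included", "true", "yes", "1"}
        records.append(
            TraitRecord(
                genus=genus,
                species=species,
                raw_annotation=str(raw).strip(),
                state=state,
                uncertain=uncertain,
                in_phylogeny=in_phy,
                refs=refs,
            )
        )
    return TraitTable(records=records, state_labels=state_labels)


@dataclass
class StateCounts:
    """Per-state totals and a (state, genus) breakdown."""

    totals: dict[str, int]
    by_genus: dict[tuple[str, str], int]
    n_records: int
    n_in_phylogeny: int

    def total(self, state: str) -> int:
        return self.totals.get(state, 0)

    def genus_count(self, state: str, genus: str) -> int:
        return self.by_genus.get((state, genus), 0)

    def to_frame(self) -> pd.DataFrame:
        """State x genus count matrix with per-state totals."""
        genera = sorted({g for (_, g) in self.by_genus})
        rows = []
        for state in ALL_STATES:
            row = {"state": state}
            for g in genera:
                row[g] = self.genus_count(state, g)
            row["total"] = self.total(state)
            rows.append(row)
        return pd.DataFrame(rows)


def count_by_state(table: TraitTable) -> StateCounts:
    """Tally records per state and per (state, genus).

    ``unknown`` and ``parasite`` are tallied separately from the three
    analysis states; all five totals sum to the record count.
    """
    totals: dict[str, int] = {s: 0 for s in ALL_STATES}
    by_genus: dict[tuple[str, str], int] = {}
    n_in_phy = 0
    for rec in table:
        totals[rec.state] = totals.get(rec.state, 0) + 1
        key = (rec.state, rec.genus)
        by_genus[key] = by_genus.get(key, 0) + 1
        if rec.in_phylogeny:
            n_in_phy += 1
    return StateCounts(
        totals=totals,
        by_genus=by_genus,
        n_records=len(table),
        n_in_phylogeny=n_in_phy,
    )


def tip_state_vectors(
    table: TraitTable,
    tree,
    *,
    include_unknown: bool = False,
) -> dict[str, np.ndarray]:
    """Build per-tip state likelihood vectors for a tree.

    Known states become indicator vectors over ``table.state_labels``;
    ``parasite`` tips (and, with ``include_unknown``, ``unknown`` tips) become
    all-ones vectors, i.e. fully ambiguous observations.

    Raises
    ------
    ValidationError
        If a tip has no matching record (lists all unmatched tips), or if the
        tree contains an ``unknown``-state species while ``include_unknown``
        is False (such tips should be pruned first).
    """
    k = len(table.state_labels)
    index = {s: i for i, s in enumerate(table.state_labels)}
    vectors: dict[str, np.ndarray] = {}
    unmatched: list[str] = []
    excluded: list[str] = []
    for label in tree.tip_labels():
        rec = table.lookup_tip(label)
        if rec is None:
            unmatched.append(label)
            continue
        if rec.state in index:
            v = np.zeros(k)
            v[index[rec.state]] = 1.0
        elif rec.state == PARASITE:
            v = np.ones(k)
        elif rec.state == UNKNOWN:
            if not include_unknown:
                excluded.append(label)
                continue
            v = np.ones(k)
        else:
            raise ValidationError(
                f"state '{rec.state}' of tip {label} not among state_labels"
            )
        vectors[label] = v
    if unmatched:
        raise ValidationError(
            "tree tips with no matching trait record: " + ", ".join(sorted(unmatched))
        )
    if excluded:
        raise ValidationError(
            "tree contains species with unknown cutting preference: "
            + ", ".join(sorted(excluded))
            + " (prune them or pass include_unknown=True)"
        )
    return vectors
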