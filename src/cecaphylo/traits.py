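"""Species trait table: loading, validation, transforms, tree alignment.

The table carries one row per species with cecal length (cm), body mass (g),
and three categorical characters — dietary category (7 levels), flight
ability (3 levels), and superordinal clade (7 levels).  Loading adds the two
analysis columns: ``log_mass`` = log10(body mass) and ``log_cecum`` =
log10(cecal length + 0.1 cm); the small constant keeps species with
essentially absent ceca (length 0) on the log scale at exactly -1.
"""

from __future__ import annotations

import logging
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

from .trees import tip_labels

logger = logging.getLogger(__name__)

CECAL_CONSTANT_CM = 0.1

DIET_LEVELS = (
    "herbivore",
    "carnivore-aquatic-invertebrates",
    "carnivore-vertebrates",
    "granivore/frugivore",
    "insectivore",
    "nectarivore",
    "omnivore",
)
FLIGHT_LEVELS = ("strong flyer", "weak flyer", "flightless")
CLADE_LEVELS = (
    "Palaeognathae",
    "Galloanserae",
    "Strisores",
    "Columbaves",
    "Gruiformes",
    "Aequorlitornithes",
    "Inopinaves",
)
FACTOR_LEVELS = {"diet": DIET_LEVELS, "flight": FLIGHT_LEVELS,
                 "clade": CLADE_LEVELS}

RAW_COLUMNS = ("species", "cecal_length_cm", "body_mass_g",
               "diet", "flight", "clade")


class TraitValidationError(ValueError):
    """Invalid trait table; message lists every offending row."""


def _canonical_name(name: str) -> str:
    return " ".join(str(name).replace("_", " ").split())


def load_traits(source) -> pd.DataFrame:
    """Read and validate a trait table from a CSV path/buffer or DataFrame.

    Returns a copy with categorical dtypes on the factor columns and the
    derived ``log_mass`` / ``log_cecum`` columns appended; row order is
    preserved.  All validation failures are collected and reported together.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise TraitValidationError(f"missing required columns: {missing}")
    df = df.copy()
    df["species"] = df["species"].astype(str).str.strip()

    problems: list[str] = []
    dup = df["species"][df["species"].duplicated(keep=False)]
    for i, sp in dup.items():
        problems.append(f"row {i}: duplicate species {sp!r}")
    mass = pd.to_numeric(df["body_mass_g"], errors="coerce")
    ceca = pd.to_numeric(df["cecal_length_cm"], errors="coerce")
    for i in df.index[~(mass > 0)]:
        problems.append(f"row {i}: body_mass_g must be > 0 "
                        f"(got {df.at[i, 'body_mass_g']!r})")
    for i in df.index[~(ceca >= 0)]:
        problems.append(f"row {i}: cecal_length_cm must be >= 0 "
                        f"(got {df.at[i, 'cecal_length_cm']!r})")
    for col, levels in FACTOR_LEVELS.items():
        bad = ~df[col].isin(levels)
        for i in df.index[bad]:
            problems.append(f"row {i}: unknown {col} level {df.at[i, col]!r}")
    if problems:
        raise TraitValidationError("invalid trait table:\n  "
                                   + "\n  ".join(problems))

    df["body_mass_g"] = mass
    df["cecal_length_cm"] = ceca
    for col, levels in FACTOR_LEVELS.items():
        df[col] = pd.Categorical(df[col], categories=list(levels))
    df["log_mass"] = np.log10(df["body_mass_g"])
    df["log_cecum"] = np.log10(df["cecal_length_cm"] + CECAL_CONSTANT_CM)
    return df


def write_traits(traits: pd.DataFrame, path) -> None:
    """Write the raw columns back to CSV (derived columns are recomputed on load)."""
    traits.loc[:, list(RAW_COLUMNS)].to_csv(path, index=False)


def align_to_tree(traits: pd.DataFrame, tree: dendropy.Tree,
                  policy: str = "strict"):
    """Match the trait table to the tree's tips.

    Species names are compared after trimming whitespace and unifying
    underscores with spaces; no fuzzy matching.  Under ``strict`` any
    mismatch on either side is an error; under ``prune`` unmatched taxa are
    dropped from both sides (counts are logged).  The returned table rows
    follow the pruned tree's tip order, so trait vectors and covariance
    matrices line up by position.
    """
    if policy not in ("strict", "prune"):
        raise ValueError(f"unknown alignment policy {policy!r}")
    tree_labels = tip_labels(tree)
    tree_by_key = {_canonical_name(lab): lab for lab in tree_labels}
    table_by_key = {_canonical_name(sp): i
                    for i, sp in traits["species"].items()}
    shared = [k for k in (_canonical_name(l) for l in tree_labels)
              if k in table_by_key]
    if not shared:
        raise ValueError("no species shared between trait table and tree")
    only_tree = [lab for lab in tree_labels
                 if _canonical_name(lab) not in table_by_key]
    only_table = [traits.at[i, "species"] for k, i in table_by_key.items()
                  if k not in tree_by_key]
    if policy == "strict" and (only_tree or only_table):
        raise ValueError(
            f"trait table and tree do not match: {len(only_tree)} tips "
            f"without traits {only_tree[:5]}..., {len(only_table)} species "
            f"without tips {only_table[:5]}...")

    pruned = tree
    if only_tree:
        pruned = tree.clone(depth=1)
        keep = [lab for lab in tree_labels
                if _canonical_name(lab) in table_by_key]
        pruned.retain_taxa_with_labels(keep)
        logger.info("pruned %d tips without trait data", len(only_tree))
    if only_table:
        logger.info("dropped %d trait rows without tree tips", len(only_table))

    order = [table_by_key[_canonical_name(lab)] for lab in tip_labels(pruned)]
    aligned = traits.loc[order].reset_index(drop=True)
    return aligned, pruned


def trait_vector(traits: pd.DataFrame, column: str,
                 taxa: Iterable[str]) -> np.ndarray:
    """Extract ``column`` ordered by ``taxa`` (canonical-name matched)."""
    lookup = {_canonical_name(sp): v
              for sp, v in zip(traits["species"], traits[column])}
    try:
        return np.asarray([lookup[_canonical_name(t)] for t in taxa])
    except KeyError as exc:
        raise KeyError(f"taxon {exc} missing from trait table") from exc
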