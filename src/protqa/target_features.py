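"""Target-conditioning features.

Feature distributions differ systematically between targets (length,
composition, fold class), so the same raw feature value can mean very
different qualities for different targets.  Three feature families let a
tree model condition on the target:

* one-hot target identity columns ``OH_<target_id>`` over the training
  targets (an unseen target at prediction time is all zeros);
* per-target z-scores of the basic features (population standard
  deviation; a constant column within a target z-scores to 0);
* amino-acid composition of the target sequence: 20 per-residue
  frequencies plus 6 physicochemical class frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import STANDARD_AA

# Standard biochemistry class memberships.  The "special" class (glycine +
# proline, the backbone-flexibility outliers) is this package's own sixth
# class, added so the block has six members.
AA_CLASSES = {
    "positive": set("KRH"),
    "negative": set("DE"),
    "aromatic": set("FWYH"),
    "polar": set("STNQCYHKRDE"),
    "nonpolar": set("AVLIMFWPG"),
    "special": set("GP"),
}

COMPOSITION_COLUMNS = tuple(f"aa_{a}" for a in STANDARD_AA) + tuple(
    f"comp_{c}" for c in AA_CLASSES
)


@dataclass
class OneHotSchema:
    """Frozen, ordered list of training target ids defining OH columns."""

    target_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("duplicate target ids in one-hot schema")

    @property
    def columns(self) -> list:
        return [f"OH_{t}" for t in self.target_ids]

    def __len__(self) -> int:
        return len(self.target_ids)


def one_hot(target_id: str, schema: OneHotSchema) -> np.ndarray:
    """Binary indicator vector; all zeros for a target outside the schema."""
    if len(schema) == 0:
        raise ValueError("one-hot schema is empty")
    vec = np.zeros(len(schema), dtype=float)
    for i, t in enumerate(schema.target_ids):
        if t == target_id:
            vec[i] = 1.0
            break
    return vec


def one_hot_table(index: pd.MultiIndex, schema: OneHotSchema) -> pd.DataFrame:
    rows = np.vstack([one_hot(t, schema) for t in index.get_level_values(0)])
    return pd.DataFrame(rows, index=index, columns=schema.columns)


def zscore_by_target(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Per-target z-scores of the given columns, as new ``<name>_z`` columns.

    Uses the population standard deviation; within-target constant
    columns map to zero.
    """
    cols = list(columns)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    grouped = table.groupby(level=0, sort=False)[cols]
    mean = grouped.transform("mean")
    std = grouped.transform("std", ddof=0)
    z = (table[cols] - mean) / std.replace(0.0, np.nan)
    z = z.fillna(0.0)
    z.columns = [f"{c}_z" for c in cols]
    return z


def aa_composition(sequence: str) -> dict:
    """20 amino-acid frequencies plus 6 class frequencies of a sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    bad = set(sequence) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard amino acids: {sorted(bad)}")
    n = len(sequence)
    out = {f"aa_{a}": sequence.count(a) / n for a in STANDARD_AA}
    for cls, members in AA_CLASSES.items():
        out[f"comp_{cls}"] = sum(1 for a in sequence if a in members) / n
    return out
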