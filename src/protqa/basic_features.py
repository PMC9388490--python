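"""Single-model ("basic") structural features computable from coordinates.

These describe one model in isolation — compactness and packing
(carbon-carbon contact densities, radius of gyration), side-chain content
and sequence coverage.  Coverage matters because a model's GDT_TS against
the native structure can never exceed the fraction of the target it
actually models.

The schema also accepts externally computed basic-feature columns (energy
terms, secondary-structure compatibilities, ...) merged by
(target_id, model_id); see :func:`merge_external_features`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import ModelStructure

BASIC_COLUMNS = ("contacts8", "contacts14", "scCarbonN", "coverage", "rg")

#: backbone carbon atom names excluded from the side-chain count
_BACKBONE_CARBONS = {"C", "CA"}


def contacts(model: ModelStructure, threshold: float) -> float:
    """Average carbon-carbon contacts per carbon atom at a distance cutoff.

    Counts unordered pairs of carbon atoms from *different* residues
    within ``threshold`` Angstrom, divided by the number of carbon atoms.
    """
    res_idx, xyz, _ = model.carbon_atoms()
    n = len(res_idx)
    if n == 0:
        raise ValueError(f"model {model.model_id!r} has no carbon atoms")
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    cross = res_idx[pairs[:, 0]] != res_idx[pairs[:, 1]]
    return float(cross.sum()) / n


def sc_carbon_count(model: ModelStructure) -> int:
    """Number of side-chain carbon atoms (CB counts; backbone C/CA do not)."""
    _, _, names = model.carbon_atoms()
    return sum(1 for name in names if name not in _BACKBONE_CARBONS)


def coverage(model: ModelStructure, target_length: int) -> float:
    """Fraction of the target sequence with a modeled CA atom."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    pos, _ = model.ca_trace()
    return len(pos) / target_length


def radius_of_gyration(model: ModelStructure) -> float:
    """Root-mean-square CA distance from the CA centroid, in Angstrom."""
    _, xyz = model.ca_trace()
    if len(xyz) == 0:
        raise ValueError("model has no CA atoms")
    centered = xyz - xyz.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def basic_feature_row(model: ModelStructure, target_length: int) -> dict:
    return {
        "contacts8": contacts(model, 8.0),
        "contacts14": contacts(model, 14.0),
        "scCarbonN": float(sc_carbon_count(model)),
        "coverage": coverage(model, target_length),
        "rg": radius_of_gyration(model),
    }


def merge_external_features(table: pd.DataFrame, external: pd.DataFrame) -> pd.DataFrame:
    """Left-join externally computed feature columns by (target_id, model_id)."""
    overlap = set(table.columns) & set(external.columns)
    if overlap:
        raise ValueError(f"external columns already present: {sorted(overlap)}")
    return table.join(external, how="left")
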