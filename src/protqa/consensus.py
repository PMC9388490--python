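"""Consensus features: a model's average similarity to its target's pool.

The consensus premise is that independently generated models which agree
with each other are all likely to be close to the (unknown) native
structure: good models cluster, bad models scatter.  For every model d of
a target's pool T the seven consensus features are the averages over all
s in T (the self term included) of gdt_1, gdt_2, gdt_4, gdt_8, GDT_TS,
GDT_HA and RMSD:

    gdt_i_consensus(d)   = (1/|T|) sum_{s in T} gdt_i(d, s),  i in {1,2,4,8}
    gdt_ts_consensus(d)  = (1/|T|) sum_{s in T} gdt_ts(d, s)
    gdt_ha_consensus(d)  = (1/|T|) sum_{s in T} gdt_ha(d, s)
    rms_consensus(d)     = (1/|T|) sum_{s in T} RMSD(d, s)
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import TargetSet
from .superpose import ALL_THRESHOLDS, GDT_HA_THRESHOLDS, GDT_TS_THRESHOLDS, gdt

logger = logging.getLogger(__name__)

CONSENSUS_COLUMNS = (
    "gdt1_consensus",
    "gdt2_consensus",
    "gdt4_consensus",
    "gdt8_consensus",
    "gdt_ts_consensus",
    "gdt_ha_consensus",
    "rms_consensus",
)

#: RMSD recorded for pairs with fewer than 3 common residues
RMSD_SENTINEL = 999.0

_GDT_KEYS = ("gdt_1", "gdt_2", "gdt_4", "gdt_8", "gdt_ts", "gdt_ha")


@dataclass
class SimilarityMatrix:
    """All-vs-all similarity scores within one target's model pool.

    Each array is |T| x |T|, symmetric; gdt-type diagonals hold the
    coverage-limited self scores and the rmsd diagonal is zero.
    """

    model_ids: list
    gdt_1: np.ndarray
    gdt_2: np.ndarray
    gdt_4: np.ndarray
    gdt_8: np.ndarray
    gdt_ts: np.ndarray
    gdt_ha: np.ndarray
    rmsd: np.ndarray

    def array(self, key: str) -> np.ndarray:
        return getattr(self, key)

    def to_frame(self, key: str) -> pd.DataFrame:
        return pd.DataFrame(self.array(key), index=self.model_ids, columns=self.model_ids)


def pairwise_similarities(
    T: TargetSet, denominator: str = "target"
) -> SimilarityMatrix:
    """Compute the full similarity matrix of a target's model pool.

    Scores are computed once per unordered pair and mirrored (with
    positional correspondence the pair score is direction-symmetric).
    Pairs sharing fewer than 3 CA residues get worst-case entries
    (gdt 0, RMSD sentinel) and a logged warning.
    """
    n = T.n_models
    denom_len = len(T.sequence)
    mats = {k: np.zeros((n, n)) for k in _GDT_KEYS}
    rmsd = np.zeros((n, n))
    for i, d in enumerate(T.models):
        # self scores: identity superposition puts every common residue at
        # distance zero, so each fraction is the coverage-limited maximum
        n_ca = len(d.ca_trace()[0])
        denom = n_ca if denominator == "common" else denom_len
        for k in _GDT_KEYS:
            mats[k][i, i] = n_ca / denom
    for i, j in itertools.combinations(range(n), 2):
        d, s = T.models[i], T.models[j]
        try:
            res = gdt(d, s, ALL_THRESHOLDS, denom_len, denominator)
        except ValueError as exc:
            logger.warning(
                "target %s: pair (%s, %s) unscorable (%s); worst values used",
                T.target_id, d.model_id, s.model_id, exc,
            )
            rmsd[i, j] = rmsd[j, i] = RMSD_SENTINEL
            continue
        vals = {
            "gdt_1": res.fractions[1.0],
            "gdt_2": res.fractions[2.0],
            "gdt_4": res.fractions[4.0],
            "gdt_8": res.fractions[8.0],
            "gdt_ts": res.mean_over(GDT_TS_THRESHOLDS),
            "gdt_ha": res.mean_over(GDT_HA_THRESHOLDS),
        }
        for k, v in vals.items():
            mats[k][i, j] = mats[k][j, i] = v
        rmsd[i, j] = rmsd[j, i] = res.rmsd_common
    return SimilarityMatrix(
        model_ids=[m.model_id for m in T.models], rmsd=rmsd, **mats
    )


def consensus_vector(index: int, M: SimilarityMatrix) -> dict:
    """The seven consensus features of model ``index`` (self term included)."""
    out = {}
    for col, key in zip(CONSENSUS_COLUMNS[:6], _GDT_KEYS):
        out[col] = float(M.array(key)[index].mean())
    out["rms_consensus"] = float(M.rmsd[index].mean())
    return out


def consensus_table(M: SimilarityMatrix) -> pd.DataFrame:
    """Consensus features for every model of the pool, one row per model."""
    rows = [consensus_vector(i, M) for i in range(len(M.model_ids))]
    return pd.DataFrame(rows, index=M.model_ids)[list(CONSENSUS_COLUMNS)]


def per_target_median(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Per-target medians, broadcast as constant ``<name>_median`` columns.

    ``table`` must be indexed by (target_id, model_id).  An even model
    count uses the mean-of-middle-two convention.
    """
    cols = list(columns)
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"columns not in table: {missing_cols}")
    if table[cols].isna().any().any():
        raise ValueError("missing values in median source columns")
    med = table.groupby(level=0, sort=False)[cols].transform("median")
    med.columns = [f"{c}_median" for c in cols]
    return med


def write_similarity_matrix(M: SimilarityMatrix, key: str, path) -> None:
    M.to_frame(key).to_csv(path, sep="\t")


def read_similarity_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
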