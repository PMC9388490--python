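"""Assemble per-model feature vectors from target sets.

The full vector for a model concatenates, per included block:

* basic:     coordinate-derived single-model features, their per-target
             z-scores and per-target medians;
* consensus: the seven pool-average similarity features, their per-target
             z-scores and medians;
* composition: the 26 amino-acid composition features of the target
             sequence (constant across a target's models).

One-hot target identity columns are appended by the regressor at fit time
(they depend on the training-target schema, not on the structures).
When the target set carries a native structure, the observed label
(GDT_TS of each model against the native) is attached as well.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .basic_features import BASIC_COLUMNS, basic_feature_row
from .consensus import (
    CONSENSUS_COLUMNS,
    consensus_table,
    pairwise_similarities,
    per_target_median,
)
from .structures import INDEX_NAMES, LABEL_COLUMN, TargetSet, validate_feature_table
from .superpose import gdt_ts
from .target_features import aa_composition

DEFAULT_BLOCKS = ("basic", "consensus", "composition")


def feature_block(name: str) -> str:
    """Classify a feature column into its block.

    Returns one of ``basic``, ``consensus``, ``basic_zscore``,
    ``consensus_zscore``, ``basic_median``, ``consensus_median``,
    ``composition``, ``one_hot``.
    """
    if name.startswith("OH_"):
        return "one_hot"
    if name.startswith(("aa_", "comp_")):
        return "composition"
    base = name
    for suffix, kind in (("_median", "median"), ("_z", "zscore")):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    else:
        kind = "raw"
    block = "consensus" if base.endswith("_consensus") or base == "rms_consensus" else "basic"
    return block if kind == "raw" else f"{block}_{kind}"


def select_block_columns(table: pd.DataFrame, blocks: Sequence[str]) -> pd.DataFrame:
    """Column subset of a full feature table for a feature-set ablation.

    Keeps each requested model-feature block together with its per-target
    z-scores and medians, plus composition when requested, plus the label
    column if present.
    """
    keep = []
    wanted = set(blocks)
    for col in table.columns:
        if col == LABEL_COLUMN:
            keep.append(col)
            continue
        block = feature_block(col)
        root = block.split("_")[0] if block != "one_hot" else block
        if block in wanted or root in wanted:
            keep.append(col)
    if not keep or keep == [LABEL_COLUMN]:
        raise ValueError(f"no feature columns match blocks {sorted(wanted)}")
    return table[keep]


def build_target_table(
    ts: TargetSet,
    blocks: Sequence[str] = DEFAULT_BLOCKS,
    include_label: bool = True,
    denominator: str = "target",
) -> pd.DataFrame:
    """Feature table for one target set, indexed by (target_id, model_id)."""
    unknown = set(blocks) - {"basic", "consensus", "composition"}
    if unknown:
        raise ValueError(f"unknown feature blocks: {sorted(unknown)}")
    index = pd.MultiIndex.from_tuples(
        [(ts.target_id, m.model_id) for m in ts.models], names=list(INDEX_NAMES)
    )
    parts = []
    zscore_sources = []
    if "basic" in blocks:
        rows = [basic_feature_row(m, len(ts.sequence)) for m in ts.models]
        basic = pd.DataFrame(rows, index=index)[list(BASIC_COLUMNS)]
        parts.append(basic)
        zscore_sources.extend(BASIC_COLUMNS)
    if "consensus" in blocks:
        M = pairwise_similarities(ts, denominator=denominator)
        cons = consensus_table(M).set_index(index)
        parts.append(cons)
        zscore_sources.extend(CONSENSUS_COLUMNS)
    if "composition" in blocks:
        comp_row = aa_composition(ts.sequence)
        comp = pd.DataFrame([comp_row] * len(index), index=index)
        parts.append(comp)
    table = pd.concat(parts, axis=1)
    if zscore_sources:
        from .target_features import zscore_by_target

        table = pd.concat([table, zscore_by_target(table, zscore_sources)], axis=1)
        table = pd.concat([table, per_target_median(table, zscore_sources)], axis=1)
    if include_label and ts.native is not None:
        labels = [
            min(1.0, max(0.0, gdt_ts(m, ts.native, len(ts.sequence), denominator)))
            for m in ts.models
        ]
        table[LABEL_COLUMN] = labels
    return validate_feature_table(table)


class FeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping a list of :class:`TargetSet` to a feature table.

    Stateless (``fit`` records nothing); exists so featurization composes
    with sklearn pipelines and so feature-subset ablations are a
    parameter, not a code path.

    Parameters
    ----------
    blocks : sequence of {"basic", "consensus", "composition"}
        Feature blocks to include.
    include_label : bool
        Attach the observed GDT_TS label where a native structure exists.
    denominator : {"target", "common"}
        GDT fraction denominator convention.
    """

    def __init__(
        self,
        blocks: Sequence[str] = DEFAULT_BLOCKS,
        include_label: bool = True,
        denominator: str = "target",
    ):
        self.blocks = blocks
        self.include_label = include_label
        self.denominator = denominator

    def fit(self, X: Iterable[TargetSet], y=None):
        return self

    def transform(self, X: Iterable[TargetSet]) -> pd.DataFrame:
        tables = [
            build_target_table(
                ts,
                blocks=self.blocks,
                include_label=self.include_label,
                denominator=self.denominator,
            )
            for ts in X
        ]
        if not tables:
            raise ValueError("no target sets given")
        return validate_feature_table(pd.concat(tables, axis=0))
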