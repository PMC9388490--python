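"""Shared fixtures.

The expensive benchmark fixtures (a 30-target x 60-model synthetic study
and its leave-one-target-out runs) are session-scoped and shared by the
acceptance tests for parameter recovery, feature importance and the
feature-set ablation, so the pairwise-similarity work is done once.
"""

from __future__ import annotations

import numpy as np
import pytest

from protqa import (
    BoostedQARegressor,
    DecoyConfig,
    FeatureExtractor,
    leave_one_target_out,
    make_dataset,
    select_block_columns,
)

#: the package's benchmark seed (documented study condition)
STUDY_SEED = 1234


@pytest.fixture(scope="session")
def small_dataset():
    """5 targets x 12 models — cheap end-to-end fixture."""
    cfg = DecoyConfig(
        n_targets=5, models_per_target=12, sequence_length=(25, 35), seed=7
    )
    datasets, manifest = make_dataset(cfg)
    return datasets, manifest


@pytest.fixture(scope="session")
def small_table(small_dataset):
    datasets, _ = small_dataset
    return FeatureExtractor().transform(datasets)


@pytest.fixture(scope="session")
def study():
    """The desk-scale benchmark: 30 targets x 60 models, fixed seed."""
    cfg = DecoyConfig(seed=STUDY_SEED)
    datasets, manifest = make_dataset(cfg)
    table = FeatureExtractor().transform(datasets)
    return datasets, manifest, table


@pytest.fixture(scope="session")
def study_reports(study):
    """LOTO reports for the all / consensus-only / basic-only feature sets."""
    datasets, _, table = study
    reports = {}
    for name, blocks in {
        "all": ("basic", "consensus", "composition"),
        "consensus": ("consensus", "composition"),
        "basic": ("basic", "composition"),
    }.items():
        sub = select_block_columns(table, blocks)
        reports[name] = leave_one_target_out(datasets, table=sub)
    return reports


@pytest.fixture(scope="session")
def study_importance(study):
    """GAIN importance of a model fitted on the full study table."""
    _, _, table = study
    model = BoostedQARegressor().fit(table)
    return model.feature_importance()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
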