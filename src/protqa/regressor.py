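"""Gradient-boosted regression from feature vectors to predicted GDT_TS.

The estimator follows the scikit-learn contract (``fit`` / ``predict`` /
``get_params``), takes a feature table indexed by (target_id, model_id),
and internally appends one-hot target-identity columns over the training
targets.  Hyperparameters follow the values that worked well for this
problem class — learning rate 0.1, 100 estimators, squared-error (RMSE)
objective — with everything else at library defaults.  Predictions are
clipped to [0, 1], the range of the GDT_TS label.

Feature importance is reported as GAIN: the total information gain of all
tree splits that use a feature.  Linear and feed-forward baselines are
available behind the same interface via the ``backend`` parameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .structures import LABEL_COLUMN
from .featurize import feature_block  # noqa: F401  (re-exported, used by callers)
from .target_features import OneHotSchema, one_hot_table

DEFAULT_SEED = 17


@dataclass
class ImportanceReport:
    """Per-feature GAIN with rank order (rank 1 = highest gain)."""

    table: pd.DataFrame  # columns: feature, gain, rank

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(n, "rank")


class BoostedQARegressor(BaseEstimator, RegressorMixin):
    """Boosted-tree (or baseline) regressor for model accuracy estimation.

    Parameters
    ----------
    learning_rate, n_estimators : boosting hyperparameters (defaults 0.1, 100).
    backend : {"lightgbm", "linear", "mlp"}
        "lightgbm" is the method; the others are comparison baselines.
    use_one_hot : append OH_<target> identity columns over training targets.
    clip : clip predictions into [0, 1].
    random_state : seed for the underlying learner.
    """

    def __init__(
        self,
        learning_rate: float = 0.1,
        n_estimators: int = 100,
        backend: str = "lightgbm",
        use_one_hot: bool = True,
        clip: bool = True,
        random_state: int = DEFAULT_SEED,
    ):
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.backend = backend
        self.use_one_hot = use_one_hot
        self.clip = clip
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _make_learner(self):
        if self.backend == "lightgbm":
            from lightgbm import LGBMRegressor

            return LGBMRegressor(
                objective="regression",  # squared-error / RMSE loss
                learning_rate=self.learning_rate,
                n_estimators=self.n_estimators,
                random_state=self.random_state,
                n_jobs=1,
                deterministic=True,
                verbose=-1,
            )
        if self.backend == "linear":
            from sklearn.linear_model import Ridge

            return Ridge(alpha=1.0, random_state=self.random_state)
        if self.backend == "mlp":
            from sklearn.neural_network import MLPRegressor

            return MLPRegressor(
                hidden_layer_sizes=(64, 32),
                max_iter=500,
                random_state=self.random_state,
            )
        raise ValueError(f"unknown backend {self.backend!r}")

    @staticmethod
    def _split_features(X: pd.DataFrame) -> pd.DataFrame:
        if LABEL_COLUMN in X.columns:
            return X.drop(columns=[LABEL_COLUMN])
        return X

    def _design(self, X: pd.DataFrame) -> pd.DataFrame:
        """Feature matrix in the stored column order, OH columns filled."""
        feats = self._split_features(X).copy()
        if self.use_one_hot:
            oh = one_hot_table(feats.index, self.onehot_schema_)
            feats = pd.concat([feats, oh], axis=1)
        missing = [c for c in self.feature_names_ if c not in feats.columns]
        non_oh = [c for c in missing if not c.startswith("OH_")]
        if non_oh:
            raise ValueError(f"missing feature columns: {non_oh}")
        if missing:  # unseen-target OH columns are all-zero
            zeros = pd.DataFrame(0.0, index=feats.index, columns=missing)
            feats = pd.concat([feats, zeros], axis=1)
        return feats[self.feature_names_]

    # -- sklearn API -------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None, filtered_targets=()):
        """Fit on a feature table; rows of ``filtered_targets`` are dropped.

        ``y`` may be omitted when ``X`` carries the label column.
        """
        if not isinstance(X, pd.DataFrame) or X.index.nlevels != 2:
            raise ValueError("X must be a feature table indexed by (target_id, model_id)")
        if y is None:
            if LABEL_COLUMN not in X.columns:
                raise ValueError(f"no y given and no {LABEL_COLUMN!r} column in X")
            y = X[LABEL_COLUMN]
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        if (y < 0).any() or (y > 1).any():
            raise ValueError("labels must lie in [0, 1]")
        filtered = set(filtered_targets)
        keep = ~X.index.get_level_values(0).isin(filtered)
        X_train, y_train = X[keep], y[keep]
        if X_train.empty:
            raise ValueError("training set is empty after target filtering")
        train_targets = list(dict.fromkeys(X_train.index.get_level_values(0)))
        if len(train_targets) < 2:
            import warnings

            warnings.warn(
                "training on a single target: one-hot identity degenerates",
                UserWarning,
                stacklevel=2,
            )
        self.onehot_schema_ = (
            OneHotSchema(train_targets) if self.use_one_hot else OneHotSchema(["_none_"])
        )
        feats = self._split_features(X_train)
        if self.use_one_hot:
            feats = pd.concat(
                [feats, one_hot_table(feats.index, self.onehot_schema_)], axis=1
            )
        self.feature_names_ = list(feats.columns)
        self.learner_ = self._make_learner()
        self.learner_.fit(feats.astype(float), y_train.to_numpy())
        self.n_features_in_ = len(self.feature_names_)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "learner_")
        feats = self._design(X)
        pred = np.asarray(self.learner_.predict(feats.astype(float)), dtype=float)
        if self.clip:
            pred = np.clip(pred, 0.0, 1.0)
        return pred

    def predict_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Predictions as a one-column frame keyed like the input table."""
        return pd.DataFrame({"predicted_gdt_ts": self.predict(X)}, index=X.index)

    # -- importance & persistence -----------------------------------------

    def feature_importance(self) -> ImportanceReport:
        """GAIN per feature; rank 1 is the most important, ties by column order."""
        check_is_fitted(self, "learner_")
        if self.backend == "lightgbm":
            gain = self.learner_.booster_.feature_importance(importance_type="gain")
        elif hasattr(self.learner_, "coef_"):
            gain = np.abs(np.ravel(self.learner_.coef_))
        else:
            raise ValueError(f"no importance metric for backend {self.backend!r}")
        df = pd.DataFrame({"feature": self.feature_names_, "gain": gain.astype(float)})
        order = np.lexsort((np.arange(len(df)), -df["gain"].to_numpy()))
        ranks = np.empty(len(df), dtype=int)
        ranks[order] = np.arange(1, len(df) + 1)
        df["rank"] = ranks
        return ImportanceReport(df)

    def save(self, path) -> None:
        check_is_fitted(self, "learner_")
        joblib.dump(self, path)
        sidecar = str(path) + ".importance.json"
        try:
            rep = self.feature_importance()
        except ValueError:
            return
        with open(sidecar, "w") as fh:
            json.dump(rep.table.to_dict(orient="records"), fh, indent=1)

    @staticmethod
    def load(path) -> "BoostedQARegressor":
        model = joblib.load(path)
        if not isinstance(model, BoostedQARegressor):
            raise TypeError(f"{path} does not hold a BoostedQARegressor")
        return model


def train(table: pd.DataFrame, config: dict | None = None) -> BoostedQARegressor:
    """Thin functional wrapper: fit a regressor on a labeled feature table."""
    config = dict(config or {})
    filtered = config.pop("filtered_targets", ())
    model = BoostedQARegressor(**config)
    return model.fit(table, filtered_targets=filtered)


def predict(model: BoostedQARegressor, table: pd.DataFrame) -> pd.DataFrame:
    return model.predict_frame(table)
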