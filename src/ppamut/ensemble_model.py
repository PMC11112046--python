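"""Per-functional-class deep ensemble: encoder -> 12-D embedding -> forest.

The predictor has two stages.  A three-layer feed-forward network (input,
hidden ReLU layer, 12-unit output layer) is trained as a regressor on
standardized features with a temporary linear head minimising mean squared
error; the head is discarded and the 12-dimensional activation of the last
layer becomes the embedding.  A random-forest regressor fitted on the
embedding produces the final ddG (kcal/mol).  One ensemble is trained per
functional class, each with its own selected FeatureSpec.

The API follows the Model/Results idiom: :class:`AffinityModel` holds data
and configuration, ``fit()`` returns an :class:`AffinityResults` carrying
the fitted state, diagnostics, ``predict`` and ``summary``.
"""

from __future__ import annotations

import datetime
import hashlib
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .core_data import FunctionalClass
from .feature_pipeline import (DEFAULT_N_FEATURES_PER_CLASS, FeatureMatrix,
                               FeatureSpec, select_features, standardize)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1
EMBEDDING_DIM = 12

EFFECT_DECREASES = "decreases affinity"
EFFECT_INCREASES = "increases affinity"
EFFECT_NEUTRAL = "neutral"


class ModelPersistenceError(RuntimeError):
    """Artifact missing, corrupted or of an incompatible format version."""


@dataclass
class EncoderSpec:
    """Architecture and training hyperparameters of the feature encoder.

    The embedding dimension defaults to 12, the width found optimal for
    this problem; widen or shrink only deliberately.
    """

    hidden_dim: int = 64
    embedding_dim: int = EMBEDDING_DIM
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim <= 0 or self.embedding_dim <= 0:
            raise ValueError("layer widths must be positive")


@dataclass
class EncoderWeights:
    """Weights of input -> hidden (ReLU) -> embedding (ReLU); the training
    head is already discarded."""

    w_hidden: np.ndarray
    b_hidden: np.ndarray
    w_embed: np.ndarray
    b_embed: np.ndarray

    @property
    def input_dim(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def embedding_dim(self) -> int:
        return self.w_embed.shape[1]


def train_encoder(X: np.ndarray, y: np.ndarray,
                  spec: EncoderSpec | None = None,
                  seed: int | None = None) -> EncoderWeights:
    """Train the encoder as a supervised regressor and drop the head.

    Deterministic for fixed (data, spec, seed): the optimiser is seeded and
    single-threaded.  Raises on non-finite loss.
    """
    spec = spec or EncoderSpec()
    if seed is None:
        seed = spec.seed
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one target per row")
    if len(y) < 10:
        raise ValueError(f"need >= 10 training rows, got {len(y)}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("training data contains NaN")
    net = MLPRegressor(
        hidden_layer_sizes=(spec.hidden_dim, spec.embedding_dim),
        activation="relu",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        batch_size=min(spec.batch_size, len(y)),
        max_iter=spec.epochs,
        shuffle=True,
        random_state=seed,
        early_stopping=False,
        n_iter_no_change=spec.epochs,  # run all epochs for determinism
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(X, y)
    if not np.isfinite(net.loss_):
        raise RuntimeError(
            f"encoder training diverged (loss={net.loss_}); "
            "inspect feature scaling and learning rate")
    return EncoderWeights(
        w_hidden=net.coefs_[0].copy(), b_hidden=net.intercepts_[0].copy(),
        w_embed=net.coefs_[1].copy(), b_embed=net.intercepts_[1].copy())


def encode(weights: EncoderWeights, X: np.ndarray) -> np.ndarray:
    """Map an (n, input_dim) matrix to its (n, 12) embedding."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != weights.input_dim:
        raise ValueError(
            f"input has {X.shape[1]} columns, encoder expects "
            f"{weights.input_dim}")
    hidden = np.maximum(X @ weights.w_hidden + weights.b_hidden, 0.0)
    return np.maximum(hidden @ weights.w_embed + weights.b_embed, 0.0)


def train_forest(Z: np.ndarray, y: np.ndarray, n_trees: int = 100,
                 seed: int | None = None) -> RandomForestRegressor:
    """Fit the final random-forest regressor on the embedding."""
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    if len(Z) == 0:
        raise ValueError("empty training set")
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                   n_jobs=1)
    forest.fit(Z, y)
    return forest


def effect_label(ddg: float) -> str:
    """Qualitative affinity effect under the dG_mut - dG_wild convention."""
    if ddg > 0:
        return EFFECT_DECREASES
    if ddg < 0:
        return EFFECT_INCREASES
    return EFFECT_NEUTRAL


class AffinityModel:
    """ddG regression model for one functional class.

    Parameters
    ----------
    endog : measured ddG values (kcal/mol), length n.
    exog : feature matrix (FeatureMatrix or DataFrame), n rows.
    functional_class : optional class label stored with the model.
    feature_spec : pre-computed selection; if None, ``fit`` runs the
        two-stage selection (correlation filter + RFE) itself.
    """

    def __init__(self, endog, exog, functional_class: FunctionalClass | str
                 | None = None,
                 feature_spec: FeatureSpec | None = None,
                 encoder_spec: EncoderSpec | None = None,
                 n_trees: int = 100,
                 n_features: int = DEFAULT_N_FEATURES_PER_CLASS):
        self.exog = exog.data if isinstance(exog, FeatureMatrix) else exog
        self.endog = np.asarray(endog, float)
        if len(self.exog) != len(self.endog):
            raise ValueError("endog and exog row counts differ")
        if isinstance(functional_class, FunctionalClass):
            functional_class = functional_class.value
        self.functional_class = functional_class
        self.feature_spec = feature_spec
        self.encoder_spec = encoder_spec or EncoderSpec()
        self.n_trees = n_trees
        self.n_features = n_features

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str = "ddg",
                       **kwargs) -> "AffinityModel":
        exog = df.drop(columns=[target])
        return cls(df[target].to_numpy(float), exog, **kwargs)

    def fit(self, seed: int = 0) -> "AffinityResults":
        """Select features (if needed), train encoder and forest."""
        if len(self.endog) < 10:
            warnings.warn(
                f"class {self.functional_class}: only {len(self.endog)} "
                "records; model flagged low-n", stacklevel=2)
        spec = self.feature_spec
        if spec is None:
            spec = select_features(
                FeatureMatrix(self.exog,
                              {c: "unknown" for c in self.exog.columns}),
                self.endog, k=min(self.n_features, self.exog.shape[1]),
                seed=seed, class_label=self.functional_class)
        Xs = standardize(self.exog, spec, fit=True).to_numpy(float)
        enc = train_encoder(Xs, self.endog, self.encoder_spec, seed=seed)
        Z = encode(enc, Xs)
        forest = train_forest(Z, self.endog, n_trees=self.n_trees, seed=seed)
        data_hash = hashlib.sha256(
            np.ascontiguousarray(self.exog.to_numpy(float)).tobytes()
            + self.endog.tobytes()).hexdigest()
        return AffinityResults(
            model=self, feature_spec=spec, encoder_weights=enc,
            forest=forest, seed=seed,
            metadata={
                "functional_class": self.functional_class,
                "n_obs": int(len(self.endog)),
                "low_n": bool(len(self.endog) < 10),
                "data_hash": data_hash,
                "fit_date": datetime.datetime.now().isoformat(timespec="seconds"),
            })


@dataclass
class AffinityResults:
    """Fitted per-class ensemble with its provenance and diagnostics."""

    model: AffinityModel | None
    feature_spec: FeatureSpec
    encoder_weights: EncoderWeights
    forest: RandomForestRegressor
    seed: int
    metadata: dict = field(default_factory=dict)

    def _embed(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_spec.selected if c not in X.columns]
        if missing:
            raise ValueError(
                f"input lacks required feature columns: {missing}")
        Xs = standardize(X, self.feature_spec, fit=False).to_numpy(float)
        return encode(self.encoder_weights, Xs)

    def predict(self, X) -> np.ndarray:
        """Predicted ddG (kcal/mol) for feature rows."""
        if isinstance(X, FeatureMatrix):
            X = X.data
        return self.forest.predict(self._embed(X))

    def predict_table(self, X) -> pd.DataFrame:
        """Predictions with qualitative effect labels, one row per input."""
        if isinstance(X, FeatureMatrix):
            X = X.data
        preds = self.predict(X)
        return pd.DataFrame({
            "ddg_pred": preds,
            "effect": [effect_label(p) for p in preds],
        }, index=X.index)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-flavoured)."""
        from .evaluation import metrics
        lines = [
            "Affinity-change ensemble (encoder -> 12-D -> random forest)",
            "=" * 60,
            f"functional class : {self.metadata.get('functional_class')}",
            f"n observations   : {self.metadata.get('n_obs')}",
            f"features selected: {len(self.feature_spec.selected)}",
            f"embedding dim    : {self.encoder_weights.embedding_dim}",
            f"forest trees     : {self.forest.n_estimators}",
            f"seed             : {self.seed}",
        ]
        if self.model is not None:
            m = metrics(self.model.endog, self.fittedvalues)
            lines += [
                f"in-sample PCC    : {m['pcc']:.3f}",
                f"in-sample MAE    : {m['mae']:.3f} kcal/mol",
                f"in-sample RMSE   : {m['rmse']:.3f} kcal/mol",
            ]
        lines.append("=" * 60)
        lines.append("top features: "
                     + ", ".join(self.feature_spec.selected[:8]))
        return "\n".join(lines)


def predict_ddg(results: AffinityResults, X) -> pd.DataFrame:
    """Functional wrapper over :meth:`AffinityResults.predict_table`."""
    return results.predict_table(X)


def train_class_ensembles(features: FeatureMatrix | pd.DataFrame,
                          y: np.ndarray,
                          classes,
                          seed: int = 0,
                          encoder_spec: EncoderSpec | None = None,
                          n_trees: int = 100,
                          n_features: int = DEFAULT_N_FEATURES_PER_CLASS,
                          ) -> dict[str, AffinityResults]:
    """Train one ensemble per functional class present in ``classes``.

    Empty classes are skipped; classes with fewer than 10 records train
    with a low-n warning and are flagged in their metadata.
    """
    data = features.data if isinstance(features, FeatureMatrix) else features
    y = np.asarray(y, float)
    classes = np.asarray([c.value if isinstance(c, FunctionalClass) else c
                          for c in classes])
    out: dict[str, AffinityResults] = {}
    for label in pd.unique(classes):
        mask = classes == label
        if mask.sum() == 0:
            continue
        if mask.sum() < 10:
            warnings.warn(
                f"class {label}: only {int(mask.sum())} records (low-n), "
                "below the encoder minimum; skipped", stacklevel=2)
            continue
        model = AffinityModel(y[mask], data[mask], functional_class=label,
                              encoder_spec=encoder_spec, n_trees=n_trees,
                              n_features=n_features)
        out[label] = model.fit(seed=seed)
    return out


def save_model(results: AffinityResults, path: str | Path) -> None:
    """Persist a fitted ensemble as a single versioned artifact."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "metadata": results.metadata,
        "seed": results.seed,
        "feature_spec": asdict(results.feature_spec),
        "encoder_weights": {
            "w_hidden": results.encoder_weights.w_hidden,
            "b_hidden": results.encoder_weights.b_hidden,
            "w_embed": results.encoder_weights.w_embed,
            "b_embed": results.encoder_weights.b_embed,
        },
        "forest": results.forest,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> AffinityResults:
    """Load a saved ensemble; predictions round-trip bit-identically."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelPersistenceError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelPersistenceError(f"{path} is not a ppamut model artifact")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelPersistenceError(
            f"artifact format {payload['format_version']} incompatible with "
            f"supported version {MODEL_FORMAT_VERSION}")
    ew = payload["encoder_weights"]
    return AffinityResults(
        model=None,
        feature_spec=FeatureSpec(**payload["feature_spec"]),
        encoder_weights=EncoderWeights(
            w_hidden=ew["w_hidden"], b_hidden=ew["b_hidden"],
            w_embed=ew["w_embed"], b_embed=ew["b_embed"]),
        forest=payload["forest"],
        seed=payload["seed"],
        metadata=payload["metadata"],
    )
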