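"""Metrics, cross-validation regimes, reporting and feature importance.

Three split regimes mirror how affinity-change predictors are stress-
tested: plain shuffled k-fold over mutations, leave-one-complex-out (all
mutations of one complex form the test fold, probing generalisation to an
unseen complex), and site-grouped folds (all substitutions at one
(complex, chain, position) site stay together, removing same-site
leakage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_data import FunctionalClass, MutationDataset
from .ensemble_model import AffinityModel, EncoderSpec
from .feature_pipeline import FeatureMatrix


def metrics(y_exp: Sequence[float], y_pred: Sequence[float]) -> dict[str, float]:
    """Pearson correlation, mean absolute error and RMSE between
    experimental and predicted ddG.

    PCC follows the textbook product-moment form
    (n*Sxy - Sx*Sy) / sqrt((n*Sxx - Sx^2)(n*Syy - Sy^2)); MAE and RMSE are
    in kcal/mol.  Zero-variance truth leaves PCC undefined (NaN) while MAE
    and RMSE are still returned.
    """
    x = np.asarray(y_exp, float)
    y = np.asarray(y_pred, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    denom_sq = (n * sxx - sx ** 2) * (n * syy - sy ** 2)
    pcc = ((n * sxy - sx * sy) / np.sqrt(denom_sq)) if denom_sq > 0 else np.nan
    err = x - y
    return {
        "pcc": float(pcc),
        "mae": float(np.abs(err).mean()),
        "rmse": float(np.sqrt((err ** 2).mean())),
    }


def kfold_split(n_or_dataset, k: int = 10, seed: int = 0,
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold over mutation rows.

    Test folds are disjoint, cover all rows, and differ in size by at most
    one; identical seeds reproduce identical folds.
    """
    n = (len(n_or_dataset) if not isinstance(n_or_dataset, int)
         else n_or_dataset)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} rows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i, test in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        out.append((np.sort(train), np.sort(test)))
    return out


def looc_split(dataset_or_complexes) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-complex-out folds, one per complex in first-appearance
    order; the test fold is exactly that complex's mutations."""
    if isinstance(dataset_or_complexes, MutationDataset):
        complexes = np.asarray(
            [r.complex_id for r in dataset_or_complexes.records])
    else:
        complexes = np.asarray(dataset_or_complexes)
    uniq = list(dict.fromkeys(complexes))
    if len(uniq) < 2:
        raise ValueError("leave-one-complex-out needs >= 2 complexes")
    out = []
    idx = np.arange(len(complexes))
    for cid in uniq:
        mask = complexes == cid
        out.append((idx[~mask], idx[mask]))
    return out


def site_grouped_split(dataset_or_sites, k: int = 10, seed: int = 0,
                       mode: str = "site",
                       ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Folds at the mutation-site or variation level.

    ``mode='site'`` keeps every (complex, chain, position) group whole in a
    single fold; ``mode='variation'`` shuffles individual substitutions and
    is identical to :func:`kfold_split` under the same seed.
    """
    if mode == "variation":
        return kfold_split(dataset_or_sites if isinstance(dataset_or_sites, int)
                           else len(dataset_or_sites), k=k, seed=seed)
    if mode != "site":
        raise ValueError(f"mode must be 'site' or 'variation', got {mode!r}")
    if isinstance(dataset_or_sites, MutationDataset):
        sites = [r.site for r in dataset_or_sites.records]
    else:
        sites = [tuple(s) for s in dataset_or_sites]
    uniq = list(dict.fromkeys(sites))
    if k > len(uniq):
        raise ValueError(f"cannot make {k} folds from {len(uniq)} sites")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    group_folds = np.array_split(order, k)
    site_to_fold = {}
    for f, grp in enumerate(group_folds):
        for g in grp:
            site_to_fold[uniq[g]] = f
    fold_of_row = np.asarray([site_to_fold[s] for s in sites])
    idx = np.arange(len(sites))
    out = []
    for f in range(k):
        mask = fold_of_row == f
        out.append((idx[~mask], idx[mask]))
    return out


@dataclass
class EvaluationReport:
    """Cross-validation outcome: per-fold, pooled, per-class and overall.

    ``overall`` is the unweighted mean of the per-class metrics (every
    functional class counts equally); ``pooled`` concatenates all test
    predictions and weights every mutation equally.
    """

    regime: str
    seed: int
    per_fold: list[dict] = field(default_factory=list)
    pooled: dict = field(default_factory=dict)
    per_class: dict[str, dict] = field(default_factory=dict)
    overall: dict = field(default_factory=dict)
    n: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        rows = dict(self.per_class)
        rows["overall"] = self.overall
        rows["pooled"] = self.pooled
        return pd.DataFrame(rows).T


def _default_predictor(encoder_spec: EncoderSpec | None, n_trees: int,
                       n_features: int) -> Callable:
    def predict(train_X: pd.DataFrame, train_y: np.ndarray,
                test_X: pd.DataFrame, seed: int,
                class_label: str | None) -> np.ndarray:
        model = AffinityModel(train_y, train_X, functional_class=class_label,
                              encoder_spec=encoder_spec, n_trees=n_trees,
                              n_features=min(n_features, train_X.shape[1]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(seed=seed)
        return res.predict(test_X)
    return predict


def _mean_metrics(cells: list[dict]) -> dict:
    keys = ("pcc", "mae", "rmse")
    out = {}
    for key in keys:
        vals = [c[key] for c in cells if key in c and np.isfinite(c[key])]
        out[key] = float(np.mean(vals)) if vals else float("nan")
    return out


def run_cv(features: FeatureMatrix | pd.DataFrame,
           y: Sequence[float],
           classes: Sequence,
           complexes: Sequence[str] | None = None,
           sites: Sequence[tuple] | None = None,
           regime: str = "kfold",
           k: int = 10,
           seed: int = 0,
           encoder_spec: EncoderSpec | None = None,
           n_trees: int = 100,
           n_features: int = 20,
           predict_fn: Callable | None = None) -> EvaluationReport:
    """Cross-validate the per-class ensemble under one split regime.

    Within each fold a separate model is trained per functional class on
    the training rows of that class and evaluated on its test rows.
    ``predict_fn(train_X, train_y, test_X, seed, class_label)`` can replace
    the default ensemble (e.g. an oracle for split-contract checks).
    Regimes: ``kfold``, ``looc``, ``site``, ``variation``.
    """
    data = features.data if isinstance(features, FeatureMatrix) else features
    y = np.asarray(y, float)
    classes = np.asarray([c.value if isinstance(c, FunctionalClass) else c
                          for c in classes])
    if regime == "kfold":
        folds = kfold_split(len(y), k=k, seed=seed)
    elif regime == "looc":
        if complexes is None:
            raise ValueError("looc regime needs complex ids")
        folds = looc_split(np.asarray(complexes))
    elif regime in ("site", "variation"):
        if regime == "site" and sites is None:
            raise ValueError("site regime needs site keys")
        folds = site_grouped_split(sites if regime == "site" else len(y),
                                   k=k, seed=seed, mode=regime)
    else:
        raise ValueError(f"unknown regime {regime!r}")

    predict = predict_fn or _default_predictor(encoder_spec, n_trees,
                                               n_features)
    per_fold = []
    all_pred = np.full(len(y), np.nan)
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        fold_pred = np.full(len(test_idx), np.nan)
        for label in pd.unique(classes[train_idx]):
            tr = train_idx[classes[train_idx] == label]
            te_mask = classes[test_idx] == label
            te = test_idx[te_mask]
            if len(te) == 0 or len(tr) == 0:
                continue
            preds = np.asarray(predict(data.iloc[tr], y[tr], data.iloc[te],
                                       seed, str(label)), float)
            fold_pred[te_mask] = preds
            all_pred[te] = preds
        valid = ~np.isnan(fold_pred)
        cell: dict = {"fold": fold_id, "n": int(valid.sum())}
        yv, pv = y[test_idx][valid], fold_pred[valid]
        if valid.sum() >= 2 and np.var(yv) > 0 and np.var(pv) > 0:
            cell.update(metrics(yv, pv))
        elif valid.sum() >= 1:
            # too small or degenerate for a correlation; report errors only
            cell["mae"] = float(np.abs(yv - pv).mean())
            cell["rmse"] = float(np.sqrt(((yv - pv) ** 2).mean()))
            cell["pcc"] = float("nan")
        per_fold.append(cell)

    evaluated = ~np.isnan(all_pred)
    pooled = metrics(y[evaluated], all_pred[evaluated]) if evaluated.sum() >= 2 else {}
    pooled["n"] = int(evaluated.sum())
    per_class = {}
    for label in pd.unique(classes):
        mask = (classes == label) & evaluated
        if mask.sum() >= 2:
            per_class[str(label)] = {**metrics(y[mask], all_pred[mask]),
                                     "n": int(mask.sum())}
    overall = _mean_metrics(list(per_class.values()))
    return EvaluationReport(regime=regime, seed=seed, per_fold=per_fold,
                            pooled=pooled, per_class=per_class,
                            overall=overall, n=len(y))


def feature_importance(results, X, y, n_repeats: int = 5,
                       seed: int = 0) -> pd.DataFrame:
    """Permutation importance: mean drop in PCC when one feature column is
    shuffled, with dispersion over repeats, sorted descending.

    Model-agnostic: works for any fitted object with ``predict`` accepting
    a DataFrame.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if isinstance(X, FeatureMatrix):
        X = X.data
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    baseline = metrics(y, results.predict(X))["pcc"]
    rows = []
    for col in X.columns:
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            drops.append(baseline - metrics(y, results.predict(Xp))["pcc"])
        rows.append({"feature": col,
                     "importance": float(np.mean(drops)),
                     "importance_std": float(np.std(drops))})
    return (pd.DataFrame(rows)
            .sort_values("importance", ascending=False)
            .reset_index(drop=True))


def train_test_report(features, y, classes, test_fraction: float = 0.2,
                      seed: int = 0, **model_kw) -> dict:
    """Headline train/test numbers: stratified-by-class 80/20 split."""
    data = features.data if isinstance(features, FeatureMatrix) else features
    y = np.asarray(y, float)
    classes = np.asarray([c.value if isinstance(c, FunctionalClass) else c
                          for c in classes])
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(y), bool)
    for label in pd.unique(classes):
        idx = np.flatnonzero(classes == label)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_mask[rng.choice(idx, size=n_test, replace=False)] = True
    predict = _default_predictor(model_kw.get("encoder_spec"),
                                 model_kw.get("n_trees", 100),
                                 model_kw.get("n_features", 20))
    train_pred = np.full(len(y), np.nan)
    test_pred = np.full(len(y), np.nan)
    for label in pd.unique(classes):
        tr = np.flatnonzero((classes == label) & ~test_mask)
        te = np.flatnonzero((classes == label) & test_mask)
        if len(tr) == 0 or len(te) == 0:
            continue
        model = AffinityModel(y[tr], data.iloc[tr], functional_class=label,
                              encoder_spec=model_kw.get("encoder_spec"),
                              n_trees=model_kw.get("n_trees", 100),
                              n_features=min(model_kw.get("n_features", 20),
                                             data.shape[1]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(seed=seed)
        train_pred[tr] = res.predict(data.iloc[tr])
        test_pred[te] = res.predict(data.iloc[te])
    tr_mask = ~np.isnan(train_pred)
    te_mask = ~np.isnan(test_pred)
    return {
        "train": metrics(y[tr_mask], train_pred[tr_mask]),
        "test": metrics(y[te_mask], test_pred[te_mask]),
        "n_train": int(tr_mask.sum()), "n_test": int(te_mask.sum()),
    }
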