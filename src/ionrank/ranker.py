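"""Gradient-boosted pairwise ranking of target vs decoy ions.

The model consumes the five per-ion features and is trained with a pairwise
logistic ranking loss: within each dataset, every (target, decoy) pair
contributes, with the target as winner.  Pairs are never formed across
datasets.  The backend contract is "gradient-boosted trees with pairwise
logistic loss, deterministic under seed"; the bundled backend is xgboost's
``rank:pairwise`` objective.  Raw ensemble outputs are min-max scaled to
[0, 1] using bounds recorded over the training corpus; scaling is strictly
monotone, so rankings (and therefore FDR estimates) are invariant to it.

Per-feature attribution uses TreeSHAP values (computed natively by the tree
backend); each ion's contribution share per feature is the absolute SHAP
value divided by the sum of absolute SHAP values across features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .evaluation import average_precision
from .scoring import FEATURE_NAMES

__all__ = [
    "RankerModel",
    "make_training_pairs",
    "train",
    "predict_scaled",
    "crossvalidate",
    "shap_contributions",
]

_REQUIRED_COLUMNS = ("dataset_id", "is_decoy", *FEATURE_NAMES)


def _check_corpus(corpus: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLUMNS if c not in corpus.columns]
    if missing:
        raise ValueError(f"corpus missing columns: {missing}")


@dataclass
class RankerModel:
    booster: xgb.Booster
    feature_names: tuple[str, ...]
    n_iterations: int
    scale_min: float
    scale_max: float
    manifest: dict = field(default_factory=dict)
    zero_importance: bool = False

    def save(self, path: str) -> None:
        """Persist as backend-native model file + JSON manifest sidecar."""
        self.booster.save_model(path)
        manifest = dict(self.manifest)
        manifest.update(
            {
                "feature_names": list(self.feature_names),
                "n_iterations": self.n_iterations,
                "scale_min": self.scale_min,
                "scale_max": self.scale_max,
            }
        )
        with open(path + ".manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "RankerModel":
        booster = xgb.Booster()
        booster.load_model(path)
        with open(path + ".manifest.json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        return cls(
            booster=booster,
            feature_names=tuple(manifest.pop("feature_names")),
            n_iterations=manifest.pop("n_iterations"),
            scale_min=manifest.pop("scale_min"),
            scale_max=manifest.pop("scale_max"),
            manifest=manifest,
        )


def make_training_pairs(corpus: pd.DataFrame) -> pd.DataFrame:
    """Per-dataset pair bookkeeping for the pairwise loss.

    Returns a frame with one row per dataset: n_targets, n_decoys and
    n_pairs = n_targets * n_decoys.  Datasets lacking either side
    contribute zero pairs (logged via warning).
    """
    _check_corpus(corpus)
    rows = []
    for ds_id, g in corpus.groupby("dataset_id", sort=True):
        n_t = int((~g["is_decoy"]).sum())
        n_d = int(g["is_decoy"].sum())
        if n_t == 0 or n_d == 0:
            warnings.warn(f"dataset {ds_id} contributes no training pairs")
        rows.append(
            {
                "dataset_id": ds_id,
                "n_targets": n_t,
                "n_decoys": n_d,
                "n_pairs": n_t * n_d,
            }
        )
    return pd.DataFrame(rows)


def _fit_booster(
    corpus: pd.DataFrame, n_iterations: int, seed: int
) -> xgb.Booster:
    df = corpus.sort_values("dataset_id", kind="stable")
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    y = (~df["is_decoy"].to_numpy(dtype=bool)).astype(np.int32)
    qid = pd.factorize(df["dataset_id"], sort=True)[0]
    dtrain = xgb.DMatrix(X, label=y, qid=qid, feature_names=list(FEATURE_NAMES))
    params = {
        "objective": "rank:pairwise",
        "eta": 0.1,
        "max_depth": 4,
        "tree_method": "hist",
        "nthread": 1,
        "seed": int(seed) & 0x7FFFFFFF,
        "lambdarank_pair_method": "mean",
    }
    return xgb.train(params, dtrain, num_boost_round=n_iterations, verbose_eval=False)


def train(
    corpus: pd.DataFrame, n_iterations: int = 1000, seed: int = 0
) -> RankerModel:
    """Train the pairwise ranking ensemble on a scored corpus.

    ``corpus`` needs columns dataset_id, is_decoy and the five features
    (optionally context).  Min-max scaling bounds are recorded from the raw
    ensemble outputs over the training corpus.  All-constant features are
    tolerated but flagged.
    """
    _check_corpus(corpus)
    pairs = make_training_pairs(corpus)
    if pairs["n_pairs"].sum() == 0:
        raise ValueError("no training pairs in corpus")
    booster = _fit_booster(corpus, n_iterations, seed)
    X = corpus[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    raw = booster.predict(xgb.DMatrix(X, feature_names=list(FEATURE_NAMES)))
    zero_importance = bool(
        (corpus[list(FEATURE_NAMES)].nunique() <= 1).all()
    )
    if zero_importance:
        warnings.warn("all features constant: model has zero importance")
    manifest = {
        "dataset_ids": sorted(map(str, corpus["dataset_id"].unique())),
        "contexts": sorted(map(str, corpus["context"].unique()))
        if "context" in corpus
        else [],
        "seed": int(seed),
    }
    return RankerModel(
        booster=booster,
        feature_names=FEATURE_NAMES,
        n_iterations=n_iterations,
        scale_min=float(raw.min()),
        scale_max=float(raw.max()),
        manifest=manifest,
        zero_importance=zero_importance,
    )


def _predict_raw(model: RankerModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    return model.booster.predict(
        xgb.DMatrix(X, feature_names=list(model.feature_names))
    )


def predict_scaled(model: RankerModel, X: np.ndarray) -> np.ndarray:
    """Min-max scaled ensemble scores in [0, 1] (clipped outside bounds)."""
    raw = _predict_raw(model, X)
    lo, hi = model.scale_min, model.scale_max
    if hi == lo:
        warnings.warn("degenerate scaling bounds; returning constant 0.5")
        return np.full(raw.shape, 0.5)
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


def _stratified_folds(
    corpus: pd.DataFrame, k: int, seed: int
) -> dict[str, int]:
    """Assign each dataset a fold, keeping context proportions constant.

    Contexts with fewer than k datasets are assigned fold -1 (always
    training) with a warning.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    if "context" in corpus.columns:
        ctx = corpus.groupby("dataset_id", sort=True)["context"].first()
    else:
        ctx = pd.Series(
            "all", index=corpus.groupby("dataset_id", sort=True).size().index
        )
    folds: dict[str, int] = {}
    for context in sorted(ctx.unique()):
        ids = sorted(ctx.index[ctx == context])
        if len(ids) < k:
            warnings.warn(
                f"context {context!r} has {len(ids)} datasets < k={k}; kept in training"
            )
            for i in ids:
                folds[i] = -1
            continue
        ids = list(rng.permutation(ids))
        for pos, ds_id in enumerate(ids):
            folds[ds_id] = pos % k
    return folds


def crossvalidate(
    corpus: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    n_iterations: int = 1000,
) -> dict:
    """Context-stratified k-fold cross-validation.

    Each fold trains on the other k-1 folds and scores its held-out
    datasets; AP (average precision of the target-vs-decoy ranking) is
    computed per held-out dataset and MAP is the unweighted mean over all
    (fold, dataset) evaluations.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (need a held-out fold)")
    _check_corpus(corpus)
    folds = _stratified_folds(corpus, k, seed)
    fold_col = corpus["dataset_id"].map(folds)
    per_dataset: dict[str, float] = {}
    for fold in range(k):
        train_df = corpus[fold_col != fold]
        test_df = corpus[fold_col == fold]
        if test_df.empty:
            continue
        model = train(train_df, n_iterations=n_iterations, seed=seed + fold)
        for ds_id, g in test_df.groupby("dataset_id", sort=True):
            scores = predict_scaled(model, g[list(FEATURE_NAMES)].to_numpy())
            order = np.argsort(-scores, kind="stable")
            labels = (~g["is_decoy"].to_numpy(dtype=bool))[order]
            if labels.sum() == 0:
                warnings.warn(f"dataset {ds_id} has no targets; skipped in AP")
                continue
            per_dataset[str(ds_id)] = average_precision(labels)
    if not per_dataset:
        raise ValueError("cross-validation evaluated no datasets")
    return {
        "per_dataset_ap": per_dataset,
        "map": float(np.mean(list(per_dataset.values()))),
        "folds": folds,
    }


def shap_contributions(
    model: RankerModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ion feature contribution shares from TreeSHAP values.

    Returns ``(shares, degenerate)``: shares is (n, 5), each row nonnegative
    and summing to 1; degenerate flags ions whose attributions were all zero
    (assigned uniform shares).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    contribs = model.booster.predict(
        xgb.DMatrix(X, feature_names=list(model.feature_names)),
        pred_contribs=True,
    )[:, :-1]  # drop bias column
    absval = np.abs(contribs.astype(np.float64))
    totals = absval.sum(axis=1)
    degenerate = totals == 0
    shares = np.empty_like(absval)
    shares[degenerate] = 1.0 / absval.shape[1]
    ok = ~degenerate
    shares[ok] = absval[ok] / totals[ok, None]
    return shares, degenerate
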