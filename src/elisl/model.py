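"""Early-late integrated forest ensembles for SL prediction.

Given k per-source feature blocks, k single-source tree ensembles plus one
early-integration model on the concatenated features are trained with one
shared hyperparameter configuration. The configuration is chosen by
sequential model-based search over a declared finite grid, scored by the
mean 5-fold cross-validated AUPRC of the weighted ensemble. Each submodel's
weight is its own mean validation AUPRC normalized over all k+1 submodels,

    w_i = p_i / sum_j p_j,

and the final score of a pair is the weighted average of the submodels'
class probabilities, yhat = sum_i w_i yhat_i. Missing feature values are
imputed by per-column training medians frozen at fit time.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

from .data_io import FeatureBlock, GenePair, SLLabelTable

logger = logging.getLogger(__name__)

CONCAT_SOURCE = "concat"

#: declared hyperparameter grid shared by all k+1 submodels
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 200, 500],
    "max_depth": [4, 8, None],
    "min_samples_leaf": [1, 5, 10],
}
GB_EXTRA_GRID: dict[str, list] = {"learning_rate": [0.05, 0.1, 0.3]}


@dataclass
class FitConfig:
    ensemble_kind: str = "rf"  # "rf" (random forest) or "gb" (gradient boosting)
    search_budget: int = 25
    n_folds: int = 5
    seed: int = 0
    grid: dict[str, list] | None = None

    def grid_points(self) -> list[dict]:
        grid = dict(self.grid) if self.grid is not None else dict(DEFAULT_GRID)
        if self.grid is None and self.ensemble_kind == "gb":
            grid.update(GB_EXTRA_GRID)
        keys = sorted(grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _make_estimator(kind: str, params: Mapping, seed: int):
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_depth=params.get("max_depth"),
            min_samples_leaf=params.get("min_samples_leaf", 1),
            random_state=seed,
            n_jobs=1,
        )
    if kind == "gb":
        from xgboost import XGBClassifier

        max_depth = params.get("max_depth")
        return XGBClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_depth=0 if max_depth is None else int(max_depth),
            min_child_weight=params.get("min_samples_leaf", 1),
            learning_rate=params.get("learning_rate", 0.1),
            tree_method="hist",
            grow_policy="lossguide",
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    raise ValueError(f"unknown ensemble kind {kind!r}")


@dataclass
class ElislModel:
    """k+1 fitted submodels with validation-normalized weights."""

    submodels: list
    weights: np.ndarray
    val_performance: np.ndarray
    sources: list[str]  # k source tags + "concat"
    widths: list[int]
    columns: dict[str, list[str]]
    impute_medians: dict[str, np.ndarray]
    hyperparams: dict
    ensemble_kind: str
    seed: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.submodels):
            raise ValueError("one weight per submodel required")
        if (self.weights < 0).any() or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")

    @property
    def k(self) -> int:
        return len(self.submodels) - 1


def assemble_datasets(blocks: Sequence[FeatureBlock]) -> list[FeatureBlock]:
    """The k per-source blocks plus their column-wise concatenation
    (provenance kept in the column names). All blocks must list the same
    pairs in the same order."""
    if len(blocks) < 2:
        raise ValueError("early-late integration needs k >= 2 sources")
    ref = [p.genes for p in blocks[0].pairs]
    for blk in blocks[1:]:
        if [p.genes for p in blk.pairs] != ref:
            raise ValueError(
                f"pair list of block {blk.source!r} does not match {blocks[0].source!r}"
            )
    concat = FeatureBlock(
        list(blocks[0].pairs),
        np.hstack([b.values for b in blocks]),
        [c for b in blocks for c in b.columns],
        CONCAT_SOURCE,
    )
    return list(blocks) + [concat]


def _impute(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    out = X.copy()
    nan_rows, nan_cols = np.nonzero(np.isnan(out))
    out[nan_rows, nan_cols] = medians[nan_cols]
    return out


def _column_medians(X: np.ndarray) -> np.ndarray:
    import warnings

    with np.errstate(all="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            med = np.nanmedian(X, axis=0)
    return np.nan_to_num(med, nan=0.0)


def _cv_trial(
    datasets: Sequence[FeatureBlock],
    y: np.ndarray,
    params: Mapping,
    config: FitConfig,
) -> tuple[float, np.ndarray]:
    """One hyperparameter trial: stratified k-fold CV of all submodels.

    Returns (mean ensemble validation AUPRC, mean per-submodel AUPRC)."""
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    n_models = len(datasets)
    fold_sub = []
    fold_ens = []
    for train_idx, val_idx in skf.split(np.zeros(len(y)), y):
        probs = np.zeros((n_models, len(val_idx)))
        sub_scores = np.zeros(n_models)
        for i, ds in enumerate(datasets):
            medians = _column_medians(ds.values[train_idx])
            Xtr = _impute(ds.values[train_idx], medians)
            Xva = _impute(ds.values[val_idx], medians)
            est = _make_estimator(config.ensemble_kind, params, config.seed)
            est.fit(Xtr, y[train_idx])
            probs[i] = est.predict_proba(Xva)[:, 1]
            sub_scores[i] = average_precision_score(y[val_idx], probs[i])
        w = sub_scores / sub_scores.sum() if sub_scores.sum() > 0 else np.full(n_models, 1 / n_models)
        ens = average_precision_score(y[val_idx], w @ probs)
        fold_sub.append(sub_scores)
        fold_ens.append(ens)
    return float(np.mean(fold_ens)), np.mean(fold_sub, axis=0)


def _smbo_order(
    grid: list[dict], budget: int, evaluate, seed: int
) -> tuple[int, list[tuple[int, float]]]:
    """Sequential model-based optimization over a finite grid.

    A few random configurations seed a random-forest surrogate of the CV
    score; remaining trials greedily pick the grid point with the best
    surrogate upper bound. Returns (best index, [(index, score), ...])."""
    from sklearn.ensemble import RandomForestRegressor

    rng = np.random.default_rng(seed)
    keys = sorted(grid[0]) if grid else []

    def encode(pt: dict) -> list[float]:
        out = []
        for k in keys:
            v = pt[k]
            out.append(-1.0 if v is None else float(v))
        return out

    X_all = np.array([encode(pt) for pt in grid])
    n_init = min(max(3, budget // 5), budget)
    order = rng.permutation(len(grid))
    tried: list[tuple[int, float]] = []
    candidates = list(order)
    for idx in candidates[:n_init]:
        tried.append((int(idx), evaluate(grid[idx])))
    while len(tried) < budget:
        remaining = [i for i in range(len(grid)) if i not in {t[0] for t in tried}]
        if not remaining:
            break
        Xobs = X_all[[t[0] for t in tried]]
        yobs = np.array([t[1] for t in tried])
        surrogate = RandomForestRegressor(n_estimators=50, random_state=seed)
        surrogate.fit(Xobs, yobs)
        preds = np.stack([t.predict(X_all[remaining]) for t in surrogate.estimators_])
        ucb = preds.mean(axis=0) + preds.std(axis=0)
        nxt = remaining[int(np.argmax(ucb))]
        tried.append((nxt, evaluate(grid[nxt])))
    best = max(tried, key=lambda t: (t[1], -t[0]))
    return best[0], tried


def fit(
    blocks: Sequence[FeatureBlock],
    labels: SLLabelTable,
    config: FitConfig | None = None,
) -> ElislModel:
    """Fit the k+1 submodels with a shared hyperparameter configuration.

    The search is exhaustive when the declared grid is no larger than the
    budget, otherwise sequential model-based. Validation performances p_i
    (mean fold AUPRC per submodel, taken from the winning trial) become the
    ensemble weights w_i = p_i / sum p_j; if all p_i are zero the weights
    fall back to uniform.
    """
    config = config or FitConfig()
    if config.search_budget < 1:
        raise ValueError("search budget must be >= 1")
    datasets = assemble_datasets(blocks)
    pairs = datasets[0].pairs
    y = labels.labels_for(pairs)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")

    grid = config.grid_points()
    results: dict[int, tuple[float, np.ndarray]] = {}

    def evaluate(params: Mapping) -> float:
        idx = grid.index(dict(params))
        if idx not in results:
            results[idx] = _cv_trial(datasets, y, params, config)
        return results[idx][0]

    if len(grid) <= config.search_budget:
        for i, pt in enumerate(grid):
            evaluate(pt)
        best_idx = max(results, key=lambda i: (results[i][0], -i))
    else:
        best_idx, _ = _smbo_order(grid, config.search_budget, evaluate, config.seed)

    best_params = grid[best_idx]
    p_i = results[best_idx][1]
    weights = p_i / p_i.sum() if p_i.sum() > 0 else np.full(len(datasets), 1 / len(datasets))

    submodels = []
    impute_medians: dict[str, np.ndarray] = {}
    for ds in datasets:
        medians = _column_medians(ds.values)
        impute_medians[ds.source] = medians
        est = _make_estimator(config.ensemble_kind, best_params, config.seed)
        est.fit(_impute(ds.values, medians), y)
        submodels.append(est)

    return ElislModel(
        submodels=submodels,
        weights=weights,
        val_performance=p_i,
        sources=[ds.source for ds in datasets],
        widths=[ds.n_features for ds in datasets],
        columns={ds.source: list(ds.columns) for ds in datasets},
        impute_medians=impute_medians,
        hyperparams=dict(best_params),
        ensemble_kind=config.ensemble_kind,
        seed=config.seed,
    )


def _check_blocks(model: ElislModel, blocks: Sequence[FeatureBlock]) -> list[FeatureBlock]:
    datasets = assemble_datasets(blocks)
    got = [(d.source, d.n_features) for d in datasets]
    expect = list(zip(model.sources, model.widths))
    if got != expect:
        raise ValueError(f"blocks {got} do not match the model's sources {expect}")
    return datasets


def predict(model: ElislModel, blocks: Sequence[FeatureBlock]) -> np.ndarray:
    """Weighted-average class probability per pair, yhat = sum w_i yhat_i."""
    return predict_per_model(model, blocks)[1]


def predict_per_model(
    model: ElislModel, blocks: Sequence[FeatureBlock]
) -> tuple[np.ndarray, np.ndarray]:
    """(per-submodel probabilities [k+1, N], ensemble probabilities [N])."""
    datasets = _check_blocks(model, blocks)
    probs = np.zeros((len(datasets), datasets[0].n_pairs))
    for i, ds in enumerate(datasets):
        X = _impute(ds.values, model.impute_medians[ds.source])
        probs[i] = model.submodels[i].predict_proba(X)[:, 1]
    return probs, model.weights @ probs


@dataclass
class PanCancerModel:
    """Weighted ensemble over already-trained per-cancer models."""

    models: dict[str, ElislModel]
    weights: dict[str, float]


def ensemble_pan_cancer(
    models: Mapping[str, ElislModel],
    validation_perf: Mapping[str, float],
    exclude: str | None = None,
) -> PanCancerModel:
    """Combine per-cancer models with validation-performance-normalized
    weights; optionally excluding the target cancer's own model
    (leave-one-cancer-out)."""
    included = {c: m for c, m in models.items() if c != exclude}
    if len(included) < 2:
        raise ValueError("pan-cancer ensembling needs at least 2 models")
    perfs = np.array([float(validation_perf[c]) for c in included])
    if perfs.sum() > 0:
        w = perfs / perfs.sum()
    else:
        w = np.full(len(included), 1 / len(included))
    return PanCancerModel(models=dict(included), weights=dict(zip(included, w)))


def predict_pan_cancer(model: PanCancerModel, blocks: Sequence[FeatureBlock]) -> np.ndarray:
    score = None
    for cancer, m in model.models.items():
        contrib = model.weights[cancer] * predict(m, blocks)
        score = contrib if score is None else score + contrib
    return score


def rank_predictions(scores: Mapping[GenePair, Sequence[float]]) -> pd.DataFrame:
    """Rank pairs by mean score over runs (descending), ties broken
    lexicographically by pair; reports the number of contributing runs."""
    rows = [
        (p.gene_a, p.gene_b, float(np.mean(v)), len(v))
        for p, v in scores.items()
        if len(v) > 0
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "mean_score", "n_runs"])
    return df.sort_values(
        ["mean_score", "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model archive


def save_model(model: ElislModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "k": model.k,
        "sources": model.sources,
        "widths": model.widths,
        "weights": model.weights.tolist(),
        "val_performance": model.val_performance.tolist(),
        "hyperparams": model.hyperparams,
        "ensemble_kind": model.ensemble_kind,
        "seed": model.seed,
        "columns": model.columns,
        "impute_medians": {s: m.tolist() for s, m in model.impute_medians.items()},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for source, est in zip(model.sources, model.submodels):
        joblib.dump(est, directory / f"submodel_{source}.joblib")


def load_model(directory: str | Path) -> ElislModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    submodels = [
        joblib.load(directory / f"submodel_{source}.joblib")
        for source in manifest["sources"]
    ]
    return ElislModel(
        submodels=submodels,
        weights=np.array(manifest["weights"]),
        val_performance=np.array(manifest["val_performance"]),
        sources=manifest["sources"],
        widths=manifest["widths"],
        columns=manifest["columns"],
        impute_medians={s: np.array(m) for s, m in manifest["impute_medians"].items()},
        hyperparams=manifest["hyperparams"],
        ensemble_kind=manifest["ensemble_kind"],
        seed=manifest["seed"],
    )


def normalize_weights(performances: Sequence[float]) -> np.ndarray:
    """w_i = p_i / sum_j p_j (uniform fallback when all p_i are zero)."""
    p = np.asarray(performances, dtype=float)
    if (p < 0).any():
        raise ValueError("performances must be non-negative")
    return p / p.sum() if p.sum() > 0 else np.full(len(p), 1 / len(p))
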