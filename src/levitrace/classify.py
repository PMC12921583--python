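"""Supervised UMAP embedding and random-forest Monte Carlo cross-validation.

Two complementary views of the feature table:

* a descriptive 2-D supervised UMAP embedding (n_neighbors = 50,
  min_dist = 0.0) to visualise class separation, and
* Monte Carlo cross-validation (MCCV) of a random-forest classifier:
  repeated stratified random 80/20 train/test splits, each training a fresh
  forest and recording test accuracy, out-of-bag error and normalised
  feature importances. MCCV yields an accuracy *distribution* rather than a
  single score, which is what small cohorts (tens of particles) call for.

One master seed deterministically spawns every per-iteration split seed and
forest seed, so a full run is bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_COLUMNS, LABEL_COLUMN

__all__ = [
    "EmbeddingResult",
    "MccvResult",
    "embed",
    "mccv",
    "tune",
    "importance_summary",
    "plot_embedding",
    "plot_accuracy_trace",
    "plot_importances",
]

DEFAULT_FOREST = {"n_estimators": 100, "max_depth": None, "max_features": "sqrt"}


@dataclass
class EmbeddingResult:
    """2-D embedding coordinates with the settings that produced them."""

    coords: np.ndarray
    labels: np.ndarray
    settings: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"umap_1": self.coords[:, 0], "umap_2": self.coords[:, 1],
             LABEL_COLUMN: self.labels}
        )


@dataclass
class MccvResult:
    """Per-iteration accuracies, OOB errors and feature importances."""

    accuracies: np.ndarray          # (n_iter,)
    oob_errors: np.ndarray          # (n_iter,)
    importances: np.ndarray         # (n_iter, n_features), rows sum to 1
    feature_names: list[str]
    settings: dict = field(default_factory=dict)

    @property
    def mean_acc(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def min_acc(self) -> float:
        return float(np.min(self.accuracies))

    @property
    def max_acc(self) -> float:
        return float(np.max(self.accuracies))

    @property
    def mean_importances(self) -> pd.Series:
        return pd.Series(
            self.importances.mean(axis=0), index=self.feature_names
        ).sort_values(ascending=False)

    def to_json(self, path) -> None:
        payload = {
            "settings": self.settings,
            "mean_accuracy": self.mean_acc,
            "min_accuracy": self.min_acc,
            "max_accuracy": self.max_acc,
            "accuracies": self.accuracies.tolist(),
            "oob_errors": self.oob_errors.tolist(),
            "mean_importances": self.mean_importances.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def iterations_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.importances,
            columns=[f"imp_{c}" for c in self.feature_names],
        )
        df.insert(0, "accuracy", self.accuracies)
        df.insert(1, "oob_error", self.oob_errors)
        df.insert(0, "iteration", np.arange(len(self.accuracies)))
        return df


def _matrix(table: pd.DataFrame, feature_subset=None):
    features = list(feature_subset) if feature_subset else [
        c for c in table.columns if c != LABEL_COLUMN and
        pd.api.types.is_numeric_dtype(table[c])
    ]
    x = table[features].to_numpy(dtype=float)
    y = table[LABEL_COLUMN].to_numpy()
    return x, y, features


def embed(
    table: pd.DataFrame,
    n_neighbors: int = 50,
    min_dist: float = 0.0,
    supervised: bool = True,
    seed: int = 0,
    scale: bool = True,
) -> EmbeddingResult:
    """Supervised 2-D UMAP embedding of the feature table.

    Features are standardised first (columns span ~20 orders of magnitude in
    SI units). In supervised mode the class labels steer the layout; it is a
    descriptive view of the full dataset, not a classifier, so no train/test
    split applies. ``n_neighbors`` is clamped to n-1 with a warning on small
    tables. Deterministic for a fixed seed.
    """
    import umap  # deferred: numba compilation is slow at import

    x, y, features = _matrix(table)
    labels = y.copy()
    if supervised and len(np.unique(labels)) < 2:
        raise ValueError("supervised embedding requires at least 2 classes")
    if n_neighbors >= len(table):
        warnings.warn(
            f"n_neighbors={n_neighbors} >= n_rows={len(table)}; clamped",
            stacklevel=2,
        )
        n_neighbors = max(len(table) - 1, 2)
    if scale:
        x = StandardScaler().fit_transform(x)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    if supervised:
        codes = pd.factorize(labels)[0]
        coords = reducer.fit_transform(x, y=codes)
    else:
        coords = reducer.fit_transform(x)
    return EmbeddingResult(
        coords=np.asarray(coords),
        labels=labels,
        settings={
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "supervised": supervised,
            "seed": seed,
            "scale": scale,
            "features": features,
        },
    )


def mccv(
    table: pd.DataFrame,
    n_iter: int = 300,
    test_fraction: float = 0.2,
    forest_settings: dict | None = None,
    feature_subset: list[str] | None = None,
    seed: int = 0,
    stratified: bool = True,
) -> MccvResult:
    """Monte Carlo cross-validation of a random-forest classifier.

    Each iteration draws a fresh random split (stratified by class unless
    disabled), trains a forest, and records the test accuracy (unweighted
    fraction correct), the out-of-bag error, and the impurity-decrease
    feature importances normalised to sum to one. If an unstratified split
    leaves a class out of the training set, that split is redrawn.
    """
    if not 0.0 < test_fraction <= 0.5:
        raise ValueError("test_fraction must lie in (0, 0.5]")
    x, y, features = _matrix(table, feature_subset)
    class_counts = pd.Series(y).value_counts()
    if (class_counts < 2).any():
        raise ValueError("every class needs at least 2 rows")
    forest_settings = {**DEFAULT_FOREST, **(forest_settings or {})}
    # stratified splits need at least one test row per class
    n_test = int(np.ceil(test_fraction * len(y)))
    if stratified:
        n_test = max(n_test, len(class_counts))
    master = np.random.SeedSequence(seed)
    iter_seeds = master.spawn(n_iter)
    accuracies = np.empty(n_iter)
    oob_errors = np.empty(n_iter)
    importances = np.empty((n_iter, len(features)))
    n_classes = len(class_counts)
    for i, iter_ss in enumerate(iter_seeds):
        states = iter_ss.generate_state(8) % (2**31)
        attempt = 0
        while True:
            split_state = int(states[attempt % 4])
            x_tr, x_te, y_tr, y_te = train_test_split(
                x, y, test_size=n_test,
                stratify=y if stratified else None,
                random_state=split_state,
            )
            if len(np.unique(y_tr)) == n_classes:
                break
            attempt += 1  # resample a split missing a class
        forest = RandomForestClassifier(
            oob_score=True, bootstrap=True, n_jobs=1,
            random_state=int(states[4]), **forest_settings,
        )
        with warnings.catch_warnings():
            # tiny training sets legitimately leave some rows OOB-less
            warnings.filterwarnings("ignore", message=".*out-of-bag.*")
            warnings.filterwarnings("ignore", message=".*OOB.*")
            forest.fit(x_tr, y_tr)
        accuracies[i] = float(np.mean(forest.predict(x_te) == y_te))
        oob_errors[i] = 1.0 - float(forest.oob_score_)
        imp = forest.feature_importances_
        total = imp.sum()
        importances[i] = imp / total if total > 0 else np.full_like(imp, 1 / len(imp))
    return MccvResult(
        accuracies=accuracies,
        oob_errors=oob_errors,
        importances=importances,
        feature_names=features,
        settings={
            "n_iter": n_iter,
            "test_fraction": test_fraction,
            "forest": {k: (v if v is None or isinstance(v, (int, float, str)) else str(v))
                       for k, v in forest_settings.items()},
            "feature_subset": features,
            "seed": seed,
            "stratified": stratified,
        },
    )


DEFAULT_FOREST_GRID = {
    "n_estimators": [100, 300, 500],
    "max_depth": [None, 5, 10],
    "max_features": ["sqrt", None],
}


def tune(
    table: pd.DataFrame,
    forest_grid: dict | None = None,
    feature_subsets: list[list[str]] | None = None,
    n_iter: int = 30,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid evaluation by mean MCCV accuracy at reduced n_iter.

    Returns the best configuration and the full grid report. Ties are broken
    by fewer features, then fewer trees, then shallower depth (None counts
    as unbounded, i.e. deepest).
    """
    forest_grid = forest_grid or DEFAULT_FOREST_GRID
    if not forest_grid or any(len(v) == 0 for v in forest_grid.values()):
        raise ValueError("forest_grid must be non-empty")
    if feature_subsets is None:
        _, _, all_features = _matrix(table)
        feature_subsets = [all_features]
    if not feature_subsets:
        raise ValueError("feature_subsets must be non-empty")
    keys = list(forest_grid)
    rows = []
    for subset in feature_subsets:
        for combo in product(*(forest_grid[k] for k in keys)):
            settings = dict(zip(keys, combo))
            result = mccv(
                table, n_iter=n_iter, test_fraction=test_fraction,
                forest_settings=settings, feature_subset=subset, seed=seed,
            )
            rows.append({
                "mean_accuracy": result.mean_acc,
                "n_features": len(subset),
                "features": tuple(subset),
                **settings,
            })
    report = pd.DataFrame(rows)

    def sort_key(row):
        depth = row.get("max_depth")
        return (
            -row["mean_accuracy"],
            row["n_features"],
            row.get("n_estimators", 0),
            float("inf") if depth is None else depth,
        )

    best_row = min(rows, key=sort_key)
    best = {
        "forest_settings": {k: best_row[k] for k in keys},
        "feature_subset": list(best_row["features"]),
        "mean_accuracy": best_row["mean_accuracy"],
    }
    return best, report


def importance_summary(
    result: MccvResult,
    all_features: list[str] | None = None,
) -> pd.DataFrame:
    """Rank features by mean importance over iterations.

    Features present in ``all_features`` but absent from the evaluated
    subset in every iteration are reported with ``used = False`` (e.g. a
    feature dropped by tuning from all iterations).
    """
    ranked = result.mean_importances
    df = pd.DataFrame({
        "feature": ranked.index,
        "mean_importance": ranked.to_numpy(),
        "used": True,
    })
    if all_features:
        unused = [f for f in all_features if f not in result.feature_names]
        if unused:
            df = pd.concat(
                [df, pd.DataFrame({
                    "feature": unused,
                    "mean_importance": np.nan,
                    "used": False,
                })],
                ignore_index=True,
            )
    return df.reset_index(drop=True)


# --------------------------------------------------------------------------
# Plots

def plot_embedding(result: EmbeddingResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in pd.unique(result.labels):
        m = result.labels == cls
        ax.scatter(result.coords[m, 0], result.coords[m, 1], s=14, label=str(cls))
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_accuracy_trace(result: MccvResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(result.accuracies, lw=0.7)
    ax.axhline(result.mean_acc, color="k", ls="--", lw=0.8,
               label=f"mean = {result.mean_acc:.2f}")
    ax.set_xlabel("MCCV iteration")
    ax.set_ylabel("test accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_importances(result: MccvResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    imp = result.mean_importances
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(range(len(imp)), imp.to_numpy())
    ax.set_xticks(range(len(imp)))
    ax.set_xticklabels(imp.index, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("mean importance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
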