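"""Model-selection and comparison protocols.

Implements the selection pipeline around the classifier: per-descriptor
gradient-boosted-tree benchmarking under stratified 10-fold CV, pairwise
branch-combination comparisons on a repeated 80/20 split, classical ML
baselines on mean-pooled embeddings, the three-way ablation
(inception-only / transformer-only / dual), the epoch x dropout grid
search, and the Wilcoxon / Friedman significance tests.

Every experiment returns a pandas DataFrame with one row per configuration
and ``<metric>_mean`` / ``<metric>_std`` columns over the nine evaluation
metrics, with a reproducibility manifest in ``DataFrame.attrs``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .descriptors import descriptor_registry, featurize
from .embeddings import EmbeddingProvider, mean_pool
from .metrics import METRIC_NAMES, MetricReport, compute_metrics, stratified_kfold
from .network import ModelConfig
from .samples import SampleSet, SplitSpec, split_dataset
from .training import evaluate, train

EMBEDDING_FEATURE = "embedding_mean"  # pseudo-descriptor: mean-pooled provider embeddings


def _xgb(seed: int) -> XGBClassifier:
    return XGBClassifier(n_estimators=100, max_depth=4, learning_rate=0.3,
                         eval_metric="logloss", random_state=seed, n_jobs=1,
                         verbosity=0)


def _summary_row(name: str, reports: list[MetricReport], extra: dict | None = None) -> dict:
    values = np.array([r.values() for r in reports])
    row: dict = {"name": name}
    for j, metric in enumerate(METRIC_NAMES):
        row[f"{metric}_mean"] = float(values[:, j].mean())
        row[f"{metric}_std"] = float(values[:, j].std(ddof=0))
    if extra:
        row.update(extra)
    return row


def _features_for(data: SampleSet, name: str,
                  provider: EmbeddingProvider | None) -> np.ndarray:
    if name == EMBEDDING_FEATURE:
        if provider is None:
            raise ValueError("embedding features require a provider")
        return mean_pool(provider.embed_set(data))
    return featurize(data, name)


def descriptor_benchmark(data: SampleSet, descriptors: list[str], k: int = 10,
                         seed: int = 0,
                         provider: EmbeddingProvider | None = None) -> pd.DataFrame:
    """Stratified k-fold CV of a gradient-boosted-tree model per descriptor.

    ``descriptors`` may include :data:`EMBEDDING_FEATURE` to benchmark
    mean-pooled provider embeddings against the sequence descriptors.
    """
    registry = descriptor_registry()
    for name in descriptors:
        if name != EMBEDDING_FEATURE and name not in registry:
            raise KeyError(f"unknown descriptor {name!r}")
    y = data.labels
    folds = stratified_kfold(y, k=k, seed=seed)
    rows = []
    fold_scores: dict[str, np.ndarray] = {}
    for name in descriptors:
        X = _features_for(data, name, provider)
        reports = []
        for train_idx, test_idx in folds:
            clf = _xgb(seed)
            clf.fit(X[train_idx], y[train_idx])
            probs = clf.predict_proba(X[test_idx])[:, 1]
            reports.append(compute_metrics(y[test_idx], probs))
        rows.append(_summary_row(name, reports, {"n_folds": k}))
        fold_scores[name] = np.array([r.values() for r in reports])
    table = pd.DataFrame(rows).set_index("name")
    table.attrs["manifest"] = {"protocol": "descriptor_benchmark", "k": k,
                               "seed": seed, "descriptors": list(descriptors)}
    table.attrs["fold_scores"] = fold_scores
    return table


def branch_combination_experiment(data: SampleSet,
                                  combos: list[tuple[str, str]],
                                  repeats: int = 20,
                                  cfg: ModelConfig | None = None,
                                  provider: EmbeddingProvider | None = None,
                                  fraction: float = 0.8,
                                  seeds: list[int] | None = None) -> pd.DataFrame:
    """Train each (branch1, branch2) pair on an 80/20 split, repeatedly.

    Each repeat reseeds both the split and the model initialisation, so the
    table is exactly re-creatable from its manifest.
    """
    cfg = cfg or ModelConfig()
    seeds = seeds or list(range(1, repeats + 1))
    rows = []
    per_combo_scores: dict[str, np.ndarray] = {}
    for b1, b2 in combos:
        combo_cfg = replace(cfg, branch_mode="dual", branch1_type=b1, branch2_type=b2)
        reports = []
        for s in seeds:
            tr, va = split_dataset(data, SplitSpec(fraction_first=fraction, seed=s))
            tm = train(tr, provider, combo_cfg, seed=s)
            reports.append(evaluate(tm, va, provider))
        name = f"{b1}+{b2}"
        rows.append(_summary_row(name, reports, {"n_repeats": len(seeds)}))
        per_combo_scores[name] = np.array([r.values() for r in reports])
    table = pd.DataFrame(rows).set_index("name")
    table.attrs["manifest"] = {"protocol": "branch_combination", "seeds": seeds,
                               "fraction": fraction, "config": cfg.to_json(),
                               "combos": [list(c) for c in combos]}
    table.attrs["repeat_scores"] = per_combo_scores
    return table


def ml_baseline_experiment(data: SampleSet, provider: EmbeddingProvider,
                           repeats: int = 20, fraction: float = 0.8,
                           seeds: list[int] | None = None) -> pd.DataFrame:
    """SVM / XGB / logistic-regression / KNN on mean-pooled embeddings.

    Uses the same repeated 80/20 split protocol as the deep-model
    comparison so rows are directly comparable.
    """
    seeds = seeds or list(range(1, repeats + 1))
    X_all = mean_pool(provider.embed_set(data))
    y_all = data.labels
    makers = {
        "SVM": lambda s: SVC(kernel="rbf", probability=True, random_state=s),
        "XGBoost": _xgb,
        "LogisticRegression": lambda s: LogisticRegression(max_iter=2000, random_state=s),
        "KNN": lambda s: KNeighborsClassifier(n_neighbors=5),
    }
    rows = []
    for name, make in makers.items():
        reports = []
        for s in seeds:
            tr_idx, va_idx = _split_indices(y_all, fraction, s)
            clf = make(s)
            clf.fit(X_all[tr_idx], y_all[tr_idx])
            probs = clf.predict_proba(X_all[va_idx])[:, 1]
            reports.append(compute_metrics(y_all[va_idx], probs))
        rows.append(_summary_row(name, reports, {"n_repeats": len(seeds)}))
    table = pd.DataFrame(rows).set_index("name")
    table.attrs["manifest"] = {"protocol": "ml_baselines", "seeds": seeds,
                               "fraction": fraction, "provider_dim": provider.dim}
    return table


def _split_indices(labels: np.ndarray, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    first = []
    for cls in (1, 0):
        cls_idx = np.flatnonzero(labels == cls)
        n_take = int(np.floor(fraction * len(cls_idx)))
        first.extend(cls_idx[rng.permutation(len(cls_idx))[:n_take]].tolist())
    first_set = set(first)
    second = [i for i in range(len(labels)) if i not in first_set]
    return np.array(sorted(first_set)), np.array(second)


def ablation_experiment(train_set: SampleSet, test_set: SampleSet,
                        provider: EmbeddingProvider | None,
                        cfg: ModelConfig | None = None,
                        seeds: list[int] | None = None) -> pd.DataFrame:
    """Inception-only vs transformer-only vs dual, identical seeds throughout."""
    overlap = set(train_set.ids) & set(test_set.ids)
    if overlap:
        raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
    cfg = cfg or ModelConfig()
    seeds = seeds or [1]
    rows = []
    for mode in ("inception_only", "transformer_only", "dual"):
        mode_cfg = replace(cfg, branch_mode=mode)
        reports = [evaluate(train(train_set, provider, mode_cfg, seed=s), test_set, provider)
                   for s in seeds]
        rows.append(_summary_row(mode, reports, {"n_repeats": len(seeds)}))
    table = pd.DataFrame(rows).set_index("name")
    table.attrs["manifest"] = {"protocol": "ablation", "seeds": seeds,
                               "config": cfg.to_json()}
    return table


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid: epochs x inception dropout x other dropout."""

    epochs: tuple[int, ...] = (15, 18, 20)
    dropout_inception: tuple[float, ...] = (0.3, 0.4, 0.5)
    dropout_other: tuple[float, ...] = (0.3, 0.4, 0.5)

    def __post_init__(self) -> None:
        if not (self.epochs and self.dropout_inception and self.dropout_other):
            raise ValueError("grid candidate lists must be non-empty")

    def combinations(self) -> list[tuple[int, float, float]]:
        return list(itertools.product(self.epochs, self.dropout_inception,
                                      self.dropout_other))


def select_best(scores: pd.DataFrame) -> pd.Series:
    """Minimum rank-sum over F1, MCC, AUC and AUPR; ties by F1 then MCC.

    Pure function of the score table: re-ranking a stored table reproduces
    the selection.
    """
    ranks = sum((-scores[m]).rank(method="min") for m in ("F1", "MCC", "AUC", "AUPR"))
    order = pd.DataFrame({"rank_sum": ranks, "F1": -scores["F1"], "MCC": -scores["MCC"]})
    best_idx = order.sort_values(["rank_sum", "F1", "MCC"]).index[0]
    return scores.loc[best_idx]


def grid_search(train_set: SampleSet, grid: GridSpec,
                provider: EmbeddingProvider | None = None,
                cfg: ModelConfig | None = None, seed: int = 0,
                fraction: float = 0.8) -> tuple[ModelConfig, pd.DataFrame]:
    """Evaluate every grid combination on an internal validation split."""
    cfg = cfg or ModelConfig()
    tr, va = split_dataset(train_set, SplitSpec(fraction_first=fraction, seed=seed))
    rows = []
    for epochs, d_inc, d_oth in grid.combinations():
        cand = replace(cfg, epochs=epochs, dropout_inception=d_inc, dropout_other=d_oth)
        report = evaluate(train(tr, provider, cand, seed=seed), va, provider)
        rows.append({"epochs": epochs, "dropout_inception": d_inc,
                     "dropout_other": d_oth,
                     **{m: getattr(report, m) for m in METRIC_NAMES}})
    scores = pd.DataFrame(rows)
    best = select_best(scores)
    best_cfg = replace(cfg, epochs=int(best["epochs"]),
                       dropout_inception=float(best["dropout_inception"]),
                       dropout_other=float(best["dropout_other"]))
    scores.attrs["manifest"] = {"protocol": "grid_search", "seed": seed,
                                "fraction": fraction, "base_config": cfg.to_json()}
    return best_cfg, scores


def wilcoxon_compare(scores_a: np.ndarray, scores_b: np.ndarray) -> dict:
    """Two-sided paired Wilcoxon signed-rank test (zero differences dropped).

    Returns p-value, the direction of the median paired difference, and a
    degenerate flag when every pair is tied (p reported as 1).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors of equal length required")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    diff = a - b
    if np.all(diff == 0):
        return {"p_value": 1.0, "direction": "equal", "degenerate": True}
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    med = float(np.median(diff[diff != 0]))
    direction = "a>b" if med > 0 else ("a<b" if med < 0 else "equal")
    return {"p_value": float(res.pvalue), "direction": direction, "degenerate": False}


def friedman_across_folds(fold_metrics: np.ndarray) -> dict:
    """Friedman rank test over a (folds x conditions) score matrix."""
    m = np.asarray(fold_metrics, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a (folds >= 2) x (conditions >= 2) matrix")
    if np.all(m == m[:, [0]]):  # constant ranks: no treatment effect
        return {"statistic": 0.0, "p_value": 1.0, "degenerate": True}
    stat, p = stats.friedmanchisquare(*[m[:, j] for j in range(m.shape[1])])
    return {"statistic": float(stat), "p_value": float(p), "degenerate": False}
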