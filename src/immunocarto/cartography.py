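"""Sentinel reference cartography and back-projection diagnosis.

The cartography is a fitted reference built from sentinel biopsies:
their normalized expression restricted to module genes (or the full
panel), per-gene z-score parameters, a complete-linkage dendrogram on
1 − Pearson correlation between samples, and a 2-D embedding.  Query
samples are diagnosed by z-scoring with the sentinel parameters,
projecting into the fitted embedding, and majority vote among the k
nearest sentinels; a fully deterministic high-dimensional
correlation-distance k-NN route is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics import fowlkes_mallows_score

from .discover import ModuleSet
from .exceptions import ConfigurationError, DataError, StatisticsError
from .normalize import NormalizedMatrix


@dataclass
class Cartography:
    """Fitted sentinel reference map."""

    zmatrix: pd.DataFrame          # sentinels × genes, z-scored
    labels: pd.Series              # sentinel -> disease
    genes: list[str]
    gene_mean: pd.Series
    gene_sd: pd.Series
    dendrogram: np.ndarray         # scipy linkage matrix
    embedding: np.ndarray | None   # sentinels × 2
    reducer: object | None = None  # fitted umap model
    seed: int = 0
    n_neighbors: int = 15
    expected_module: dict = field(default_factory=dict)

    @property
    def diseases(self) -> list[str]:
        return sorted(self.labels.unique())


def build_cartography(
    norm: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    modules: ModuleSet | None = None,
    gene_set: str = "module",
    seed: int = 0,
    n_neighbors: int = 15,
    use_embedding: bool = True,
    expected_module: dict | None = None,
) -> Cartography:
    """Fit the sentinel reference from normalized log2 expression.

    gene_set ``"module"`` restricts to module genes (requires
    ``modules``); ``"all"`` uses the full endogenous panel.  Constant
    genes (zero sentinel SD) are dropped with a warning.  The embedding
    is deterministic for a fixed seed.
    """
    data = norm.data if isinstance(norm, NormalizedMatrix) else norm
    labels = labels.reindex(data.index)
    if labels.isna().any():
        raise DataError("every sentinel needs a disease label")
    if labels.nunique() < 2:
        raise ConfigurationError("cartography needs at least 2 diseases")
    counts = labels.value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ConfigurationError(f"need >= 3 sentinels per disease; too few for {small}")
    if gene_set == "module":
        if modules is None:
            raise ConfigurationError("gene_set='module' requires a ModuleSet")
        modules.validate_against(data)
        genes = [g for g in modules.all_genes]
    elif gene_set == "all":
        genes = list(data.columns)
    else:
        raise ConfigurationError(f"unknown gene_set {gene_set!r}")

    sub = data[genes]
    mean, sd = sub.mean(axis=0), sub.std(axis=0, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} constant gene(s) from cartography",
            stacklevel=2,
        )
        genes = [g for g in genes if g not in set(constant)]
        sub, mean, sd = sub[genes], mean[genes], sd[genes]
    z = (sub - mean) / sd

    dend = linkage(pdist(z.to_numpy(), metric="correlation"), method="complete")
    embedding, reducer = None, None
    if use_embedding:
        import umap  # deferred: heavy import

        nn = min(n_neighbors, len(z) - 1)
        reducer = umap.UMAP(
            n_components=2, n_neighbors=nn, random_state=seed, n_jobs=1
        )
        embedding = reducer.fit_transform(z.to_numpy())
    return Cartography(
        zmatrix=z,
        labels=labels,
        genes=genes,
        gene_mean=mean,
        gene_sd=sd,
        dendrogram=dend,
        embedding=embedding,
        reducer=reducer,
        seed=seed,
        n_neighbors=n_neighbors,
        expected_module=dict(expected_module or {}),
    )


@dataclass
class DiagnosisResult:
    """Back-projection diagnosis of one query sample."""

    assigned: str
    votes: dict[str, int]
    mean_distance: dict[str, float]
    dominant_module: str | None = None
    concordant: bool | None = None


def _zscore_query(carto: Cartography, profile: pd.Series) -> np.ndarray:
    missing = [g for g in carto.genes if g not in profile.index]
    if missing:
        raise DataError(f"query sample missing cartography genes: {missing[:10]}")
    vals = profile[carto.genes].astype(float)
    return ((vals - carto.gene_mean) / carto.gene_sd).to_numpy()


def classify_sample(
    carto: Cartography,
    profile: pd.Series,
    k: int = 5,
    method: str = "embedding",
    dominant_module: str | None = None,
) -> DiagnosisResult:
    """Assign a query sample to the majority disease of its k nearest
    sentinels (ties broken by smallest mean distance to the tied
    diseases' nearest sentinels).

    method ``"embedding"`` projects into the fitted embedding (default);
    ``"pearson"`` votes directly on 1 − Pearson distance in z-space.
    """
    name = profile.name if profile.name is not None else "query"
    frame = pd.DataFrame([profile.to_numpy()], index=[name], columns=profile.index)
    result = classify_table(
        carto, frame, k=k, method=method,
        dominant_modules={name: dominant_module} if dominant_module else None,
    )
    return next(iter(result.values()))


def classify_table(
    carto: Cartography,
    profiles: pd.DataFrame,
    k: int = 5,
    method: str = "embedding",
    dominant_modules: dict[str, str] | None = None,
) -> dict[str, DiagnosisResult]:
    """Classify every row of a queries × genes matrix (batch transform)."""
    if k > len(carto.zmatrix):
        raise ConfigurationError(f"k={k} exceeds sentinel count {len(carto.zmatrix)}")
    zq = np.vstack([_zscore_query(carto, profiles.loc[sid]) for sid in profiles.index])
    if method == "embedding":
        if carto.reducer is None:
            raise ConfigurationError("cartography was built without an embedding")
        q = carto.reducer.transform(zq)
        dmat = cdist(q, carto.embedding, metric="euclidean")
    elif method == "pearson":
        dmat = cdist(zq, carto.zmatrix.to_numpy(), metric="correlation")
    else:
        raise ConfigurationError(f"unknown classification method {method!r}")

    results: dict[str, DiagnosisResult] = {}
    for row, sid in enumerate(profiles.index):
        dists = dmat[row]
        nn = np.argsort(dists, kind="stable")[:k]
        votes = carto.labels.iloc[nn].value_counts().to_dict()
        mean_dist = {
            d: float(dists[(carto.labels == d).to_numpy()].mean())
            for d in carto.diseases
        }
        top = max(votes.values())
        tied = [d for d, v in votes.items() if v == top]
        assigned = tied[0] if len(tied) == 1 else min(tied, key=lambda d: mean_dist[d])
        dominant = (dominant_modules or {}).get(sid)
        concordant = None
        if dominant is not None and carto.expected_module:
            expected = carto.expected_module.get(assigned)
            concordant = expected is not None and expected == dominant
        results[str(sid)] = DiagnosisResult(
            assigned=assigned,
            votes={d: int(votes.get(d, 0)) for d in carto.diseases},
            mean_distance=mean_dist,
            dominant_module=dominant,
            concordant=concordant,
        )
    return results


def sentinel_cluster_diagnosis(carto: Cartography, k: int | None = None) -> pd.Series:
    """Diagnose sentinels by cutting their own dendrogram at k clusters
    and mapping clusters to diseases by optimal (Hungarian) assignment."""
    if k is None:
        k = len(carto.diseases)
    clusters = fcluster(carto.dendrogram, t=k, criterion="maxclust")
    mapping = _hungarian_cluster_map(clusters, carto.labels)
    return pd.Series(
        [mapping.get(c, f"cluster{c}") for c in clusters], index=carto.labels.index
    )


def _hungarian_cluster_map(clusters: np.ndarray, labels: pd.Series) -> dict[int, str]:
    tab = pd.crosstab(pd.Series(clusters, index=labels.index), labels)
    row_idx, col_idx = linear_sum_assignment(-tab.to_numpy())
    return {int(tab.index[r]): str(tab.columns[c]) for r, c in zip(row_idx, col_idx)}


def class_metrics(predicted: Sequence, true: Sequence) -> pd.DataFrame:
    """One-vs-rest precision, recall and specificity per class."""
    predicted, true = list(predicted), list(true)
    if len(predicted) != len(true):
        raise DataError("predicted and true label vectors differ in length")
    classes = sorted(set(true) | set(predicted))
    rows = {}
    for c in classes:
        tp = sum(p == c and t == c for p, t in zip(predicted, true))
        fp = sum(p == c and t != c for p, t in zip(predicted, true))
        fn = sum(p != c and t == c for p, t in zip(predicted, true))
        tn = len(true) - tp - fp - fn
        rows[c] = {
            "precision": tp / (tp + fp) if tp + fp else np.nan,
            "recall": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def fm_index(partition1: Sequence, partition2: Sequence) -> float:
    """Pairwise Fowlkes–Mallows index: TP / sqrt((TP+FP)(TP+FN)) over
    all sample pairs, symmetric and invariant to label renaming."""
    if len(partition1) != len(partition2):
        raise DataError("partitions differ in length")
    if len(partition1) < 2:
        raise StatisticsError("FM index needs at least 2 samples")
    enc = lambda p: pd.factorize(np.asarray(p, dtype=object))[0]
    return float(fowlkes_mallows_score(enc(partition1), enc(partition2)))
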