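"""Protocol-comparison and single-cell statistics.

Quantification accuracy against an equimolar spike-in pool is summarised
as the coefficient of variation (CV) of per-sample expression: under a
perfectly unbiased protocol every spike-in has identical RPMM, so CV
measures the departure from the equimolar truth. Reproducibility is the
Euclidean distance between samples on log2 expression, split into
within-protocol and between-protocol pairs. The single-cell stage adds
molecule-based cell QC, library-size log-normalization, variance-
stabilizing variable-feature selection, PCA -> SNN -> Louvain clustering
with a UMAP embedding, and adjusted mutual information between cluster
and external labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import igraph
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_mutual_info_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .refio import ReferenceSet

logger = logging.getLogger(__name__)


def coefficient_of_variation(
    expression: pd.Series,
    all_feature_ids: Sequence[str] | None = None,
    detected_only: bool = False,
) -> float:
    """Sample standard deviation / mean of one sample's spike-in expression.

    By default the CV runs over every reference feature with zeros
    included — the equimolar truth expects every feature present, so a
    dropout is a real deviation. ``detected_only=True`` restricts to
    features with nonzero expression (the alternative convention for
    absolute CV values).
    """
    values = expression
    if all_feature_ids is not None:
        values = expression.reindex(list(all_feature_ids), fill_value=0.0)
    if detected_only:
        values = values[values > 0]
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError("CV requires at least two features")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined: mean expression is zero")
    return float(arr.std(ddof=1) / mean)


def reproducibility_distances(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pairwise Euclidean distances on log2(value + pseudocount).

    Each unordered sample pair appears once, labelled ``within`` when both
    samples share a protocol group and ``between`` otherwise.
    """
    unknown = [s for s in matrix.columns if s not in groups]
    if unknown:
        raise ValueError(f"samples without a group label: {unknown}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    logm = np.log2(matrix.astype(float) + pseudocount)
    rows = []
    for a, b in combinations(matrix.columns, 2):
        d = float(np.linalg.norm(logm[a].to_numpy() - logm[b].to_numpy()))
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "group_a": groups[a],
                "group_b": groups[b],
                "kind": "within" if groups[a] == groups[b] else "between",
                "distance": d,
            }
        )
    return pd.DataFrame(rows)


def gcontent_detection_association(
    refs: ReferenceSet, detection_rates: pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation of per-feature detection rate against
    G-content (average ranks on ties, large-sample p value).

    A positive rho reproduces the ligation-bias signature: G-richer
    sequences are captured, hence detected, more often. Constant input
    yields (nan, nan).
    """
    g = refs.g_content_series()
    rates = detection_rates.reindex(g.index)
    if len(g) < 10:
        raise ValueError("need at least 10 features")
    if rates.nunique() <= 1 or g.nunique() <= 1:
        logger.warning("constant vector: Spearman rho undefined")
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(g.to_numpy(), rates.to_numpy())
    return float(rho), float(p)


def filter_cells(molecule_totals: pd.Series, min_molecules: int = 50) -> list[str]:
    """Keep cells with at least ``min_molecules`` detected molecules
    (default 50, the miRNA-molecule floor separating cells from
    reagent-only negative controls)."""
    if min_molecules < 0:
        raise ValueError("min_molecules must be >= 0")
    kept = [str(s) for s, v in molecule_totals.items() if v >= min_molecules]
    if not kept:
        warnings.warn("no cells pass the molecule threshold")
    return kept


def lognormalize(raw: pd.DataFrame, scale: float = 10_000.0) -> pd.DataFrame:
    """Library-size normalization to ``scale`` counts followed by ln(1+x)
    (the standard single-cell log-normalization; natural log)."""
    sums = raw.sum(axis=0)
    zero = sums == 0
    if zero.any():
        logger.warning("zero-library columns zeroed: %s", list(sums.index[zero]))
    safe = sums.replace(0, np.nan)
    return np.log1p(raw.astype(float) * scale / safe).fillna(0.0)


def variable_features(raw: pd.DataFrame, n: int = 2000, span: float = 0.3) -> list[str]:
    """Rank features by variance-stabilized variance (the "vst" recipe).

    Fits expected log10 variance as a lowess function of log10 mean over
    features, standardizes raw counts by the predicted standard deviation
    with values clipped at sqrt(n_samples), and ranks features by the
    variance of the standardized values. Returns the top ``n`` feature ids.
    """
    X = raw.astype(float)
    n_samples = X.shape[1]
    means = X.mean(axis=1)
    variances = X.var(axis=1, ddof=1)
    usable = variances > 0
    if usable.sum() < n:
        warnings.warn(
            f"only {int(usable.sum())} features with nonzero variance; returning all"
        )
    std_var = pd.Series(0.0, index=X.index)
    if usable.any():
        logm = np.log10(means[usable])
        logv = np.log10(variances[usable])
        fitted = lowess(
            logv.to_numpy(),
            logm.to_numpy(),
            frac=span,
            return_sorted=False,
        )
        exp_sd = pd.Series(np.sqrt(10.0**fitted), index=logm.index)
        clip = np.sqrt(n_samples)
        Z = X.loc[usable.index[usable]].sub(means[usable], axis=0).div(exp_sd, axis=0)
        Z = Z.clip(upper=clip, lower=-clip)
        std_var.loc[Z.index] = Z.var(axis=1, ddof=1)
    ranked = std_var.sort_values(ascending=False, kind="stable")
    return list(ranked.index[: min(n, len(ranked))])


@dataclass
class ClusterConfig:
    """Embedding/clustering settings (single-cell defaults: 15 PCs, SNN
    k=20 Jaccard-weighted, Louvain resolution 1.4, UMAP 15 neighbours)."""

    n_variable_features: int = 2000
    n_pcs: int = 15
    umap_neighbors: int = 15
    louvain_resolution: float = 1.4
    snn_k: int = 20
    seed: int = 0

    def validated(self, n_samples: int, n_features: int) -> "ClusterConfig":
        n_pcs = min(self.n_pcs, min(n_features, n_samples) - 1)
        snn_k = min(self.snn_k, n_samples - 1)
        umap_neighbors = min(self.umap_neighbors, n_samples - 1)
        if n_pcs < 1:
            raise ValueError("too few samples for PCA")
        return ClusterConfig(
            self.n_variable_features,
            n_pcs,
            umap_neighbors,
            self.louvain_resolution,
            snn_k,
            self.seed,
        )


def snn_graph(pcs: np.ndarray, k: int) -> igraph.Graph:
    """Shared-nearest-neighbour graph: k nearest neighbours (self
    included) in PC space, edges weighted by the Jaccard overlap of
    neighbourhoods; zero-overlap edges are dropped."""
    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k, n)).fit(pcs)
    _d, idx = nn.kneighbors(pcs)
    sets = [set(row) for row in idx]
    edges, weights = [], []
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            if shared:
                union = len(sets[i] | sets[j])
                edges.append((i, j))
                weights.append(shared / union)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def embed_and_cluster(
    normalized: pd.DataFrame, cfg: ClusterConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """PCA on variable features -> SNN graph -> Louvain communities;
    UMAP on the same PCs for a 2-D embedding. Deterministic given
    ``cfg.seed``.

    ``normalized`` is features x samples (log-normalized); returns UMAP
    coordinates (samples x 2) and integer cluster labels per sample.
    """
    import umap  # deferred: slow import

    n_features, n_samples = normalized.shape
    if n_samples < 3:
        raise ValueError("too few samples to embed and cluster (need >= 3)")
    cfg = cfg.validated(n_samples, n_features)
    if n_samples < cfg.n_pcs + 1:
        raise ValueError("too few samples for the requested number of PCs")
    X = normalized.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    pca = PCA(n_components=cfg.n_pcs, svd_solver="full", random_state=cfg.seed)
    pcs = pca.fit_transform(X)
    # fix component signs by the largest-magnitude loading so PCA output
    # is invariant to feature order
    anchor = np.abs(pca.components_).argmax(axis=1)
    signs = np.sign(pca.components_[np.arange(pca.components_.shape[0]), anchor])
    signs[signs == 0] = 1.0
    pcs = pcs * signs
    g = snn_graph(pcs, cfg.snn_k)
    part = g.community_multilevel(
        weights=g.es["weight"] if g.ecount() else None,
        resolution=cfg.louvain_resolution,
    )
    labels = pd.Series(part.membership, index=normalized.columns, name="cluster")
    reducer = umap.UMAP(
        n_neighbors=max(2, cfg.umap_neighbors),
        n_components=2,
        random_state=cfg.seed,
        min_dist=0.1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(pcs)
    embedding = pd.DataFrame(
        coords, index=normalized.columns, columns=["umap1", "umap2"]
    )
    return embedding, labels


def adjusted_mutual_information(
    labels_a: Sequence, labels_b: Sequence
) -> float:
    """Chance-corrected agreement between two labelings (arithmetic-mean
    normalization); 1 for identical partitions, ~0 for independent ones."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    return float(adjusted_mutual_info_score(list(labels_a), list(labels_b)))


@dataclass
class MetricsReport:
    """Aggregated per-run metrics (JSON/TSV-serialisable)."""

    cv_per_sample: dict[str, float] = field(default_factory=dict)
    distances: pd.DataFrame | None = None
    detected_per_sample: dict[str, int] = field(default_factory=dict)
    gcontent_rho: float = float("nan")
    gcontent_p: float = float("nan")
    cells_passing_qc: list[str] = field(default_factory=list)
    reads_per_umi_mean: float = float("nan")
    reads_per_umi_sd: float = float("nan")

    def to_json_dict(self) -> dict:
        out = {
            "cv_per_sample": self.cv_per_sample,
            "detected_per_sample": self.detected_per_sample,
            "gcontent_rho": self.gcontent_rho,
            "gcontent_p": self.gcontent_p,
            "cells_passing_qc": self.cells_passing_qc,
            "reads_per_umi_mean": self.reads_per_umi_mean,
            "reads_per_umi_sd": self.reads_per_umi_sd,
        }
        if self.distances is not None:
            out["median_within"] = float(
                self.distances.query("kind == 'within'")["distance"].median()
            )
            out["median_between"] = float(
                self.distances.query("kind == 'between'")["distance"].median()
            )
        return out
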