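"""Fitness-profile clustering and pathway over-representation.

Genes with significant fitness effects are grouped by hierarchical
agglomerative clustering (Ward linkage on Euclidean distances between
per-condition fitness profiles); the number of clusters is chosen by
maximizing mean silhouette width over a scanned range, ties going to the
smaller k. Clusters are then tested for pathway over-representation with
a one-sided hypergeometric test on a generic (gene, pathway) annotation
table — no database access required.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = [
    "cluster", "pathway", "overlap", "cluster_size", "pathway_size",
    "universe_size", "p_value", "p_adjust_bh",
]


@dataclass
class ClusterResult:
    """Cluster assignments with the silhouette scan that selected k."""

    assignments: pd.Series  # gene -> cluster id in 1..k
    k: int
    silhouette_by_k: dict[int, float]
    linkage: str

    def members(self, cluster_id: int) -> list[str]:
        return self.assignments.index[self.assignments == cluster_id].tolist()


def cluster_genes(
    fitness_matrix: pd.DataFrame,
    k_range: Iterable[int] = range(2, 13),
    method: str = "ward",
) -> ClusterResult:
    """Cluster genes by fitness-profile similarity, k chosen by silhouette.

    ``fitness_matrix`` is gene x condition; missing cells are imputed to 0
    (neutral — a missing score means the gene was not scored there) with
    the imputed count logged. Requires at least 3 genes and non-identical
    rows (silhouette width is undefined otherwise).
    """
    X = fitness_matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("clustering requires at least 3 genes")
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        logger.info("imputing %d missing fitness cells to 0 before clustering", n_missing)
        X = np.nan_to_num(X, nan=0.0)
    if pdist(X).max() == 0:
        raise ValueError("degenerate input: all fitness profiles are identical")

    Z = scipy_linkage(X, method=method)
    ks = sorted({int(k) for k in k_range if 2 <= k <= n - 1})
    if not ks:
        raise ValueError(f"k_range contains no feasible k for n={n}")
    scores: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(X, labels))
        labels_by_k[k] = labels
    if not scores:
        raise ValueError("no k in range produced >= 2 clusters")
    best_k = max(sorted(scores), key=lambda k: (scores[k], -k))
    labels = labels_by_k[best_k]
    # relabel clusters to consecutive ids in order of first appearance
    remap = {old: new for new, old in enumerate(pd.unique(labels), start=1)}
    assignments = pd.Series([remap[l] for l in labels], index=fitness_matrix.index, name="cluster")
    return ClusterResult(assignments=assignments, k=len(remap), silhouette_by_k=scores, linkage=method)


def enrich(
    clusters: Mapping[str, int] | pd.Series,
    annotation: pd.DataFrame,
    universe: Iterable[str],
    top_n: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric pathway over-representation per cluster.

    ``annotation`` has columns (gene, pathway); a gene may carry several
    pathways or none (contributing to the universe only). For each
    (cluster, pathway) pair the upper-tail p-value
    ``P(X >= overlap), X ~ Hypergeom(universe, pathway_size, cluster_size)``
    is computed. Rows are sorted by p within cluster; ``top_n`` keeps the
    best n pathways per cluster. Raw p-values are the primary ranking (a
    Benjamini-Hochberg column is provided alongside).
    """
    assignments = pd.Series(dict(clusters)) if not isinstance(clusters, pd.Series) else clusters
    universe = set(universe)
    missing = set(assignments.index) - universe
    if missing:
        raise ValueError(f"{len(missing)} clustered genes absent from universe")
    ann = annotation.rename(columns=dict(zip(annotation.columns[:2], ["gene", "pathway"])))
    ann = ann[ann["gene"].isin(universe)]
    pathway_sets = {p: set(g["gene"]) for p, g in ann.groupby("pathway")}
    M = len(universe)
    rows = []
    for cluster_id in sorted(assignments.unique()):
        members = set(assignments.index[assignments == cluster_id])
        for pathway, genes in pathway_sets.items():
            overlap = len(members & genes)
            p = float(hypergeom.sf(overlap - 1, M, len(genes), len(members)))
            rows.append((cluster_id, pathway, overlap, len(members), len(genes), M, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    if len(out):
        out["p_adjust_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values(["cluster", "p_value"], kind="stable").reset_index(drop=True)
        if top_n is not None:
            out = out.groupby("cluster", group_keys=False).head(top_n).reset_index(drop=True)
    else:
        out["p_adjust_bh"] = pd.Series(dtype=float)
    return out


def tsne_embedding(fitness_matrix: pd.DataFrame, seed: int = 0, perplexity: float = 30.0) -> pd.DataFrame:
    """Optional 2-D t-SNE embedding of fitness profiles (for plotting)."""
    from sklearn.manifold import TSNE

    X = np.nan_to_num(fitness_matrix.to_numpy(dtype=float), nan=0.0)
    perplexity = min(perplexity, max(1.0, (len(X) - 1) / 3.0))
    emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca").fit_transform(X)
    return pd.DataFrame(emb, index=fitness_matrix.index, columns=["tsne1", "tsne2"])
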