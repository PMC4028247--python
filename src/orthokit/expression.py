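"""Tissue-expression clustering of the orthologue gene set.

Representative samples (at most four per tissue) are chosen nearest to the
per-tissue median profile, averaged into a gene x tissue matrix, and
clustered with Euclidean k-means.  The working k defaults to 10, chosen
from an inertia-vs-k elbow scan over k = 1..50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .localization import ConsensusCall

DEFAULT_K = 10
DEFAULT_K_RANGE = range(1, 51)


@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series  # gene -> cluster id (0-based)
    centroids: np.ndarray
    inertia: float
    seed: int
    restarts: int


@dataclass
class RepresentativeSelection:
    """Chosen samples per tissue plus the audit dendrograms.

    ``linkages`` holds the average-linkage tree (correlation distance) for
    every tissue with more samples than the cap; emitted for inspection,
    the selection itself is nearest-to-median.
    """

    selected: dict[str, list[str]]
    linkages: dict[str, np.ndarray]

    @property
    def all_samples(self) -> list[str]:
        out: list[str] = []
        for tissue in sorted(self.selected):
            out.extend(self.selected[tissue])
        return out


def read_expression_matrix(path: str) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    return df


def read_tissue_map(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def select_representatives(
    matrix: pd.DataFrame,
    tissue_map: Mapping[str, str],
    max_n: int = 4,
) -> RepresentativeSelection:
    """Pick at most ``max_n`` representative samples per tissue.

    Tissues at or under the cap keep all samples.  Larger tissues keep the
    ``max_n`` samples closest (Euclidean) to the per-tissue median profile;
    distance ties break on sample id, so the choice is deterministic and
    invariant to column order.
    """
    unmapped = [s for s in matrix.columns if s not in tissue_map]
    if unmapped:
        raise KeyError(f"samples without tissue assignment: {unmapped}")
    tissues: dict[str, list[str]] = {}
    for sample in matrix.columns:
        tissues.setdefault(tissue_map[sample], []).append(sample)
    selected: dict[str, list[str]] = {}
    linkages: dict[str, np.ndarray] = {}
    for tissue in sorted(tissues):
        samples = sorted(tissues[tissue])
        if not samples:
            raise ValueError(f"tissue {tissue!r} has no samples")
        if len(samples) <= max_n:
            selected[tissue] = samples
            continue
        sub = matrix[samples]
        # audit output: average-linkage tree on 1 - Pearson correlation
        linkages[tissue] = linkage(pdist(sub.T.values, metric="correlation"),
                                   method="average")
        median_profile = sub.median(axis=1)
        dist = ((sub.sub(median_profile, axis=0)) ** 2).sum(axis=0) ** 0.5
        order = sorted(samples, key=lambda s: (dist[s], s))
        selected[tissue] = sorted(order[:max_n])
    return RepresentativeSelection(selected=selected, linkages=linkages)


def tissue_means(
    matrix: pd.DataFrame, selection: RepresentativeSelection
) -> pd.DataFrame:
    """Gene x tissue matrix of arithmetic means over the selected samples."""
    cols = {}
    for tissue in sorted(selection.selected):
        cols[tissue] = matrix[selection.selected[tissue]].mean(axis=1)
    return pd.DataFrame(cols)


def kmeans_fit(
    gene_tissue: pd.DataFrame,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    init: np.ndarray | None = None,
) -> ClusterModel:
    """Euclidean k-means, best of ``restarts`` k-means++ initializations.

    Deterministic given (seed, restarts).  ``init`` optionally supplies an
    extra explicit centroid seeding evaluated alongside the random
    restarts (used by the elbow scan to enforce monotone inertia).
    """
    n_genes = len(gene_tissue)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_genes:
        raise ValueError(f"k={k} exceeds the number of genes ({n_genes})")
    x = gene_tissue.values
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    km.fit(x)
    best = km
    if init is not None:
        km2 = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
        km2.fit(x)
        if km2.inertia_ < best.inertia_:
            best = km2
    return ClusterModel(
        k=k,
        assignments=pd.Series(best.labels_, index=gene_tissue.index, name="cluster"),
        centroids=best.cluster_centers_.copy(),
        inertia=float(best.inertia_),
        seed=seed,
        restarts=restarts,
    )


def elbow_scan(
    gene_tissue: pd.DataFrame,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    seed: int = 0,
    restarts: int = 10,
) -> pd.DataFrame:
    """Best-of-restarts inertia for each k; columns (k, inertia).

    The distance to the optimal solution (one gene per cluster, inertia 0)
    is the inertia itself.  Each k is additionally warm-started from the
    previous solution's centroids plus the member farthest from its
    centroid, which guarantees a non-increasing curve.
    """
    ks = sorted(set(int(k) for k in k_range))
    rows = []
    prev: ClusterModel | None = None
    x = gene_tissue.values
    for k in ks:
        if k > len(gene_tissue):
            break
        init = None
        if prev is not None and k == prev.k + 1:
            centroids = prev.centroids
            resid = x - centroids[prev.assignments.values]
            worst = int(np.argmax((resid ** 2).sum(axis=1)))
            init = np.vstack([centroids, x[worst]])
        model = kmeans_fit(gene_tissue, k, seed=seed, restarts=restarts, init=init)
        rows.append({"k": k, "inertia": model.inertia})
        prev = model
    return pd.DataFrame(rows, columns=["k", "inertia"])


def cluster_tissue_medians(
    model: ClusterModel, gene_tissue: pd.DataFrame
) -> pd.DataFrame:
    """Cluster x tissue table of medians over member genes.

    Empty clusters yield all-NaN rows.
    """
    rows = {}
    for cluster in range(model.k):
        genes = model.assignments.index[model.assignments == cluster]
        if len(genes) == 0:
            rows[cluster] = pd.Series(np.nan, index=gene_tissue.columns)
        else:
            rows[cluster] = gene_tissue.loc[genes].median(axis=0)
    return pd.DataFrame(rows).T


def localization_distribution(
    model: ClusterModel, calls: Mapping[str, ConsensusCall]
) -> pd.DataFrame:
    """Cluster x compartment counts of member genes.

    Multi-compartment consensus calls count 1/|compartments| toward each,
    so row sums equal cluster sizes.  Genes without a call (or with an
    empty call) count under "unknown".
    """
    counts: dict[int, dict[str, float]] = {c: {} for c in range(model.k)}
    for gene, cluster in model.assignments.items():
        call = calls.get(gene)
        if call is None or not call.compartments:
            counts[cluster]["unknown"] = counts[cluster].get("unknown", 0.0) + 1.0
            continue
        share = 1.0 / len(call.compartments)
        for comp in call.compartments:
            counts[cluster][comp] = counts[cluster].get(comp, 0.0) + share
    table = pd.DataFrame(counts).T.fillna(0.0)
    return table.reindex(sorted(table.columns), axis=1)
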