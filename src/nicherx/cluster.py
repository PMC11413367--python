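"""Clustering, marker annotation, gene-signature scoring, and DE statistics.

Clustering follows the standard single-cell recipe: highly variable genes by
log-space variance, PCA, a k-nearest-neighbor graph in PC space, and Leiden
or Louvain community detection at a given resolution.  Signature scoring
comes in two flavors: a binned-background control score (set mean minus a
mean over expression-matched control genes) and a deterministic rank-AUC
single-sample statistic used where a smooth per-observation enrichment score
is needed.  Differential expression is a tie-corrected Wilcoxon rank-sum of
group vs rest with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ValidationError
from .io import GeneSet, ObsMatrix, stage_rng

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    labels: np.ndarray  # dense integers from 0, one per observation
    obs_ids: list[str]
    params: dict

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.obs_ids, name="cluster")


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _require_log(matrix: ObsMatrix, op: str) -> None:
    if matrix.layer != "log_transformed":
        raise ValidationError(f"{op} requires a log_transformed layer, got {matrix.layer!r}")


def _delog(values: np.ndarray, matrix: ObsMatrix) -> np.ndarray:
    """Invert the log transform using the base recorded at normalization."""
    base = matrix.meta.get("log_base", "e")
    if base == "2":
        return np.exp2(values) - 1.0
    return np.expm1(values)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def knn_edges(points: np.ndarray, k: int) -> np.ndarray:
    """Symmetrized (union) k-nearest-neighbor edge list over row vectors."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(points))).fit(points)
    _dist, idx = nn.kneighbors(points)
    src = np.repeat(np.arange(len(points)), idx.shape[1] - 1)
    dst = idx[:, 1:].ravel()
    lo, hi = np.minimum(src, dst), np.maximum(src, dst)
    return np.unique(np.stack([lo, hi], axis=1), axis=0)


def cluster_expression(
    matrix: ObsMatrix,
    n_hvg: int = 2000,
    n_pcs: int = 30,
    k_neighbors: int = 10,
    resolution: float = 1.0,
    algorithm: str = "leiden",
    seed: int = 0,
    sample_center: bool = False,
) -> ClusterResult:
    """HVG selection, PCA, kNN graph, and community detection.

    ``sample_center`` subtracts each sample's per-gene mean before PCA — a
    light-weight robustness option in place of dedicated batch integration
    (the synthetic data is batch-free).
    """
    _require_log(matrix, "cluster_expression")
    if algorithm not in ("leiden", "louvain"):
        raise ConfigError(f"unknown clustering algorithm {algorithm!r}")
    if matrix.n_obs < n_pcs:
        raise ValidationError(
            f"cannot compute {n_pcs} PCs from {matrix.n_obs} observations"
        )
    X = matrix.dense().T  # obs x genes
    if sample_center:
        samples = matrix.obs_meta["sample_id"].to_numpy()
        for s in pd.unique(samples):
            mask = samples == s
            X[mask] -= X[mask].mean(axis=0, keepdims=True)
    if n_hvg < X.shape[1]:
        variances = X.var(axis=0)
        hvg = np.sort(np.argsort(variances)[::-1][:n_hvg])
        X = X[:, hvg]
    n_comp = min(n_pcs, X.shape[1], X.shape[0])
    pcs = PCA(n_components=n_comp, random_state=seed, svd_solver="randomized").fit_transform(X)
    edges = knn_edges(pcs, k_neighbors)
    graph = igraph.Graph(n=matrix.n_obs, edges=[tuple(e) for e in edges])
    if algorithm == "leiden":
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=int(seed),
        )
        labels = np.array(part.membership)
    else:
        _pyrandom.seed(int(seed))
        labels = np.array(
            graph.community_multilevel(resolution=resolution).membership
        )
    labels = _relabel_by_size(labels)
    params = {
        "n_hvg": n_hvg,
        "n_pcs": n_pcs,
        "k_neighbors": k_neighbors,
        "resolution": resolution,
        "algorithm": algorithm,
        "seed": seed,
        "sample_center": sample_center,
    }
    return ClusterResult(labels=labels, obs_ids=list(matrix.obs_ids), params=params)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters as dense integers, largest cluster first."""
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[l] for l in labels], dtype=int)


def annotate_by_markers(
    matrix: ObsMatrix, clusters: ClusterResult, panels: list[GeneSet]
) -> dict[int, str]:
    """Assign each cluster the marker panel with the highest mean z-scored mean.

    For each gene, cluster means are z-scored across clusters; a panel's score
    for a cluster is the mean over its present genes; the argmax panel names
    the cluster.  Ties break by panel order with a warning.
    """
    _require_log(matrix, "annotate_by_markers")
    if not panels:
        raise ConfigError("no marker panels supplied")
    X = matrix.dense()
    labels = clusters.labels
    cluster_ids = np.unique(labels)
    cluster_means = np.stack(
        [X[:, labels == c].mean(axis=1) for c in cluster_ids], axis=1
    )  # genes x clusters
    mu = cluster_means.mean(axis=1, keepdims=True)
    sd = cluster_means.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (cluster_means - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    panel_scores = []
    kept_panels = []
    for panel in panels:
        idx = matrix.gene_index(panel.genes)
        if idx.size == 0:
            logger.warning("marker panel %s has no genes in the matrix; skipped", panel.name)
            continue
        kept_panels.append(panel.name)
        panel_scores.append(z[idx, :].mean(axis=0))
    if not kept_panels:
        raise ConfigError("no marker panel has genes present in the matrix")
    scores = np.stack(panel_scores, axis=0)  # panels x clusters

    annotation: dict[int, str] = {}
    for j, c in enumerate(cluster_ids):
        col = scores[:, j]
        best = int(np.argmax(col))
        if np.sum(col == col[best]) > 1:
            logger.warning("cluster %d: tied panel scores, keeping first panel in order", c)
        annotation[int(c)] = kept_panels[best]
    return annotation


# ---------------------------------------------------------------------------
# gene-set scoring
# ---------------------------------------------------------------------------


def score_gene_set(
    matrix: ObsMatrix,
    gene_set: GeneSet,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Binned-background signature score per observation.

    Genes are binned into ``n_bins`` by mean expression; each set gene draws
    ``ctrl_size`` control genes (without replacement, excluding set genes)
    from its own bin; the score is mean(set genes) - mean(pooled controls).
    Adding a constant to every gene therefore cancels out.
    """
    _require_log(matrix, "score_gene_set")
    X = matrix.dense()
    set_idx = matrix.gene_index(gene_set.genes)
    if set_idx.size == 0:
        raise ValidationError(f"no gene of set {gene_set.name!r} present in the matrix")
    rng = stage_rng(seed, f"score_gene_set:{gene_set.name}")

    gene_means = X.mean(axis=1)
    order = np.argsort(gene_means, kind="stable")
    bin_of = np.empty(matrix.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b

    set_mask = np.zeros(matrix.n_genes, dtype=bool)
    set_mask[set_idx] = True
    control: list[np.ndarray] = []
    for b in np.unique(bin_of[set_idx]):
        pool = np.flatnonzero((bin_of == b) & ~set_mask)
        n_in_bin = int((bin_of[set_idx] == b).sum())
        want = min(ctrl_size * n_in_bin, pool.size)
        if want < ctrl_size * n_in_bin:
            logger.debug("bin %d: only %d control genes available", b, pool.size)
        if want:
            control.append(rng.choice(pool, size=want, replace=False))
    ctrl_idx = np.concatenate(control) if control else np.array([], dtype=int)

    set_mean = X[set_idx, :].mean(axis=0)
    ctrl_mean = X[ctrl_idx, :].mean(axis=0) if ctrl_idx.size else np.zeros(matrix.n_obs)
    return pd.Series(set_mean - ctrl_mean, index=matrix.obs_ids, name=gene_set.name)


def score_gene_set_rank(matrix: ObsMatrix, gene_set: GeneSet) -> pd.Series:
    """Rank-AUC single-sample enrichment score, ES in [-1, 1].

    Per observation, ES = 2U/(m(n-m)) - 1 where U is the Mann-Whitney
    statistic of set-gene expression ranks against all other genes (average
    ranks on ties).  Invariant to any monotone transform of an observation's
    expression vector; ES = 1 when the set genes are exactly the top-m.
    """
    _require_log(matrix, "score_gene_set_rank")
    set_idx = matrix.gene_index(gene_set.genes)
    m = set_idx.size
    n = matrix.n_genes
    if m == 0:
        raise ValidationError(f"no gene of set {gene_set.name!r} present in the matrix")
    if m >= n:
        raise ValidationError(f"set {gene_set.name!r} covers every gene; ES undefined")
    X = matrix.dense()
    ranks = scipy.stats.rankdata(X, axis=0)  # per observation, over genes
    rank_sum = ranks[set_idx, :].sum(axis=0)
    u = rank_sum - m * (m + 1) / 2.0
    es = 2.0 * u / (m * (n - m)) - 1.0
    return pd.Series(es, index=matrix.obs_ids, name=gene_set.name)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def rank_genes_wilcoxon(
    matrix: ObsMatrix,
    groups: pd.Series | np.ndarray,
    min_group_size: int = 3,
    exact: bool = False,
    epsilon: float = 1e-9,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE of each group vs the rest, per feature.

    Default is the tie-corrected normal approximation; ``exact=True`` uses the
    exact Mann-Whitney null (suitable for tiny groups).  Fold changes are
    computed on de-logged normalized means, log2((m_in+eps)/(m_out+eps)).
    BH adjustment is applied across features within each group.
    """
    _require_log(matrix, "rank_genes_wilcoxon")
    groups = pd.Series(np.asarray(groups), index=matrix.obs_ids)
    group_names = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(group_names) < 2:
        raise ValidationError("rank_genes_wilcoxon needs at least two groups")

    X = matrix.dense()
    linear = _delog(X, matrix)
    n = matrix.n_obs
    ranks = scipy.stats.rankdata(X, axis=1)
    # tie correction term per feature: sum over tied groups of t^3 - t
    tie_term = np.zeros(matrix.n_genes)
    for i in range(matrix.n_genes):
        _vals, counts = np.unique(X[i], return_counts=True)
        tied = counts[counts > 1]
        if tied.size:
            tie_term[i] = float(np.sum(tied.astype(float) ** 3 - tied))

    out = []
    for g in group_names:
        mask = (groups == g).to_numpy()
        n1 = int(mask.sum())
        n2 = n - n1
        if n1 < min_group_size or n2 < 1:
            logger.warning("group %r below min size %d; skipped", g, min_group_size)
            continue
        mean_in = linear[:, mask].mean(axis=1)
        mean_out = linear[:, ~mask].mean(axis=1)
        log2fc = np.log2((mean_in + epsilon) / (mean_out + epsilon))
        if exact:
            pvals = np.array(
                [
                    scipy.stats.mannwhitneyu(
                        X[i, mask], X[i, ~mask], alternative="two-sided", method="exact"
                    ).pvalue
                    for i in range(matrix.n_genes)
                ]
            )
        else:
            r1 = ranks[:, mask].sum(axis=1)
            u = r1 - n1 * (n1 + 1) / 2.0
            mu = n1 * n2 / 2.0
            var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
            sd = np.sqrt(np.maximum(var, 0.0))
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(sd > 0, (u - mu) / np.where(sd > 0, sd, 1.0), 0.0)
            pvals = 2.0 * scipy.stats.norm.sf(np.abs(z))
            pvals = np.minimum(pvals, 1.0)
        padj = bh_adjust(pvals)
        frame = pd.DataFrame(
            {
                "feature": matrix.gene_ids,
                "group": g,
                "mean_in": mean_in,
                "mean_out": mean_out,
                "log2fc": log2fc,
                "p_value": pvals,
                "p_adjusted": padj,
            }
        )
        frame["rank"] = (
            frame["p_adjusted"].rank(method="first").astype(int)
        )
        out.append(frame)
    if not out:
        raise ValidationError("no group met the minimum size requirement")
    return pd.concat(out, ignore_index=True)


def significant_genes(
    de: pd.DataFrame, group: str, padj_cutoff: float = 0.05, lfc_cutoff: float = 0.25
) -> list[str]:
    """Features passing the adjusted-p and log2 fold-change cutoffs for a group."""
    sub = de[(de["group"] == group)]
    hit = sub[(sub["p_adjusted"] < padj_cutoff) & (sub["log2fc"] > lfc_cutoff)]
    return hit["feature"].tolist()


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------


def over_representation_test(
    hit_genes: list[str], gene_sets: list[GeneSet], universe: list[str]
) -> pd.DataFrame:
    """Right-tailed hypergeometric over-representation of hits in each set.

    p = P(overlap >= observed) with BH adjustment across the tested sets.
    """
    if not universe:
        raise ValidationError("empty universe")
    uni = set(universe)
    hits = set(hit_genes)
    if not hits <= uni:
        raise ValidationError("hit_genes must be a subset of the universe")
    M, n_hits = len(uni), len(hits)
    rows = []
    for gs in gene_sets:
        members = set(gs.genes) & uni
        overlap = len(members & hits)
        p = scipy.stats.hypergeom.sf(overlap - 1, M, len(members), n_hits)
        rows.append({"set": gs.name, "set_size": len(members), "overlap": overlap, "p_value": p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    return table
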