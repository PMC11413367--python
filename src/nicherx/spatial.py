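"""Spatial graphs and permutation neighborhood enrichment.

Per-sample spot graphs (k nearest Euclidean neighbors, symmetrized) are
merged into one multi-component graph with no inter-sample edges.  Label
neighborhood enrichment compares the observed number of edges joining two
compartment labels against a null in which labels are permuted uniformly —
by default within each sample, the only null that respects per-sample label
composition on a merged graph — and reports a permutation z-score per label
pair.  The proximity-graph export clips negative z-scores to zero and scales
the remaining weights by 0.25, dropping zero-weight edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import SpotCoordinates, stage_rng
from .cluster import knn_edges

logger = logging.getLogger(__name__)


@dataclass
class SpatialGraph:
    """Merged multi-sample spot adjacency (undirected, no cross-sample edges)."""

    obs_ids: list[str]
    sample_ids: np.ndarray  # per-node sample
    edges: np.ndarray  # (n_edges, 2) int array, lo < hi, unique

    def __post_init__(self) -> None:
        if self.edges.size:
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValidationError("spatial graph contains self-loops")
            if np.any(self.sample_ids[self.edges[:, 0]] != self.sample_ids[self.edges[:, 1]]):
                raise ValidationError("spatial graph contains inter-sample edges")
            if len(np.unique(self.edges, axis=0)) != len(self.edges):
                raise ValidationError("spatial graph contains duplicate edges")

    @property
    def n_nodes(self) -> int:
        return len(self.obs_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class EnrichmentMatrix:
    """Observed pair counts, permutation mean/sd, and z per label pair."""

    labels: list[str]
    observed: np.ndarray  # labels x labels, symmetric edge counts
    perm_mean: np.ndarray
    perm_sd: np.ndarray
    zscores: np.ndarray  # NaN where sd == 0
    n_permutations: int
    seed: int

    def z_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.zscores, index=self.labels, columns=self.labels)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if j < i:
                    continue
                rows.append(
                    {
                        "label_a": a,
                        "label_b": b,
                        "observed": self.observed[i, j],
                        "perm_mean": self.perm_mean[i, j],
                        "perm_sd": self.perm_sd[i, j],
                        "z": self.zscores[i, j],
                    }
                )
        return pd.DataFrame(rows)


def build_knn_graph(coords: SpotCoordinates, k: int = 6) -> SpatialGraph:
    """Per-sample k-nearest-neighbor graphs merged without inter-sample edges.

    k = 6 is the native packing of a hex spot grid.  Each sample needs at
    least k + 1 spots.
    """
    table = coords.table.reset_index(drop=True)
    obs_ids = table["obs_id"].tolist()
    sample_ids = table["sample_id"].to_numpy()
    all_edges = []
    for sample in pd.unique(sample_ids):
        idx = np.flatnonzero(sample_ids == sample)
        if idx.size <= k:
            raise ValidationError(
                f"sample {sample!r} has {idx.size} spots; need more than k={k}"
            )
        pts = table.loc[idx, ["x", "y"]].to_numpy(dtype=float)
        local = knn_edges(pts, k)
        all_edges.append(idx[local])
    edges = (
        np.unique(np.vstack(all_edges), axis=0) if all_edges else np.empty((0, 2), dtype=int)
    )
    return SpatialGraph(obs_ids=obs_ids, sample_ids=sample_ids, edges=edges)


def _pair_counts(
    edge_labels_a: np.ndarray, edge_labels_b: np.ndarray, n_labels: int
) -> np.ndarray:
    """Symmetric label-pair edge counts; same-label edges counted once."""
    counts = np.zeros((n_labels, n_labels))
    lo = np.minimum(edge_labels_a, edge_labels_b)
    hi = np.maximum(edge_labels_a, edge_labels_b)
    np.add.at(counts, (lo, hi), 1.0)
    return counts + np.triu(counts, 1).T


def nhood_enrichment(
    graph: SpatialGraph,
    labels: pd.Series | np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    stratify_by_sample: bool = True,
) -> EnrichmentMatrix:
    """Permutation z-scores for label co-adjacency on the spatial graph.

    O_ab counts edges whose endpoints carry labels {a, b}; the null permutes
    labels uniformly (within each sample when ``stratify_by_sample``).  Cells
    with zero permutation sd get z = NaN and are flagged in the export.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(graph.obs_ids).to_numpy()
    labels = np.asarray(labels)
    if pd.isna(labels).any():
        raise ValidationError("every node must be labeled")
    label_names = sorted(pd.unique(labels).tolist())
    if len(label_names) < 2:
        raise ValidationError("nhood_enrichment needs at least two labels")
    codes = np.array([label_names.index(l) for l in labels])
    n_labels = len(label_names)

    ea, eb = graph.edges[:, 0], graph.edges[:, 1]
    observed = _pair_counts(codes[ea], codes[eb], n_labels)

    rng = stage_rng(seed, "nhood_enrichment")
    strata = (
        [np.flatnonzero(graph.sample_ids == s) for s in pd.unique(graph.sample_ids)]
        if stratify_by_sample
        else [np.arange(graph.n_nodes)]
    )
    perm_sum = np.zeros_like(observed)
    perm_sq = np.zeros_like(observed)
    perm_codes = codes.copy()
    for _ in range(n_permutations):
        for idx in strata:
            perm_codes[idx] = codes[idx][rng.permutation(idx.size)]
        counts = _pair_counts(perm_codes[ea], perm_codes[eb], n_labels)
        perm_sum += counts
        perm_sq += counts * counts
    mean = perm_sum / n_permutations
    var = perm_sq / n_permutations - mean * mean
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (observed - mean) / np.where(sd > 0, sd, 1.0), np.nan)
    n_flagged = int(np.isnan(z[np.triu_indices(n_labels)]).sum())
    if n_flagged:
        logger.warning("%d label pairs have zero permutation sd; z undefined", n_flagged)
    return EnrichmentMatrix(
        labels=label_names,
        observed=observed,
        perm_mean=mean,
        perm_sd=sd,
        zscores=z,
        n_permutations=n_permutations,
        seed=seed,
    )


def proximity_graph_export(
    enrich: EnrichmentMatrix,
    compartment_sizes: dict[str, int],
    scale: float = 0.25,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clipped, scaled proximity graph as node and edge tables.

    Edge weight = max(z, 0) * scale; zero-weight (and undefined-z) edges are
    dropped, which removes spatially distant compartment pairs.  Node size is
    the compartment's spot count.
    """
    nodes = pd.DataFrame(
        {
            "label": enrich.labels,
            "size": [int(compartment_sizes.get(l, 0)) for l in enrich.labels],
        }
    )
    rows = []
    for i, a in enumerate(enrich.labels):
        for j, b in enumerate(enrich.labels):
            if j < i:
                continue
            z = enrich.zscores[i, j]
            if not np.isfinite(z):
                continue
            weight = max(z, 0.0) * scale
            if weight > 0:
                rows.append({"label_a": a, "label_b": b, "weight": weight})
    edges = pd.DataFrame(rows, columns=["label_a", "label_b", "weight"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        nodes.to_csv(out_dir / "proximity_nodes.csv", index=False)
        edges.to_csv(out_dir / "proximity_edges.csv", index=False)
    return nodes, edges


def exact_nhood_null(
    graph: SpatialGraph, labels: np.ndarray, max_nodes: int = 12
) -> EnrichmentMatrix:
    """Exhaustive-permutation oracle for tiny single-sample graphs.

    Enumerates every distinct label assignment (multiset permutations) and
    computes the exact null mean/sd of pair counts.  Only feasible for a
    handful of nodes; used to validate the Monte-Carlo estimate.
    """
    from itertools import permutations

    if graph.n_nodes > max_nodes:
        raise ConfigError(f"exact null limited to {max_nodes} nodes")
    if len(pd.unique(graph.sample_ids)) != 1:
        raise ConfigError("exact null supports a single sample only")
    label_names = sorted(pd.unique(labels).tolist())
    codes = np.array([label_names.index(l) for l in labels])
    n_labels = len(label_names)
    ea, eb = graph.edges[:, 0], graph.edges[:, 1]
    observed = _pair_counts(codes[ea], codes[eb], n_labels)

    seen = set()
    all_counts = []
    for perm in permutations(codes.tolist()):
        if perm in seen:
            continue
        seen.add(perm)
        arr = np.array(perm)
        all_counts.append(_pair_counts(arr[ea], arr[eb], n_labels))
    stack = np.stack(all_counts)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (observed - mean) / np.where(sd > 0, sd, 1.0), np.nan)
    return EnrichmentMatrix(
        labels=label_names,
        observed=observed,
        perm_mean=mean,
        perm_sd=sd,
        zscores=z,
        n_permutations=len(all_counts),
        seed=-1,
    )
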