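"""End-to-end orchestration of the synthetic study.

``run_drug_discovery`` executes the full screen on one simulated cohort:
simulate spots and cells, normalize, cluster + annotate compartments and
T-cell clusters (or take the planted labels when the caller only exercises
the downstream statistics), score the drug dictionary, apply enrichment and
specificity filters, and rank the survivors by Teff signature score.  The
returned bundle keeps every intermediate table so tests can audit each
decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as cl
from . import pharm, simulate
from .io import DrugRecord, ObsMatrix
from .preprocess import normalize_total_log


@dataclass
class PipelineResult:
    config: simulate.SimConfig
    seed: int
    spatial_labels: pd.Series
    cell_labels: pd.Series
    enrichment: pd.DataFrame
    specificity: pd.DataFrame
    ranking: pd.DataFrame
    planted_drug_id: str | None
    truth_spatial: simulate.GroundTruth
    truth_cells: simulate.GroundTruth
    annotation_accuracy_spatial: float = float("nan")
    annotation_accuracy_cells: float = float("nan")
    extras: dict = field(default_factory=dict)

    @property
    def planted_rank(self) -> int | None:
        if self.planted_drug_id is None:
            return None
        hit = self.ranking[self.ranking["drug_id"] == self.planted_drug_id]
        return int(hit["rank"].iloc[0]) if len(hit) else None


def annotate_spatial(
    matrix_log: ObsMatrix,
    config: simulate.SimConfig,
    seed: int,
    resolution: float = 1.2,
    n_pcs: int = 50,
    k_neighbors: int = 10,
) -> tuple[pd.Series, cl.ClusterResult]:
    """Cluster spots and name clusters by compartment marker panels."""
    clusters = cl.cluster_expression(
        matrix_log,
        n_hvg=2000,
        n_pcs=n_pcs,
        k_neighbors=k_neighbors,
        resolution=resolution,
        algorithm="leiden",
        seed=seed,
    )
    annotation = cl.annotate_by_markers(matrix_log, clusters, simulate.marker_panels(config))
    return pharm.labels_from_clusters(clusters, annotation), clusters


def annotate_cells(
    matrix_log: ObsMatrix,
    config: simulate.SimConfig,
    seed: int,
    resolution: float = 1.0,
    n_pcs: int = 30,
    k_neighbors: int = 10,
) -> tuple[pd.Series, cl.ClusterResult]:
    """Cluster cells and name clusters by T-cell marker panels."""
    clusters = cl.cluster_expression(
        matrix_log,
        n_hvg=2000,
        n_pcs=n_pcs,
        k_neighbors=k_neighbors,
        resolution=resolution,
        algorithm="leiden",
        seed=seed,
    )
    annotation = cl.annotate_by_markers(matrix_log, clusters, simulate.cell_marker_panels(config))
    return pharm.labels_from_clusters(clusters, annotation), clusters


def _accuracy(predicted: pd.Series, truth: simulate.GroundTruth) -> float:
    true_labels = truth.labels().reindex(predicted.index)
    return float((predicted.to_numpy() == true_labels.to_numpy()).mean())


def run_drug_discovery(
    config: simulate.SimConfig | None = None,
    seed: int = 0,
    use_true_labels: bool = False,
) -> PipelineResult:
    """Full screen: simulate, label, score, filter, rank.

    ``use_true_labels`` bypasses clustering/annotation and uses the planted
    compartment and cluster labels — for tests that target only the drug
    statistics.
    """
    config = config if config is not None else simulate.SimConfig()

    spatial_raw, _coords, truth_sp = simulate.simulate_spatial(config, seed)
    spatial_log = normalize_total_log(spatial_raw, target_sum=10_000, log_base=2)
    if use_true_labels:
        spatial_labels = truth_sp.labels().reindex(spatial_log.obs_ids)
        acc_sp = 1.0
    else:
        spatial_labels, _ = annotate_spatial(spatial_log, config, seed)
        acc_sp = _accuracy(spatial_labels, truth_sp)

    drugs = simulate.simulate_drug_dictionary(config, seed)
    universe = pharm.filter_drug_universe(drugs)
    scores = pharm.compute_drug_scores(spatial_log, universe)
    enrichment = pharm.differential_drug_enrichment(scores, spatial_labels)
    specificity = pharm.specificity_filter(scores, spatial_labels)

    enriched_ids = set(
        enrichment.loc[enrichment["enriched_any_interest"], "drug_id"].unique()
    )
    passing_ids = [
        d
        for d in specificity.index[specificity["passes_specificity"]]
        if d in enriched_ids
    ]
    passing: list[DrugRecord] = [d for d in universe if d.drug_id in set(passing_ids)]

    cells_raw, truth_sc = simulate.simulate_single_cell(config, seed)
    cells_log = normalize_total_log(cells_raw, target_sum=10_000, log_base="e")
    if use_true_labels:
        cell_labels = truth_sc.labels().reindex(cells_log.obs_ids)
        acc_sc = 1.0
    else:
        cell_labels, _ = annotate_cells(cells_log, config, seed)
        acc_sc = _accuracy(cell_labels, truth_sc)

    teff_present = [
        c for c in pharm.DEFAULT_TEFF_CLUSTERS if c in set(pd.unique(cell_labels))
    ]
    if passing and teff_present:
        ranking = pharm.rank_by_teff_score(
            passing, cells_log, cell_labels, teff_clusters=tuple(teff_present), seed=seed
        )
    else:
        ranking = pd.DataFrame(columns=["drug_id", "teff_score", "score_defined", "rank"])

    return PipelineResult(
        config=config,
        seed=seed,
        spatial_labels=spatial_labels,
        cell_labels=cell_labels,
        enrichment=enrichment,
        specificity=specificity,
        ranking=ranking,
        planted_drug_id=truth_sp.planted_drug_id,
        truth_spatial=truth_sp,
        truth_cells=truth_sc,
        annotation_accuracy_spatial=acc_sp,
        annotation_accuracy_cells=acc_sc,
        extras={"n_universe": len(universe), "n_passing": len(passing)},
    )


def recovery_rate(
    n_seeds: int = 20,
    config: simulate.SimConfig | None = None,
    base_seed: int = 0,
    use_true_labels: bool = False,
) -> tuple[float, list[int | None]]:
    """Fraction of seeds on which the planted drug attains rank 1."""
    ranks: list[int | None] = []
    for i in range(n_seeds):
        result = run_drug_discovery(
            config=config, seed=base_seed + i, use_true_labels=use_true_labels
        )
        ranks.append(result.planted_rank)
    hits = sum(1 for r in ranks if r == 1)
    return hits / n_seeds, ranks


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def _null_small_config() -> simulate.SimConfig:
    """Reduced zero-effect cohort for calibration runs."""
    return simulate.null_config(
        n_samples_case=1,
        n_samples_control=1,
        spots_per_sample=150,
        n_genes=400,
        n_cells={"kidney": 200, "blood": 200},
        n_decoy_drugs=8,
    )


def null_wilcoxon_fpr(n_seeds: int = 50, base_seed: int = 0) -> float:
    """Per-feature Wilcoxon false-positive rate (padj < 0.05) on null cohorts.

    Every program effect is zero, so compartment labels are exchangeable and
    any BH-significant gene is a false positive.  Returns the rate averaged
    over seeds.
    """
    from .cluster import rank_genes_wilcoxon

    rates = []
    for i in range(n_seeds):
        cfg = _null_small_config()
        matrix, _coords, truth = simulate.simulate_spatial(cfg, base_seed + i)
        log = normalize_total_log(matrix, log_base=2)
        labels = truth.labels().reindex(log.obs_ids)
        top2 = labels.value_counts().index[:2]
        keep = np.flatnonzero(labels.isin(top2).to_numpy())
        sub = log.subset(obs=keep)
        de = rank_genes_wilcoxon(sub, labels.iloc[keep])
        rates.append(float((de["p_adjusted"] < 0.05).mean()))
    return float(np.mean(rates))


def null_decoy_enrichment_rate(n_seeds: int = 50, base_seed: int = 0) -> float:
    """Fraction of drugs flagged enriched on zero-effect cohorts.

    With no planted programs, drug scores are exchangeable across
    compartments; the enrichment flag should fire at most at the nominal
    level.  "Interest" compartments are the two most frequent labels of each
    simulated cohort (all labels are exchangeable under the null).
    """
    flags = total = 0
    for i in range(n_seeds):
        cfg = _null_small_config()
        matrix, _coords, truth = simulate.simulate_spatial(cfg, base_seed + i)
        log = normalize_total_log(matrix, log_base=2)
        labels = truth.labels().reindex(log.obs_ids)
        interest = tuple(labels.value_counts().index[:2])
        drugs = simulate.simulate_drug_dictionary(cfg, base_seed + i)
        scores = pharm.compute_drug_scores(log, pharm.filter_drug_universe(drugs))
        enrichment = pharm.differential_drug_enrichment(scores, labels, interest=interest)
        per_drug = enrichment.groupby("drug_id")["enriched"].any()
        flags += int(per_drug.sum())
        total += len(per_drug)
    return flags / total


def null_abundance_flag_rate(n_seeds: int = 50, base_seed: int = 0) -> float:
    """Per-compartment false-flag rate of the ALR+Welch test on null tables."""
    from .composition import CompositionTable, differential_abundance

    flags = total = 0
    probs = np.array([0.35, 0.30, 0.20, 0.15])
    comps = ["CNT/PC", "PT", "glom", "inflamed"]
    for i in range(n_seeds):
        rng = simulate.stage_rng(base_seed + i, "null_abundance")
        counts = pd.DataFrame(
            {f"S{j}": rng.multinomial(400, probs) for j in range(16)}, index=comps
        ).T
        groups = pd.Series(
            ["case"] * 8 + ["control"] * 8, index=counts.index
        )
        table = CompositionTable(counts=counts, groups=groups)
        result = differential_abundance(table, reference="CNT/PC")
        flags += int(result["flagged"].sum())
        total += len(result)
    return flags / total


def planted_enrichment_stat(config: simulate.SimConfig, seed: int) -> float:
    """Max interest-compartment log2FC of the planted drug, on planted labels.

    Light-weight statistic for effect-size monotonicity checks; uses whichever
    inflamed compartments the simulated cohort realized (small cohorts may
    lack one entirely).
    """
    spatial_raw, _coords, truth = simulate.simulate_spatial(config, seed)
    spatial_log = normalize_total_log(spatial_raw, target_sum=10_000, log_base=2)
    labels = truth.labels().reindex(spatial_log.obs_ids)
    drugs = simulate.simulate_drug_dictionary(config, seed)
    scores = pharm.compute_drug_scores(spatial_log, pharm.filter_drug_universe(drugs))
    present = tuple(c for c in pharm.DEFAULT_INTEREST if c in set(pd.unique(labels)))
    if not present:
        return float("nan")
    enrichment = pharm.differential_drug_enrichment(scores, labels, interest=present)
    sub = enrichment[enrichment["drug_id"] == truth.planted_drug_id]
    return float(sub["log2fc"].max()) if len(sub) else float("nan")
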