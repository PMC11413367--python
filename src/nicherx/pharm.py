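"""Drug-prioritization: universe filter, target scoring, enrichment,
specificity, and Teff ranking.

The stage mirrors a digital-pharmacology screen: restrict the dictionary to
antineoplastic/immunomodulating drugs (ATC L01/L02/L04, excluding the L03
immunostimulants) that are approved and chemically viable; score every
observation for every drug as the mean log-normalized expression of its
target genes; test each drug's scores for enrichment in the inflamed
compartments of interest (Wilcoxon vs rest, BH across drugs, log2FC > 0.25);
keep drugs whose detected-score fraction is at least 75% in every interest
compartment and below 75% in every other compartment; finally rank the
survivors by the binned-background signature score of their targets averaged
over CD4+/CD8+ effector T cells.

Two distinct scores are used on purpose: the non-negative target-mean score
makes the 0.25 log2 fold-change cutoff well defined, while the background-
corrected signature score gives the final T-cell specificity ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError
from .cluster import ClusterResult, bh_adjust, score_gene_set, _require_log
from .io import DrugRecord, GeneSet, ObsMatrix

logger = logging.getLogger(__name__)

DEFAULT_INTEREST = ("inflamed_glomerular", "inflamed_interstitial")
DEFAULT_TEFF_CLUSTERS = ("CD4_Teff", "CD8_Teff")


@dataclass
class DrugScoreMatrix:
    """Observations x drugs target-mean scores on the log-normalized layer."""

    scores: pd.DataFrame  # obs x drugs
    n_targets_present: pd.Series  # per drug
    log_base: str = "e"
    excluded: list[str] = field(default_factory=list)


def filter_drug_universe(
    drugs: list[DrugRecord],
    include_prefixes: tuple[str, ...] = ("L01", "L02", "L04"),
    exclude_prefixes: tuple[str, ...] = ("L03",),
    require_approved: bool = True,
    require_viable: bool = True,
) -> list[DrugRecord]:
    """ATC-prefix and flag filter defining the candidate drug universe."""
    kept = []
    for drug in drugs:
        code = drug.atc_code
        if not any(code.startswith(p) for p in include_prefixes):
            continue
        if any(code.startswith(p) for p in exclude_prefixes):
            continue
        if require_approved and not drug.approved:
            continue
        if require_viable and not drug.viable:
            continue
        if not drug.targets:
            logger.warning("drug %s has no targets; dropped from universe", drug.drug_id)
            continue
        kept.append(drug)
    return kept


def compute_drug_scores(matrix: ObsMatrix, drugs: list[DrugRecord]) -> DrugScoreMatrix:
    """score(obs, drug) = mean log-normalized expression over present targets."""
    _require_log(matrix, "compute_drug_scores")
    X = matrix.dense()
    columns: dict[str, np.ndarray] = {}
    n_present: dict[str, int] = {}
    excluded: list[str] = []
    for drug in drugs:
        idx = matrix.gene_index(drug.targets)
        if idx.size == 0:
            excluded.append(drug.drug_id)
            logger.warning("drug %s: no target present in matrix; excluded", drug.drug_id)
            continue
        columns[drug.drug_id] = X[idx, :].mean(axis=0)
        n_present[drug.drug_id] = int(idx.size)
    if not columns:
        raise ValidationError("no drug has a target present in the matrix")
    return DrugScoreMatrix(
        scores=pd.DataFrame(columns, index=matrix.obs_ids),
        n_targets_present=pd.Series(n_present, name="n_targets_present"),
        log_base=matrix.meta.get("log_base", "e"),
        excluded=excluded,
    )


def _delog_scores(values: np.ndarray, log_base: str) -> np.ndarray:
    if log_base == "2":
        return np.exp2(values) - 1.0
    return np.expm1(values)


def differential_drug_enrichment(
    scores: DrugScoreMatrix,
    compartment_labels: pd.Series | np.ndarray,
    interest: tuple[str, ...] = DEFAULT_INTEREST,
    lfc_cutoff: float = 0.25,
    padj_cutoff: float = 0.05,
    epsilon: float = 1e-9,
) -> pd.DataFrame:
    """Wilcoxon enrichment of drug scores in each interest compartment vs rest.

    A drug is "enriched" iff p_adjusted < cutoff AND log2fc > cutoff in at
    least one interest compartment.  BH runs across drugs within each
    compartment.  log2fc compares de-logged score means.
    """
    labels = _aligned_labels(scores.scores.index, compartment_labels)
    present = set(pd.unique(labels))
    for comp in interest:
        if comp not in present:
            raise ValidationError(f"interest compartment {comp!r} absent from labels")

    values = scores.scores.to_numpy()
    linear = _delog_scores(values, scores.log_base)
    rows = []
    for comp in interest:
        mask = labels == comp
        if mask.sum() == 0 or (~mask).sum() == 0:
            raise ValidationError(f"compartment {comp!r} has no spots")
        pvals = np.ones(values.shape[1])
        lfcs = np.zeros(values.shape[1])
        for j in range(values.shape[1]):
            col = values[:, j]
            stat = scipy.stats.mannwhitneyu(
                col[mask], col[~mask], alternative="two-sided"
            )
            pvals[j] = stat.pvalue
            m_in = linear[mask, j].mean()
            m_out = linear[~mask, j].mean()
            lfcs[j] = np.log2((m_in + epsilon) / (m_out + epsilon))
        padj = bh_adjust(pvals)
        for j, drug_id in enumerate(scores.scores.columns):
            rows.append(
                {
                    "drug_id": drug_id,
                    "compartment": comp,
                    "log2fc": lfcs[j],
                    "p_value": pvals[j],
                    "p_adjusted": padj[j],
                    "enriched": bool(padj[j] < padj_cutoff and lfcs[j] > lfc_cutoff),
                }
            )
    result = pd.DataFrame(rows)
    flags = result.groupby("drug_id")["enriched"].any()
    result["enriched_any_interest"] = result["drug_id"].map(flags)
    return result


def specificity_filter(
    scores: DrugScoreMatrix,
    compartment_labels: pd.Series | np.ndarray,
    interest: tuple[str, ...] = DEFAULT_INTEREST,
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Detected-score fractions per compartment and the 75% specificity rule.

    f(drug, compartment) = fraction of the compartment's observations with a
    positive drug score (>= 1 target detected).  A drug passes iff f >=
    threshold in EVERY interest compartment and f < threshold in EVERY other
    compartment.  The fractions are returned so every decision is auditable.
    """
    labels = _aligned_labels(scores.scores.index, compartment_labels)
    compartments = list(pd.unique(labels))
    detected = scores.scores.to_numpy() > 0
    fractions = pd.DataFrame(
        {
            comp: detected[labels == comp, :].mean(axis=0)
            for comp in compartments
        },
        index=scores.scores.columns,
    )
    interest_cols = [c for c in compartments if c in set(interest)]
    other_cols = [c for c in compartments if c not in set(interest)]
    passes = fractions[interest_cols].ge(threshold).all(axis=1)
    if other_cols:
        passes &= fractions[other_cols].lt(threshold).all(axis=1)
    result = fractions.copy()
    result.columns = [f"frac_{c}" for c in fractions.columns]
    result["min_interest_fraction"] = fractions[interest_cols].min(axis=1)
    result["max_other_fraction"] = (
        fractions[other_cols].max(axis=1) if other_cols else 0.0
    )
    result["passes_specificity"] = passes
    return result.rename_axis("drug_id")


def rank_by_teff_score(
    passing_drugs: list[DrugRecord],
    cell_matrix: ObsMatrix,
    cell_labels: pd.Series | np.ndarray,
    teff_clusters: tuple[str, ...] = DEFAULT_TEFF_CLUSTERS,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank passing drugs by their targets' signature score in Teff cells.

    teff_score(drug) = mean over CD4+/CD8+ Teff cells of the binned-background
    gene-set score of the drug's targets on the single-cell matrix.  Sorted
    decreasing; ties break by drug_id (warned); drugs without any target in
    the matrix get an undefined score and sort last, flagged.
    """
    labels = _aligned_labels(cell_matrix.obs_ids, cell_labels)
    present = set(pd.unique(labels))
    missing = [c for c in teff_clusters if c not in present]
    if missing:
        raise ValidationError(f"Teff clusters absent from cell labels: {missing}")
    teff_mask = np.isin(labels, list(teff_clusters))

    rows = []
    for drug in passing_drugs:
        idx = cell_matrix.gene_index(drug.targets)
        if idx.size == 0:
            logger.warning("drug %s: no target in cell matrix; teff_score undefined", drug.drug_id)
            rows.append(
                {"drug_id": drug.drug_id, "teff_score": np.nan, "score_defined": False}
            )
            continue
        per_cell = score_gene_set(
            cell_matrix,
            GeneSet(name=f"targets:{drug.drug_id}", genes=list(dict.fromkeys(drug.targets))),
            n_bins=n_bins,
            ctrl_size=ctrl_size,
            seed=seed,
        )
        rows.append(
            {
                "drug_id": drug.drug_id,
                "teff_score": float(per_cell.to_numpy()[teff_mask].mean()),
                "score_defined": True,
            }
        )
    result = pd.DataFrame(rows)
    dup = result.duplicated(subset="teff_score", keep=False) & result["score_defined"]
    if dup.any():
        logger.warning("tied teff scores broken by drug_id order: %s",
                       result.loc[dup, "drug_id"].tolist())
    result = result.sort_values(
        by=["score_defined", "teff_score", "drug_id"],
        ascending=[False, False, True],
        na_position="last",
    ).reset_index(drop=True)
    result["rank"] = np.arange(1, len(result) + 1)
    return result


def _aligned_labels(index, labels) -> np.ndarray:
    if isinstance(labels, pd.Series):
        labels = labels.reindex(index).to_numpy()
    labels = np.asarray(labels)
    if pd.isna(labels).any():
        raise ValidationError("compartment labels must cover every observation")
    return labels


def labels_from_clusters(clusters: ClusterResult, annotation: dict[int, str]) -> pd.Series:
    """Translate integer cluster labels into compartment names."""
    names = np.array([annotation[int(c)] for c in clusters.labels])
    return pd.Series(names, index=clusters.obs_ids, name="compartment")
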