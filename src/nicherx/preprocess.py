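"""Quality control and normalization for spot, cell, and protein matrices.

Two QC modes mirror the two data layers: ``spatial`` keeps observations with
detected-gene count >= min_genes and total counts inside an inclusive
[min_counts, max_counts] window; ``single_cell`` keeps cells whose detected
gene count lies strictly between the bounds and whose mitochondrial count
fraction (over ``MT-`` prefixed symbols, on raw counts) is at most the
threshold.  Gene filtering (detected in >= min_obs_per_gene observations) is
applied after the observation filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ConfigError, ValidationError
from .io import ObsMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    min_genes_per_obs: int = 100
    max_genes_per_obs: int | None = None  # exclusive upper bound, single_cell only
    min_obs_per_gene: int = 3
    min_counts: float = 2000
    max_counts: float = 35000
    max_mito_fraction: float = 1.0
    mode: str = "spatial"

    def __post_init__(self) -> None:
        if self.mode not in ("spatial", "single_cell"):
            raise ConfigError(f"unknown QC mode {self.mode!r}")
        if self.min_counts > self.max_counts:
            raise ConfigError("min_counts exceeds max_counts")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ConfigError("max_mito_fraction must lie in [0, 1]")

    @classmethod
    def spatial_defaults(cls) -> "QCThresholds":
        return cls(
            min_genes_per_obs=100,
            min_obs_per_gene=3,
            min_counts=2000,
            max_counts=35000,
            mode="spatial",
        )

    @classmethod
    def single_cell_defaults(cls) -> "QCThresholds":
        return cls(
            min_genes_per_obs=500,
            max_genes_per_obs=5000,
            min_obs_per_gene=3,
            min_counts=0,
            max_counts=np.inf,
            max_mito_fraction=0.10,
            mode="single_cell",
        )


@dataclass
class QCReport:
    mode: str
    n_obs_in: int = 0
    n_obs_out: int = 0
    n_genes_in: int = 0
    n_genes_out: int = 0
    removed_by_rule: dict = field(default_factory=dict)

    def validate(self) -> None:
        obs_removed = sum(
            v for k, v in self.removed_by_rule.items() if not k.startswith("gene")
        )
        # rules may overlap, so per-rule sums bound the total from above
        if self.n_obs_in - self.n_obs_out > obs_removed:
            raise ValidationError("QC report per-rule counts inconsistent with totals")


def _detected_and_totals(matrix: ObsMatrix) -> tuple[np.ndarray, np.ndarray]:
    v = matrix.values
    if sp.issparse(v):
        detected = np.asarray((v > 0).sum(axis=0)).ravel()
        totals = np.asarray(v.sum(axis=0)).ravel()
    else:
        detected = (v > 0).sum(axis=0)
        totals = v.sum(axis=0)
    return detected, totals


def qc_filter(matrix: ObsMatrix, thresholds: QCThresholds) -> tuple[ObsMatrix, QCReport]:
    """Filter observations then genes; returns the surviving matrix and report."""
    if matrix.layer != "raw_counts":
        raise ValidationError(f"qc_filter requires raw_counts, got {matrix.layer!r}")
    detected, totals = _detected_and_totals(matrix)
    report = QCReport(
        mode=thresholds.mode, n_obs_in=matrix.n_obs, n_genes_in=matrix.n_genes
    )

    if thresholds.mode == "spatial":
        keep_genes_rule = detected >= thresholds.min_genes_per_obs
        keep_counts = (totals >= thresholds.min_counts) & (totals <= thresholds.max_counts)
        keep_obs = keep_genes_rule & keep_counts
        report.removed_by_rule["obs_min_genes"] = int((~keep_genes_rule).sum())
        report.removed_by_rule["obs_counts_window"] = int((~keep_counts).sum())
    else:
        # "less than 500 or more than 5000 expressed genes" removed: bounds exclusive
        keep_genes_rule = detected >= thresholds.min_genes_per_obs
        if thresholds.max_genes_per_obs is not None:
            keep_genes_rule &= detected <= thresholds.max_genes_per_obs
        mito_idx = [i for i, g in enumerate(matrix.gene_ids) if g.startswith("MT-")]
        if mito_idx and matrix.n_obs:
            v = matrix.values
            mito_counts = (
                np.asarray(v[mito_idx, :].sum(axis=0)).ravel()
                if sp.issparse(v)
                else v[mito_idx, :].sum(axis=0)
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        else:
            mito_frac = np.zeros(matrix.n_obs)
        keep_mito = mito_frac <= thresholds.max_mito_fraction
        keep_counts = (totals >= thresholds.min_counts) & (totals <= thresholds.max_counts)
        keep_obs = keep_genes_rule & keep_mito & keep_counts
        report.removed_by_rule["obs_gene_bounds"] = int((~keep_genes_rule).sum())
        report.removed_by_rule["obs_mito_fraction"] = int((~keep_mito).sum())
        report.removed_by_rule["obs_counts_window"] = int((~keep_counts).sum())

    obs_idx = np.flatnonzero(keep_obs)
    filtered = matrix.subset(obs=obs_idx)

    detected_per_gene, _ = _gene_detection(filtered)
    keep_genes = detected_per_gene >= thresholds.min_obs_per_gene
    report.removed_by_rule["gene_min_obs"] = int((~keep_genes).sum())
    filtered = filtered.subset(genes=np.flatnonzero(keep_genes))

    report.n_obs_out = filtered.n_obs
    report.n_genes_out = filtered.n_genes
    report.validate()
    return filtered, report


def _gene_detection(matrix: ObsMatrix) -> tuple[np.ndarray, np.ndarray]:
    v = matrix.values
    if sp.issparse(v):
        det = np.asarray((v > 0).sum(axis=1)).ravel()
        tot = np.asarray(v.sum(axis=1)).ravel()
    else:
        det = (v > 0).sum(axis=1)
        tot = v.sum(axis=1)
    return det, tot


def normalize_total_log(
    matrix: ObsMatrix, target_sum: float = 10_000.0, log_base: float | str = 2
) -> ObsMatrix:
    """Scale each observation to ``target_sum`` total, then log(x + 1).

    ``log_base`` is 2 for the spatial branch and "e" (natural log, log1p) for
    the single-cell branch; the base is recorded in the matrix metadata so
    downstream fold changes de-log correctly.
    """
    if matrix.layer != "raw_counts":
        raise ValidationError(f"normalize_total_log requires raw_counts, got {matrix.layer!r}")
    if log_base not in (2, "e"):
        raise ConfigError("log_base must be 2 or 'e'")
    _detected, totals = _detected_and_totals(matrix)
    zero = totals == 0
    if zero.any():
        logger.warning("%d observations have zero total counts; left all-zero", int(zero.sum()))
    scale = np.where(zero, 0.0, target_sum / np.maximum(totals, 1e-300))

    if sp.issparse(matrix.values):
        values = (matrix.values.astype(np.float64) @ sp.diags(scale)).tocsr()
        values.data = np.log1p(values.data)
        if log_base == 2:
            values.data /= np.log(2.0)
    else:
        values = np.asarray(matrix.values, dtype=np.float64) * scale[None, :]
        values = np.log1p(values)
        if log_base == 2:
            values /= np.log(2.0)

    return ObsMatrix(
        values=values,
        gene_ids=list(matrix.gene_ids),
        obs_ids=list(matrix.obs_ids),
        obs_meta=matrix.obs_meta.copy(),
        layer="log_transformed",
        meta={**matrix.meta, "log_base": "2" if log_base == 2 else "e", "target_sum": target_sum},
    )


def clr_normalize(protein_matrix: ObsMatrix) -> ObsMatrix:
    """Centered log-ratio normalization: y_g = log(x_g + 1) - mean_g log(x_g + 1)."""
    v = protein_matrix.dense()
    if v.size and v.min() < 0:
        raise ValidationError("clr_normalize requires non-negative counts")
    logged = np.log1p(v)
    centered = logged - logged.mean(axis=0, keepdims=True)
    return ObsMatrix(
        values=centered,
        gene_ids=list(protein_matrix.gene_ids),
        obs_ids=list(protein_matrix.obs_ids),
        obs_meta=protein_matrix.obs_meta.copy(),
        layer="clr",
        meta=dict(protein_matrix.meta),
    )
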