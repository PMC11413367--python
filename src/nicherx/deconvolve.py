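"""Reference-based spot deconvolution by non-negative least squares.

A signature matrix holds the mean de-logged normalized expression profile of
each cell type from the single-cell atlas (on a common gene space, typically
atlas HVGs intersected with the spatial genes).  Each spot's library-size
normalized linear expression vector y is decomposed as min ||y - S w||_2
subject to w >= 0 — mixing is linear in transcript abundance, hence the
linear scale — and w is renormalized to sum to one.  Spots with an all-zero
solution fall back to uniform proportions and are flagged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp

from .errors import ValidationError
from .io import ObsMatrix

logger = logging.getLogger(__name__)


def build_signature(
    cell_matrix: ObsMatrix,
    labels: pd.Series | np.ndarray,
    genes: list[str] | None = None,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-type mean de-logged normalized expression (genes x cell types).

    ``cell_matrix`` may be a log_transformed layer (it is de-logged using the
    recorded base) or an already linear normalized layer.  Types with fewer
    than ``min_cells`` cells are excluded with a warning.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(cell_matrix.obs_ids).to_numpy()
    labels = np.asarray(labels)

    if cell_matrix.layer == "log_transformed":
        from .cluster import _delog

        values = _delog(cell_matrix.dense(), cell_matrix)
    elif cell_matrix.layer in ("normalized", "raw_counts"):
        values = cell_matrix.dense()
    else:
        raise ValidationError(f"cannot build signature from layer {cell_matrix.layer!r}")

    if genes is not None:
        idx = cell_matrix.gene_index(genes)
        if idx.size == 0:
            raise ValidationError("no requested signature gene present in the cell matrix")
        values = values[idx, :]
        gene_ids = [cell_matrix.gene_ids[i] for i in idx]
    else:
        gene_ids = list(cell_matrix.gene_ids)

    columns = {}
    for cell_type in pd.unique(labels):
        mask = labels == cell_type
        if mask.sum() < min_cells:
            logger.warning(
                "cell type %r has %d cells (< %d); excluded from signature",
                cell_type,
                int(mask.sum()),
                min_cells,
            )
            continue
        columns[cell_type] = values[:, mask].mean(axis=1)
    if not columns:
        raise ValidationError("no cell type met the min_cells requirement")
    signature = pd.DataFrame(columns, index=gene_ids)
    zero_types = signature.columns[(signature.sum(axis=0) == 0).to_numpy()].tolist()
    if zero_types:
        raise ValidationError(f"signature columns all zero for types {zero_types}")
    return signature


def highly_variable_genes(matrix: ObsMatrix, n_top: int = 500) -> list[str]:
    """Top genes by variance of the (log) values — the atlas HVG set."""
    v = matrix.values
    if sp.issparse(v):
        mean = np.asarray(v.mean(axis=1)).ravel()
        sq = np.asarray(v.multiply(v).mean(axis=1)).ravel()
        var = sq - mean**2
    else:
        var = np.asarray(v).var(axis=1)
    order = np.argsort(var)[::-1][:n_top]
    return [matrix.gene_ids[i] for i in np.sort(order)]


def deconvolve_nnls(
    spot_matrix: ObsMatrix, signature: pd.DataFrame, target_sum: float = 10_000.0
) -> pd.DataFrame:
    """Estimate per-spot cell-type proportions by NNLS against the signature.

    Spots and signature are matched on their common gene set (>= 2 genes
    required).  Spot values are brought to the linear scale (de-logged if
    needed) and library-size normalized; signature columns are normalized to
    the same total so the weights are proportion-like before the final
    renormalization to sum one.
    """
    common = [g for g in signature.index if g in set(spot_matrix.gene_ids)]
    if len(common) < 2:
        raise ValidationError("fewer than 2 genes shared between spots and signature")

    if spot_matrix.layer == "log_transformed":
        from .cluster import _delog

        values = _delog(spot_matrix.dense(), spot_matrix)
    else:
        values = spot_matrix.dense()
    idx = spot_matrix.gene_index(common)
    y = values[idx, :]
    totals = y.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(totals > 0, y * (target_sum / np.maximum(totals, 1e-300)), 0.0)

    S = signature.loc[common].to_numpy(dtype=float)
    col_totals = S.sum(axis=0)
    if np.any(col_totals <= 0):
        raise ValidationError("signature has an all-zero column on the common gene set")
    S = S * (target_sum / col_totals)

    n_types = S.shape[1]
    props = np.zeros((spot_matrix.n_obs, n_types))
    flagged = np.zeros(spot_matrix.n_obs, dtype=bool)
    for j in range(spot_matrix.n_obs):
        w, _res = scipy.optimize.nnls(S, y[:, j])
        total = w.sum()
        if total <= 0:
            props[j] = 1.0 / n_types
            flagged[j] = True
        else:
            props[j] = w / total
    if flagged.any():
        logger.warning("%d spots had all-zero NNLS solutions; set uniform", int(flagged.sum()))
    result = pd.DataFrame(props, index=spot_matrix.obs_ids, columns=list(signature.columns))
    result.attrs["zero_signal"] = flagged
    return result


def teff_localization_summary(
    proportions: pd.DataFrame,
    compartments: pd.Series | np.ndarray,
    teff_types: list[str] | None = None,
) -> pd.DataFrame:
    """Tukey box summaries of Teff proportions per compartment.

    For each compartment x cell type: median, type-6 quartiles, whisker
    bounds (the most extreme data points within 1.5 IQR of the box), and the
    outlier count beyond the whiskers.
    """
    from .clinical import quantile_type6

    if isinstance(compartments, pd.Series):
        compartments = compartments.reindex(proportions.index).to_numpy()
    compartments = np.asarray(compartments)
    if pd.isna(compartments).any():
        raise ValidationError("compartment labels must cover every spot")
    types = teff_types if teff_types is not None else list(proportions.columns)

    rows = []
    for comp in pd.unique(compartments):
        mask = compartments == comp
        for cell_type in types:
            vals = proportions.loc[mask, cell_type].to_numpy(dtype=float)
            q1 = quantile_type6(vals, 0.25)
            med = quantile_type6(vals, 0.5)
            q3 = quantile_type6(vals, 0.75)
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
            rows.append(
                {
                    "compartment": comp,
                    "cell_type": cell_type,
                    "n": vals.size,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_low": inside.min() if inside.size else med,
                    "whisker_high": inside.max() if inside.size else med,
                    "n_outliers": int(((vals < lo_fence) | (vals > hi_fence)).sum()),
                }
            )
    return pd.DataFrame(rows)
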