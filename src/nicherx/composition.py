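"""Compartment composition tables and reference-based differential abundance.

Spot compositions are compositional data: only relative abundances are
identified.  The test therefore works on additive log-ratios (ALR) against a
fixed reference compartment — ALR_c = log((n_c + 0.5) / (n_ref + 0.5)) per
sample — and compares case vs control per non-reference compartment with a
Welch two-sample t-test, BH-adjusted across compartments.  The Haldane-
Anscombe pseudo-count 0.5 handles empty cells.  Outputs are labeled
``alr_welch``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError
from .cluster import bh_adjust


@dataclass
class CompositionTable:
    counts: pd.DataFrame  # samples x compartments, spot counts
    groups: pd.Series  # sample -> case/control

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.counts.index)
        if self.groups.isna().any():
            missing = self.groups[self.groups.isna()].index.tolist()
            raise ValidationError(f"samples with unknown group: {missing}")
        values = self.counts.to_numpy()
        if np.any(values < 0) or np.any(values != np.floor(values)):
            raise ValidationError("composition counts must be non-negative integers")


def composition_table(
    labels: pd.Series | np.ndarray,
    sample_ids: pd.Series | np.ndarray,
    groups: dict[str, str] | pd.Series,
    compartments: list[str] | None = None,
) -> CompositionTable:
    """Cross-tabulate spot labels by sample; absent compartments get zeros."""
    labels = np.asarray(labels)
    sample_ids = np.asarray(sample_ids)
    if len(labels) != len(sample_ids):
        raise ValidationError("labels and sample_ids must align")
    counts = pd.crosstab(pd.Series(sample_ids, name="sample"), pd.Series(labels, name="label"))
    if compartments is not None:
        counts = counts.reindex(columns=compartments, fill_value=0)
    group_series = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    return CompositionTable(counts=counts.astype(int), groups=group_series)


def differential_abundance(
    table: CompositionTable,
    reference: str = "CNT/PC",
    fdr: float = 0.05,
    pseudo: float = 0.5,
    case_group: str = "case",
    control_group: str = "control",
) -> pd.DataFrame:
    """ALR-vs-reference Welch test of case against control per compartment.

    Returns one row per non-reference compartment with the ALR effect
    (difference of group means), p, BH-adjusted p, and the FDR decision flag.
    The reference compartment is excluded from testing by construction.
    """
    if reference not in table.counts.columns:
        raise ValidationError(f"reference compartment {reference!r} absent from table")
    for group in (case_group, control_group):
        if (table.groups == group).sum() < 2:
            raise ValidationError(f"need at least 2 samples in group {group!r}")

    ref = table.counts[reference].to_numpy(dtype=float)
    rows = []
    for comp in table.counts.columns:
        if comp == reference:
            continue
        alr = np.log((table.counts[comp].to_numpy(dtype=float) + pseudo) / (ref + pseudo))
        case_vals = alr[(table.groups == case_group).to_numpy()]
        ctrl_vals = alr[(table.groups == control_group).to_numpy()]
        effect = case_vals.mean() - ctrl_vals.mean()
        stat = scipy.stats.ttest_ind(case_vals, ctrl_vals, equal_var=False)
        rows.append(
            {
                "compartment": comp,
                "effect_alr": effect,
                "p_value": float(stat.pvalue),
                "method": "alr_welch",
            }
        )
    result = pd.DataFrame(rows)
    result["p_adjusted"] = bh_adjust(result["p_value"].to_numpy())
    result["flagged"] = result["p_adjusted"] < fdr
    return result
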