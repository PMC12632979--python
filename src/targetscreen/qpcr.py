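"""Relative expression and knockdown efficiency from qPCR Ct values.

Implements the classic 2^-ddCt quantification: the target gene's Ct is
normalized to an internal reference gene (dCt) within each condition, and the
knockdown condition is then normalized to the control-siRNA condition (ddCt).
No amplification-efficiency correction is applied.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def relative_expression(ct_gene_kd: float, ct_ref_kd: float,
                        ct_gene_ctrl: float, ct_ref_ctrl: float) -> float:
    """Fold change of the target gene in the knockdown vs control condition.

    Returns ``2 ** -[(ct_gene_kd - ct_ref_kd) - (ct_gene_ctrl - ct_ref_ctrl)]``;
    always positive.  One extra cycle on the knockdown gene halves the result.
    """
    values = (ct_gene_kd, ct_ref_kd, ct_gene_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(v) for v in values):
        raise ValueError(f"non-finite Ct value in {values!r}")
    ddct = (ct_gene_kd - ct_ref_kd) - (ct_gene_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def knockdown_efficiency(fold_changes) -> float:
    """Percent reduction in expression: ``100 * (1 - mean(fold changes))``.

    Averaging is over replicate fold changes (not over ddCt).  Negative when
    expression rose.
    """
    folds = np.asarray(list(fold_changes), dtype=float)
    if folds.size == 0:
        raise ValueError("knockdown_efficiency requires at least one fold change")
    if not np.isfinite(folds).all():
        raise ValueError("non-finite fold change")
    return 100.0 * (1.0 - folds.mean())


def summarize_knockdown(ct_table: pd.DataFrame,
                        control_condition: str = "control") -> pd.DataFrame:
    """Per-gene knockdown efficiency from a replicate Ct table.

    ``ct_table`` columns: gene, condition, replicate, ct_gene, ct_reference.
    Replicates of the knockdown condition are paired with the mean control
    dCt for the same gene; one fold change per knockdown replicate is then
    averaged into a percent efficiency.
    """
    rows = []
    for gene, sub in ct_table.groupby("gene", sort=True):
        ctrl = sub[sub["condition"] == control_condition]
        kd = sub[sub["condition"] != control_condition]
        if ctrl.empty or kd.empty:
            raise ValueError(
                f"gene {gene!r}: need both knockdown and {control_condition!r} rows"
            )
        dct_ctrl = (ctrl["ct_gene"] - ctrl["ct_reference"]).mean()
        folds = [
            2.0 ** (-((r.ct_gene - r.ct_reference) - dct_ctrl))
            for r in kd.itertuples()
        ]
        rows.append({
            "gene": gene,
            "n_replicates": len(folds),
            "mean_fold_change": float(np.mean(folds)),
            "knockdown_pct": knockdown_efficiency(folds),
        })
    return pd.DataFrame(rows, columns=["gene", "n_replicates",
                                       "mean_fold_change", "knockdown_pct"])
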