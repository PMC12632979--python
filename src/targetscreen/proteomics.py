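"""Sample QC and per-protein differential abundance.

Samples with too few quantified proteins are excluded (strict "fewer than"
semantics).  Within each cell line, every protein is tested across all siRNA
groups by one-way ANOVA, and each target-vs-control pairwise contrast is
adjusted with Tukey's HSD (Tukey-Kramer for unequal group sizes).  Missing
intensities are handled complete-case per protein per group; a group below
the minimum observation count drops out of that protein's test.

The per-contrast log2 fold change (mean target minus mean control on the
log2 scale) is the ranking statistic consumed by the enrichment stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import RunConfig
from .containers import ProteinMatrix
from .phenotypes import CONTROL_SIRNA
from .stats import studentized_range_sf

logger = logging.getLogger(__name__)

DE_COLUMNS = ["protein", "cell_line", "target", "n_target", "n_control",
              "log2fc", "q_stat", "p_tukey", "significant", "infinite_f"]


@dataclass
class QCReport:
    kept: list
    excluded: pd.DataFrame  # sample, n_proteins, cell_line, target


def qc_filter_samples(pm: ProteinMatrix, min_proteins: int) -> tuple[ProteinMatrix, QCReport]:
    """Drop samples with fewer than ``min_proteins`` quantified proteins.

    A sample with exactly ``min_proteins`` is retained.  Raises if every
    sample would be excluded.
    """
    if min_proteins < 0:
        raise ValueError("min_proteins must be >= 0")
    counts = pm.detected_counts()
    drop = counts.index[counts < min_proteins]
    keep = [s for s in pm.values.columns if s not in set(drop)]
    if not keep:
        raise ValueError(
            f"all {pm.n_samples} samples have fewer than {min_proteins} "
            "quantified proteins"
        )
    excluded = pd.DataFrame({
        "sample": list(drop),
        "n_proteins": counts.loc[drop].to_numpy(),
        "cell_line": pm.samples.loc[drop, "cell_line"].to_numpy(),
        "target": pm.samples.loc[drop, "target"].to_numpy(),
    })
    if len(drop):
        logger.info("QC: excluded %d/%d samples with < %d proteins",
                    len(drop), pm.n_samples, min_proteins)
    return pm.subset_samples(keep), QCReport(kept=keep, excluded=excluded)


def _group_summaries(values: np.ndarray, group_idx: list[np.ndarray]):
    """nan-aware per-group (count, mean, within-group SS) for each protein."""
    P = values.shape[0]
    G = len(group_idx)
    n = np.zeros((P, G))
    mean = np.full((P, G), np.nan)
    ssw = np.zeros((P, G))
    for g, idx in enumerate(group_idx):
        block = values[:, idx]
        cnt = np.sum(~np.isnan(block), axis=1)
        n[:, g] = cnt
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(np.where(cnt[:, None] > 0, block, np.nan), axis=1)
            mean[:, g] = m
            dev = block - m[:, None]
            ssw[:, g] = np.nansum(dev * dev, axis=1)
    return n, mean, ssw


def anova_tukey(pm: ProteinMatrix, cell_line: str,
                control: str = CONTROL_SIRNA,
                alpha: float = 0.05, min_obs: int = 3) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA across all siRNA groups plus Tukey HSD contrasts.

    Returns ``(de, anova, skipped)``: per-contrast differential-abundance rows
    (target vs control, Tukey-adjusted p), per-protein ANOVA F and p, and a
    report of proteins/groups that failed the minimum-observation filter.

    Proteins where every retained group is constant at a common value get
    F = 0 and all pairwise p = 1; zero residual variance with unequal means
    is emitted as an infinite-F record (p = 0, flagged).
    """
    sub = pm.for_cell_line(cell_line)
    groups = sorted(sub.samples["target"].unique())
    if control not in groups:
        raise ValueError(f"no {control!r} samples in cell line {cell_line!r}")
    sample_arr = sub.samples
    group_idx = [np.flatnonzero((sample_arr["target"] == g).to_numpy())
                 for g in groups]
    values = sub.values.to_numpy()
    proteins = sub.values.index.to_numpy()
    n, mean, ssw = _group_summaries(values, group_idx)

    valid = n >= min_obs                      # (P, G)
    ctrl_col = groups.index(control)
    k = valid.sum(axis=1).astype(float)       # groups entering the ANOVA
    testable = (k >= 2) & valid[:, ctrl_col]

    # one-way ANOVA over valid groups
    nv = np.where(valid, n, 0.0)
    mv = np.where(valid, mean, 0.0)
    N = nv.sum(axis=1)
    grand = np.divide((nv * mv).sum(axis=1), N, out=np.zeros_like(N), where=N > 0)
    ssb = (nv * (mv - grand[:, None]) ** 2).sum(axis=1)
    ssw_tot = np.where(valid, ssw, 0.0).sum(axis=1)
    df_between = k - 1.0
    df_within = N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        msb = ssb / df_between
        msw = ssw_tot / df_within
        F = msb / msw
    zero_resid = testable & (msw <= 0)
    flat = zero_resid & (ssb <= 1e-12)        # all values identical
    inf_f = zero_resid & ~flat
    p_anova = np.full(len(proteins), np.nan)
    ok = testable & (msw > 0)
    p_anova[ok] = sps.f.sf(F[ok], df_between[ok], df_within[ok])
    F[flat], p_anova[flat] = 0.0, 1.0
    F[inf_f], p_anova[inf_f] = np.inf, 0.0

    anova = pd.DataFrame({
        "protein": proteins, "cell_line": cell_line,
        "n_groups": k.astype(int), "F": F, "p_anova": p_anova,
        "tested": testable,
    })

    # Tukey HSD for each target-vs-control contrast
    de_parts = []
    tgt_cols = [j for j, g in enumerate(groups) if g != control]
    for j in tgt_cols:
        m_ok = testable & valid[:, j]
        if not m_ok.any():
            continue
        diff = mean[m_ok, j] - mean[m_ok, ctrl_col]
        n_t, n_c = n[m_ok, j], n[m_ok, ctrl_col]
        msw_j, k_j, df_j = msw[m_ok], k[m_ok], df_within[m_ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(msw_j * (1.0 / n_t + 1.0 / n_c) / 2.0)
            q = np.abs(diff) / se
        p = np.full(q.shape, np.nan)
        zero_var = ~(msw_j > 0)
        p[zero_var & (np.abs(diff) <= 1e-12)] = 1.0
        p[zero_var & (np.abs(diff) > 1e-12)] = 0.0
        q[zero_var] = np.where(np.abs(diff[zero_var]) > 1e-12, np.inf, 0.0)
        todo = ~zero_var
        if todo.any():
            kd = np.stack([k_j[todo], df_j[todo]], axis=1)
            for (kk, dd) in np.unique(kd, axis=0):
                sel = todo.copy()
                sel[todo] = (kd[:, 0] == kk) & (kd[:, 1] == dd)
                p[sel] = studentized_range_sf(q[sel], int(kk), float(dd))
        de_parts.append(pd.DataFrame({
            "protein": proteins[m_ok], "cell_line": cell_line,
            "target": groups[j],
            "n_target": n_t.astype(int), "n_control": n_c.astype(int),
            "log2fc": diff, "q_stat": q, "p_tukey": p,
            "significant": p <= alpha,
            "infinite_f": zero_var & (np.abs(diff) > 1e-12),
        }))
    de = (pd.concat(de_parts, ignore_index=True) if de_parts
          else pd.DataFrame(columns=DE_COLUMNS))

    skipped_rows = []
    n_skipped = int((~testable).sum())
    if n_skipped:
        for i in np.flatnonzero(~testable):
            skipped_rows.append({"protein": proteins[i], "cell_line": cell_line,
                                 "reason": "min_obs"})
        logger.info("cell line %s: %d protein(s) failed the min-obs filter",
                    cell_line, n_skipped)
    skipped = pd.DataFrame(skipped_rows, columns=["protein", "cell_line", "reason"])
    return de[DE_COLUMNS], anova, skipped


def differential_abundance(pm: ProteinMatrix, config: RunConfig | None = None,
                           control: str = CONTROL_SIRNA):
    """QC-filter then run per-cell-line ANOVA + Tukey over the whole matrix.

    Returns ``(de, anova, skipped, qc_report)``.  With
    ``config.pool_cell_lines_anova`` the ANOVA pools all groups across cell
    lines instead (contrast labels then carry the pooled pseudo-line "all").
    """
    config = config or RunConfig()
    pm, qc = qc_filter_samples(pm, config.qc_min_proteins)
    if config.pool_cell_lines_anova:
        pooled = ProteinMatrix(
            pm.values,
            pm.samples.assign(
                target=pm.samples["target"].where(
                    pm.samples["target"] == control,
                    pm.samples["target"] + "@" + pm.samples["cell_line"]),
                cell_line="all"),
        )
        lines = ["all"]
        pm = pooled
    else:
        lines = sorted(pm.samples["cell_line"].unique())
    de, anova, skipped = [], [], []
    for line in lines:
        d, a, s = anova_tukey(pm, line, control=control,
                              alpha=config.alpha, min_obs=config.min_obs_per_group)
        de.append(d); anova.append(a); skipped.append(s)
    return (pd.concat(de, ignore_index=True),
            pd.concat(anova, ignore_index=True),
            pd.concat(skipped, ignore_index=True),
            qc)


def target_self_effect(de: pd.DataFrame, target_gene_map: dict) -> pd.DataFrame:
    """The targeted protein's own log2FC in each knockdown.

    ``target_gene_map`` maps each target siRNA to the protein it silences.
    Targets whose protein never passed testing are recorded as not quantified.
    """
    rows = []
    for (target, line), sub in de.groupby(["target", "cell_line"], sort=True):
        gene = target_gene_map.get(target)
        hit = sub[sub["protein"] == gene] if gene is not None else sub.iloc[0:0]
        if gene is None or hit.empty:
            rows.append({"target": target, "cell_line": line, "protein": gene,
                         "log2fc": np.nan, "quantified": False})
        else:
            rows.append({"target": target, "cell_line": line, "protein": gene,
                         "log2fc": float(hit["log2fc"].iloc[0]),
                         "quantified": True})
    return pd.DataFrame(rows, columns=["target", "cell_line", "protein",
                                       "log2fc", "quantified"])
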