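"""Cross-modal integration: phenotype-enrichment correlation and top-tier calls.

Assay effect sizes (the mixed-model marginal means per siRNA and cell line)
are correlated against per-term enrichment scores across knockdowns with
Spearman's rho; LPS-induced NFkB readouts are excluded because the proteomes
were collected without LPS induction.  A target is "top-tier" when it has at
least one phenotypic assay hit and at least one biodomain whose proteomic
signature significantly reverses the disease signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .stats import bh_adjust, spearman_rho

logger = logging.getLogger(__name__)

CORR_COLUMNS = ["assay", "term", "n_obs", "rho", "p", "p_adj", "significant"]

VERDICT_COLUMNS = ["target", "n_assay_hits", "hit_assays", "n_reversal_domains",
                   "reversal_domains", "n_phenotype_term_links", "top_tier"]


def _exclude_lps(effects: pd.DataFrame) -> pd.DataFrame:
    dosed = effects["dose"].fillna(0.0) > 0
    if dosed.any():
        logger.info("excluding %d LPS-dosed effect rows from integration",
                    int(dosed.sum()))
    return effects[~dosed]


def phenotype_nes_correlation(effects: pd.DataFrame,
                              enrichment: pd.DataFrame,
                              config: RunConfig | None = None) -> pd.DataFrame:
    """Spearman correlation of assay effect sizes with term NES.

    ``effects`` is the hit table (one row per assay x target x cell line x
    dose with an ``estimate``); ``enrichment`` is the long knockdown
    enrichment table with ``target``, ``cell_line``, ``set_id``, ``nes``
    columns.  Observations are (target, cell line) points aligned by inner
    join; (assay, term) pairs with fewer than the configured minimum are not
    tested, and constant vectors are excluded from the BH family.
    """
    config = config or RunConfig()
    eff = _exclude_lps(effects)
    rows = []
    enr = enrichment.dropna(subset=["nes"])
    for assay, asub in eff.groupby("assay", sort=True):
        merged = asub.merge(enr, on=["target", "cell_line"], how="inner")
        for term, tsub in merged.groupby("set_id", sort=True):
            x = tsub["estimate"].to_numpy(dtype=float)
            y = tsub["nes"].to_numpy(dtype=float)
            rec = {"assay": assay, "term": term, "n_obs": len(tsub)}
            if (len(tsub) < config.min_integration_obs
                    or np.unique(x).size < 2 or np.unique(y).size < 2):
                rec.update({"rho": np.nan, "p": np.nan, "tested": False})
            else:
                rho, p = spearman_rho(x, y)
                rec.update({"rho": rho, "p": p, "tested": bool(np.isfinite(rho))})
            rows.append(rec)
    out = pd.DataFrame(rows, columns=["assay", "term", "n_obs", "rho", "p",
                                      "tested"])
    out["p_adj"] = np.nan
    tested = out["tested"].to_numpy(dtype=bool) if not out.empty else np.array([], bool)
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["significant"] = tested & (out["p_adj"] <= config.alpha)
    return out[CORR_COLUMNS]


@dataclass
class TopTierRule:
    """The explicit boolean rule behind a top-tier call.

    Defaults encode: at least one assay hit in any cell line AND at least one
    biodomain with a significant disease-signature reversal in any cell line.
    ``require_reversal_direction=False`` relaxes the proteomic side to any
    significant domain correlation regardless of sign; ``domain_whitelist``
    restricts which domains may count as proteomic evidence.
    """

    min_assay_hits: int = 1
    min_reversal_domains: int = 1
    require_reversal_direction: bool = True
    domain_whitelist: tuple[str, ...] | None = None

    @classmethod
    def from_config(cls, config: RunConfig) -> "TopTierRule":
        return cls(min_assay_hits=config.min_assay_hits,
                   min_reversal_domains=config.min_reversal_domains,
                   require_reversal_direction=config.require_reversal_direction,
                   domain_whitelist=config.domain_whitelist)


def call_top_tier(effects: pd.DataFrame, domain_concordance: pd.DataFrame,
                  rule: TopTierRule | None = None,
                  phenotype_corr: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-target verdicts combining phenotypic and proteomic evidence.

    ``effects`` must carry ``hit`` flags; ``domain_concordance`` carries the
    per-(target, cell line, biodomain) direction labels.  The phenotype-term
    correlation table, when given, only annotates the count of significant
    links for assays in which the target is a hit (descriptive).
    """
    rule = rule or TopTierRule()
    dc = domain_concordance
    if rule.domain_whitelist is not None and not dc.empty:
        dc = dc[dc["biodomain"].isin(rule.domain_whitelist)]
    targets = sorted(set(effects["target"]) | set(dc["target"] if not dc.empty else []))
    rows = []
    for target in targets:
        esub = effects[(effects["target"] == target) & effects["hit"]]
        hit_assays = sorted(set(
            f"{a}" + (f"@{d:g}" if pd.notna(d) and d else "")
            for a, d in zip(esub["assay"], esub["dose"])))
        n_hits = len(esub)
        if dc.empty:
            dsub = dc
        elif rule.require_reversal_direction:
            dsub = dc[(dc["target"] == target) & (dc["direction"] == "reversal")]
        else:
            dsub = dc[(dc["target"] == target) & (dc["direction"] != "none")]
        domains = sorted(set(dsub["biodomain"])) if not dsub.empty else []
        n_links = 0
        if phenotype_corr is not None and not phenotype_corr.empty and hit_assays:
            assays_hit = set(esub["assay"])
            n_links = int(phenotype_corr[
                phenotype_corr["significant"]
                & phenotype_corr["assay"].isin(assays_hit)].shape[0])
        rows.append({
            "target": target,
            "n_assay_hits": n_hits,
            "hit_assays": ";".join(hit_assays),
            "n_reversal_domains": len(domains),
            "reversal_domains": ";".join(domains),
            "n_phenotype_term_links": n_links,
            "top_tier": bool(n_hits >= rule.min_assay_hits
                             and len(domains) >= rule.min_reversal_domains),
        })
    return pd.DataFrame(rows, columns=VERDICT_COLUMNS)
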