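"""Disease-signature concordance and reversal scoring.

A perturbation's enrichment signature is compared against the disease
signature three ways:

* per-biodomain Kendall tau-b on zero-imputed NES pairs (a term that is
  non-significant or absent on one side contributes NES 0 there);
* per-biodomain Pearson correlation of protein-level log2 fold changes
  against the disease effect of the orthologous protein;
* quadrant classification of terms by the sign pattern of the paired NES.

A domain with a significantly negative correlation is labeled a "reversal":
the knockdown pushes the domain's terms opposite to their disease direction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import BiodomainMap, GeneSetCollection
from .stats import bh_adjust, kendall_tau_b, pearson_r

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["term", "biodomain", "nes_perturbation", "nes_disease"]


def zero_impute_pairs(results_perturbation: pd.DataFrame,
                      results_disease: pd.DataFrame,
                      bdmap: BiodomainMap,
                      sig_threshold: float = 0.05) -> pd.DataFrame:
    """Pair the two enrichment analyses term-by-term with zero imputation.

    The table covers the union of terms significant (adjusted p <= threshold)
    in either analysis; a term that is non-significant or absent on one side
    gets NES 0 there.  Terms mapped to several domains appear once per
    domain; unmapped terms appear under "none".
    """
    def _sig(res: pd.DataFrame) -> pd.DataFrame:
        if res.empty:
            return res
        return res[res["p_adj"] <= sig_threshold]

    sig_a, sig_b = _sig(results_perturbation), _sig(results_disease)
    union = sorted(set(sig_a["set_id"]) | set(sig_b["set_id"]))
    if not union:
        logger.warning("zero_impute_pairs: no term significant in either analysis")
        return pd.DataFrame(columns=PAIR_COLUMNS)
    nes_a = dict(zip(sig_a["set_id"], sig_a["nes"]))
    nes_b = dict(zip(sig_b["set_id"], sig_b["nes"]))
    rows = []
    for term in union:
        domains = bdmap.domains_of(term) or ("none",)
        for d in domains:
            rows.append({"term": term, "biodomain": d,
                         "nes_perturbation": float(nes_a.get(term, 0.0)),
                         "nes_disease": float(nes_b.get(term, 0.0))})
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def domain_kendall(pair_table: pd.DataFrame, alpha: float = 0.05,
                   min_terms: int = 5,
                   group_cols=("target", "cell_line")) -> pd.DataFrame:
    """Kendall tau-b per biodomain between the paired NES vectors.

    ``pair_table`` may carry extra grouping columns (target, cell line);
    one tau per (group, biodomain).  Degenerate domains (fewer than
    ``min_terms`` pairs, or a constant vector on either side) are emitted
    untested and excluded from the BH family.  Direction labels:
    "reversal" when significant with tau < 0, "concordant" when significant
    with tau > 0, "none" otherwise.
    """
    keys = [c for c in group_cols if c in pair_table.columns] + ["biodomain"]
    rows = []
    for key, sub in pair_table.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        x = sub["nes_perturbation"].to_numpy(dtype=float)
        y = sub["nes_disease"].to_numpy(dtype=float)
        rec = dict(zip(keys, key))
        rec["n_terms"] = len(sub)
        if (len(sub) < min_terms or np.unique(x).size < 2
                or np.unique(y).size < 2):
            rec.update({"tau": np.nan, "p": np.nan, "tested": False})
        else:
            tau, p = kendall_tau_b(x, y)
            rec.update({"tau": tau, "p": p, "tested": bool(np.isfinite(tau))})
        rows.append(rec)
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=[*keys, "n_terms", "tau", "p", "tested",
                                     "p_adj", "direction"])
    out["p_adj"] = np.nan
    tested = out["tested"].to_numpy(dtype=bool)
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    sig = tested & (out["p_adj"].to_numpy() <= alpha)
    out["direction"] = "none"
    out.loc[sig & (out["tau"] < 0), "direction"] = "reversal"
    out.loc[sig & (out["tau"] > 0), "direction"] = "concordant"
    return out


def proteins_by_domain(collection: GeneSetCollection,
                       bdmap: BiodomainMap) -> dict[str, set]:
    """Proteins grouped into biodomains via annotation to any domain term."""
    out: dict[str, set] = {}
    for set_id in collection:
        for d in bdmap.domains_of(set_id):
            out.setdefault(d, set()).update(collection.genes(set_id))
    return out


def resolve_orthologs(ortholog_map: pd.DataFrame):
    """One-to-one human<->mouse pairs; ambiguous genes dropped and counted.

    Returns ``(mapping, report)`` where mapping is mouse id -> human id and
    report counts dropped one-to-many pairs.
    """
    hm = ortholog_map.drop_duplicates()
    amb_h = hm["human"].duplicated(keep=False)
    amb_m = hm["mouse"].duplicated(keep=False)
    keep = hm[~(amb_h | amb_m)]
    dropped = int((amb_h | amb_m).sum())
    if dropped:
        logger.info("ortholog map: dropped %d ambiguous pair(s)", dropped)
    report = pd.DataFrame({"dropped_ambiguous_pairs": [dropped],
                           "kept_pairs": [len(keep)]})
    return dict(zip(keep["mouse"], keep["human"])), report


def domain_protein_pearson(de: pd.DataFrame, disease_effects: pd.DataFrame,
                           ortholog_map: pd.DataFrame,
                           collection: GeneSetCollection,
                           bdmap: BiodomainMap,
                           alpha: float = 0.05,
                           min_proteins: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein-level Pearson correlation per (target, cell line, biodomain).

    For each domain, the knockdown log2FCs of the domain's proteins are
    correlated with the disease effect of the orthologous protein.  BH runs
    across all tested rows; one-to-many ortholog pairs are dropped.
    """
    mouse_to_human, ortho_report = resolve_orthologs(ortholog_map)
    effect = dict(zip(disease_effects["gene"], disease_effects["effect"]))
    domains = proteins_by_domain(collection, bdmap)
    rows = []
    for (target, line), sub in de.groupby(["target", "cell_line"], sort=True):
        fc = dict(zip(sub["protein"], sub["log2fc"]))
        for domain in sorted(domains):
            xs, ys = [], []
            for prot in domains[domain]:
                if prot not in fc:
                    continue
                human = mouse_to_human.get(prot)
                if human is None or human not in effect:
                    continue
                xs.append(fc[prot])
                ys.append(effect[human])
            rec = {"target": target, "cell_line": line, "biodomain": domain,
                   "n_proteins": len(xs)}
            if (len(xs) < min_proteins or np.unique(xs).size < 2
                    or np.unique(ys).size < 2):
                rec.update({"r": np.nan, "p": np.nan, "tested": False})
            else:
                r, p = pearson_r(xs, ys)
                rec.update({"r": r, "p": p, "tested": True})
            rows.append(rec)
    out = pd.DataFrame(rows, columns=["target", "cell_line", "biodomain",
                                      "n_proteins", "r", "p", "tested"])
    out["p_adj"] = np.nan
    tested = out["tested"].to_numpy(dtype=bool)
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["significant"] = tested & (out["p_adj"] <= alpha)
    return out, ortho_report


def quadrant_counts(pair_table: pd.DataFrame,
                    group_cols=("target", "cell_line")) -> pd.DataFrame:
    """Count terms per biodomain by the sign pattern of the paired NES.

    Classes: up/up, down/down (concordant), up/down, down/up (reversed),
    and one-sided (NES 0 on either side).  Counts sum to the number of
    terms considered.
    """
    keys = [c for c in group_cols if c in pair_table.columns] + ["biodomain"]
    rows = []
    for key, sub in pair_table.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        a = sub["nes_perturbation"].to_numpy(dtype=float)
        b = sub["nes_disease"].to_numpy(dtype=float)
        one_sided = (a == 0) | (b == 0)
        rec = dict(zip(keys, key))
        rec.update({
            "n_terms": len(sub),
            "up_up": int(((a > 0) & (b > 0)).sum()),
            "down_down": int(((a < 0) & (b < 0)).sum()),
            "up_down": int(((a > 0) & (b < 0)).sum()),
            "down_up": int(((a < 0) & (b > 0)).sum()),
            "one_sided": int(one_sided.sum()),
        })
        rows.append(rec)
    out = pd.DataFrame(rows, columns=[*keys, "n_terms", "up_up", "down_down",
                                      "up_down", "down_up", "one_sided"])
    if not out.empty:
        total = out[["up_up", "down_down", "up_down", "down_up",
                     "one_sided"]].sum(axis=1)
        assert (total == out["n_terms"]).all()
    return out
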