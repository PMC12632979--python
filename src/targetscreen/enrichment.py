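"""Preranked gene-set enrichment.

Genes are ranked by a signed statistic (a knockdown log2 fold change, or a
disease meta-analysis effect).  Each set is scored by the weighted
Kolmogorov-Smirnov running-sum statistic: walking down the ranked list, the
sum rises by ``|stat|^w / sum(|stat|^w over set hits)`` at each set member
and falls by ``1/(N - N_hit)`` at each non-member; the enrichment score (ES)
is the signed extreme of this walk and the leading edge is the set members
up to (positive ES) or from (negative ES) that extreme.

Significance is by gene-label permutation: set labels are reassigned to
random positions, the null ES distribution is split by sign, NES is the ES
divided by the mean |null ES| of the same sign, and p uses the add-one
estimator, so p >= 1/(n_perm + 1).  Ranking ties are broken by gene id,
making every result deterministic for a given seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import BiodomainMap, GeneSetCollection
from .stats import bh_adjust

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["set_id", "size", "es", "nes", "p", "p_adj",
                  "biodomains", "leading_edge"]


@dataclass
class RankedList:
    """A descending-sorted ranking of unique genes by a signed statistic."""

    genes: np.ndarray
    stats: np.ndarray

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        genes = np.asarray(s.index, dtype=object)
        stats = np.asarray(s.to_numpy(), dtype=float)
        if len(set(genes)) != len(genes):
            raise ValueError("ranking contains duplicate genes")
        if not np.isfinite(stats).all():
            raise ValueError("ranking statistics must be finite")
        # descending by statistic, ties broken by gene id (deterministic)
        order = np.lexsort((genes, -stats))
        return cls(genes=genes[order], stats=stats[order])

    def __len__(self) -> int:
        return len(self.genes)

    def positions_of(self, gene_set) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.genes)}
        pos = sorted(index[g] for g in gene_set if g in index)
        return np.asarray(pos, dtype=np.int64)


def _es_from_positions(pos: np.ndarray, abs_w: np.ndarray, n: int):
    """ES for one or many position vectors.

    ``pos`` is (k,) or (m, k) of ascending hit positions; ``abs_w`` is the
    (n,) vector of |stat|^weight.  Returns (es, extreme_index) where
    extreme_index is the hit index attaining the extreme (for the 1-D case).
    """
    pos2 = np.atleast_2d(pos)
    m, k = pos2.shape
    miss_denom = n - k
    w = abs_w[pos2]                       # (m, k)
    total = w.sum(axis=1, keepdims=True)
    flat = total[:, 0] <= 0
    if flat.any():                        # all-zero stats in the set: uniform
        w[flat] = 1.0
        total[flat] = float(k)
    hcum = np.cumsum(w, axis=1) / total   # after each hit
    j = np.arange(k)
    if miss_denom > 0:
        miss = (pos2 - j) / miss_denom    # misses seen just before hit j
    else:
        miss = np.zeros_like(hcum)
    after = hcum - miss
    before = np.concatenate([np.zeros((m, 1)), hcum[:, :-1]], axis=1) - miss
    i_max = np.argmax(after, axis=1)
    i_min = np.argmin(before, axis=1)
    best_max = after[np.arange(m), i_max]
    best_min = before[np.arange(m), i_min]
    pick_pos = best_max >= -best_min - 1e-12   # tie -> positive
    es = np.where(pick_pos, best_max, best_min)
    extreme = np.where(pick_pos, i_max, i_min)
    if np.ndim(pos) == 1:
        return float(es[0]), int(extreme[0]), bool(pick_pos[0])
    return es


def running_es(ranked: RankedList, gene_set, weight: float = 1.0):
    """Enrichment score and leading edge of ``gene_set`` in ``ranked``.

    Raises ``ValueError`` on an empty intersection ("no overlap").
    """
    pos = ranked.positions_of(gene_set)
    if pos.size == 0:
        raise ValueError("no overlap between gene set and ranked list")
    if pos.size == len(ranked):
        raise ValueError("gene set covers the entire ranked list")
    abs_w = np.abs(ranked.stats) ** weight
    es, extreme, positive = _es_from_positions(pos, abs_w, len(ranked))
    if positive:
        leading = [str(ranked.genes[p]) for p in pos[: extreme + 1]]
    else:
        leading = [str(ranked.genes[p]) for p in pos[extreme:]]
    return es, leading


def nes_and_p(ranked: RankedList, gene_set, n_perm: int,
              rng: np.random.Generator, weight: float = 1.0) -> dict:
    """Permutation NES and p-value for one gene set.

    Labels are permuted ``n_perm`` times (equivalently: the set is reassigned
    to random positions); NES = ES / mean(|null ES| of the same sign);
    p = (1 + #{null ES at least as extreme, same sign}) / (1 + #same sign).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    pos = ranked.positions_of(gene_set)
    if pos.size == 0:
        raise ValueError("no overlap between gene set and ranked list")
    n = len(ranked)
    k = pos.size
    abs_w = np.abs(ranked.stats) ** weight
    es, extreme, positive = _es_from_positions(pos, abs_w, n)

    null = np.empty(n_perm)
    chunk = max(1, int(2_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        draws = rng.random((m, n)).argpartition(k - 1, axis=1)[:, :k]
        draws.sort(axis=1)
        null[done:done + m] = _es_from_positions(draws, abs_w, n)
        done += m

    same = null > 0 if es >= 0 else null < 0
    n_same = int(same.sum())
    if n_same == 0:
        return {"es": es, "nes": np.nan, "p": 1.0 / (1.0 + n_perm),
                "n_same_sign": 0, "nes_defined": False,
                "leading_edge_index": extreme, "positions": pos}
    mean_mag = np.abs(null[same]).mean()
    nes = es / mean_mag if mean_mag > 0 else np.nan
    extreme_count = int((np.abs(null[same]) >= abs(es)).sum())
    p = (1.0 + extreme_count) / (1.0 + n_same)
    return {"es": es, "nes": float(nes), "p": float(p), "n_same_sign": n_same,
            "nes_defined": bool(np.isfinite(nes)),
            "leading_edge_index": extreme, "positions": pos}


def enrich_collection(ranked: RankedList, collection: GeneSetCollection,
                      bdmap: BiodomainMap | None = None,
                      config: RunConfig | None = None,
                      rng: np.random.Generator | None = None):
    """Score every set in a collection; BH across all tested sets.

    Returns ``(results, skipped)``.  Sets outside the size bounds (after
    intersection with the ranked universe) or with no overlap are skipped
    with a reason.  Biodomain annotation is ";"-joined, "none" when unmapped.
    """
    config = config or RunConfig()
    rng = rng or np.random.default_rng(config.seed)
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    rows, skipped = [], []
    for set_id in sorted(collection):
        genes = collection.genes(set_id)
        pos = ranked.positions_of(genes)
        size = int(pos.size)
        if size == 0:
            skipped.append({"set_id": set_id, "size": size, "reason": "no overlap"})
            continue
        if size < config.min_set_size:
            skipped.append({"set_id": set_id, "size": size, "reason": "too small"})
            continue
        if size > config.max_set_size:
            skipped.append({"set_id": set_id, "size": size, "reason": "too large"})
            continue
        res = nes_and_p(ranked, genes, config.n_permutations, rng,
                        weight=config.gsea_weight)
        if not res["nes_defined"]:
            skipped.append({"set_id": set_id, "size": size,
                            "reason": "nes undefined (no same-sign permutations)"})
        es = res["es"]
        if es >= 0:
            lead = res["positions"][: res["leading_edge_index"] + 1]
        else:
            lead = res["positions"][res["leading_edge_index"]:]
        domains = bdmap.domains_of(set_id) if bdmap is not None else ()
        rows.append({
            "set_id": set_id, "size": size, "es": es, "nes": res["nes"],
            "p": res["p"],
            "biodomains": ";".join(domains) if domains else "none",
            "leading_edge": ",".join(str(ranked.genes[p]) for p in lead),
        })
    if not rows:
        logger.warning("all %d sets were filtered out", len(collection))
        empty = pd.DataFrame(columns=RESULT_COLUMNS)
        return empty, pd.DataFrame(skipped, columns=["set_id", "size", "reason"])
    results = pd.DataFrame(rows)
    results["p_adj"] = bh_adjust(results["p"].to_numpy())
    results = results[RESULT_COLUMNS]
    # emitted invariants
    assert ((np.sign(results["nes"].fillna(0)) * np.sign(results["es"])) >= 0).all()
    return results, pd.DataFrame(skipped, columns=["set_id", "size", "reason"])


def ranking_from_de(de: pd.DataFrame, target: str, cell_line: str) -> pd.Series:
    """Extract the per-protein log2FC ranking for one knockdown contrast."""
    sub = de[(de["target"] == target) & (de["cell_line"] == cell_line)]
    return sub.set_index("protein")["log2fc"].astype(float)
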