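"""Published screen summary counts and the arithmetic defined on them.

The screen drew candidate targets from two hypothesis areas (17 immune, 14
mitochondrial, 2 shared) and reported per-assay hit counts over the candidate
list.  These printed counts are inputs; the functions below recompute the
derived quantities (candidate union, hit-rate percentages) from them.
"""

from __future__ import annotations

import pandas as pd

HYPOTHESIS_AREA_SIZES = {"Immune Response": 17, "Mitochondrial Metabolism": 14}
N_SHARED_TARGETS = 2

#: Targets called a hit in each assay, out of the candidate union.
ASSAY_HIT_COUNTS = {
    "NFkB (LPS induced)": 19,
    "NFkB (uninduced)": 11,
    "MitoTracker": 5,
    "phagocytosis": 3,
    "alamarBlue": 3,
}

#: Targets that were a hit in at least one assay.
N_TARGETS_WITH_ANY_HIT = 25


def candidate_target_count() -> int:
    """Size of the union of the hypothesis-area target lists."""
    return sum(HYPOTHESIS_AREA_SIZES.values()) - N_SHARED_TARGETS


def hit_rate_percent(n_hits: int, n_candidates: int | None = None) -> float:
    """Hit rate as a percentage of the candidate union."""
    n = candidate_target_count() if n_candidates is None else n_candidates
    if n <= 0:
        raise ValueError("candidate count must be positive")
    return 100.0 * n_hits / n


def screen_summary() -> pd.DataFrame:
    """Per-assay and overall hit rates recomputed from the printed counts."""
    n = candidate_target_count()
    rows = [{"assay": a, "n_hits": h, "hit_rate_pct": hit_rate_percent(h, n)}
            for a, h in ASSAY_HIT_COUNTS.items()]
    rows.append({"assay": "any assay", "n_hits": N_TARGETS_WITH_ANY_HIT,
                 "hit_rate_pct": hit_rate_percent(N_TARGETS_WITH_ANY_HIT, n)})
    return pd.DataFrame(rows, columns=["assay", "n_hits", "hit_rate_pct"])
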