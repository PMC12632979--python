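"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive (prefix sums, O(n^2) pair counting,
direct formulas) and shares no code with the package.
"""

import numpy as np


def es_prefix_sum(genes, stats, gene_set, weight=1.0):
    """Enrichment score by walking the ranked list one step at a time."""
    genes = np.asarray(genes, dtype=object)
    stats = np.asarray(stats, dtype=float)
    order = np.lexsort((genes, -stats))  # descending stat, gene-id tiebreak
    genes, stats = genes[order], stats[order]
    member = np.array([g in set(gene_set) for g in genes])
    n, k = len(genes), int(member.sum())
    norm = np.sum(np.abs(stats[member]) ** weight)
    running = 0.0
    best_pos, best_neg = 0.0, 0.0
    for i in range(n):
        if member[i]:
            if norm > 0:
                running += np.abs(stats[i]) ** weight / norm
            else:
                running += 1.0 / k
        else:
            running -= 1.0 / (n - k)
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    # tolerance-based tie-break (positive wins an exact tie)
    return best_pos if best_pos >= -best_neg - 1e-12 else best_neg


def bh_step_up(p):
    """Benjamini-Hochberg step-up adjusted p-values, literal definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for i in range(m - 1, -1, -1):
        val = min(prev, p[order[i]] * m / (i + 1))
        adj[order[i]] = val
        prev = val
    return adj


def kendall_tau_b_pairs(x, y):
    """Tau-b from O(n^2) concordant/discordant pair counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            if s > 0:
                conc += 1
            elif s < 0:
                disc += 1
    n0 = n * (n - 1) / 2

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return np.sum(counts * (counts - 1) / 2)

    n1, n2 = tie_term(x), tie_term(y)
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    return (conc - disc) / denom if denom > 0 else np.nan


def average_ranks(v):
    v = np.asarray(v, dtype=float)
    ranks = np.empty(len(v))
    for i, vi in enumerate(v):
        less = np.sum(v < vi)
        equal = np.sum(v == vi)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_rank_pearson(x, y):
    """Spearman rho as Pearson correlation of average ranks."""
    return pearson_formula(average_ranks(x), average_ranks(y))


def pearson_formula(x, y):
    """Pearson r straight from the covariance formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
    return float(np.sum(xc * yc) / denom) if denom > 0 else np.nan


def reml_log_likelihood(y, X, groups, var_batch, var_resid):
    """Restricted log-likelihood of a random-intercept model, direct formula.

    y = X b + Z u + e with u ~ N(0, var_batch I) per group and
    e ~ N(0, var_resid I); b is profiled out.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    levels = {g: i for i, g in enumerate(dict.fromkeys(groups))}
    Z = np.zeros((n, len(levels)))
    for i, g in enumerate(groups):
        Z[i, levels[g]] = 1.0
    V = var_resid * np.eye(n) + var_batch * (Z @ Z.T)
    sign, logdet_v = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    _, logdet_x = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = r @ Vi @ r
    return -0.5 * (logdet_v + logdet_x + quad + (n - p) * np.log(2 * np.pi))


def one_way_anova_f(groups):
    """Textbook sums-of-squares one-way ANOVA F statistic."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    k = len(groups)
    n = len(all_v)
    return (ssb / (k - 1)) / (ssw / (n - k))
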