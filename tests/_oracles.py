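"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the ANOVA oracle works
from explicit group-mean projections on balanced designs, and the interval
oracle enumerates every base of a toy chromosome.
"""

from itertools import combinations

import numpy as np
import pandas as pd


def balanced_anova_oracle(y, factors):
    """Classical sums-of-squares factorial ANOVA on a balanced design.

    ``factors`` maps factor name -> per-observation level array. Model =
    all main effects + all two-way interactions (no higher terms). Returns
    {term: (F, p, df)} plus residual df, computed purely from group means.
    """
    from scipy import stats

    y = np.asarray(y, dtype=float)
    n = len(y)
    grand = y.mean()
    df = pd.DataFrame({**factors, "_y": y})

    def cell_means(names):
        return df.groupby(list(names), observed=True)["_y"].agg(["mean", "size"])

    names = list(factors)
    ss, dfs = {}, {}
    main_effect = {}
    for a in names:
        g = cell_means([a])
        ss[a] = float((g["size"] * (g["mean"] - grand) ** 2).sum())
        dfs[a] = len(g) - 1
        main_effect[a] = g["mean"] - grand
    for a, b in combinations(names, 2):
        g = cell_means([a, b])
        dev = []
        for (la, lb), row in g.iterrows():
            d = row["mean"] - grand - main_effect[a][la] - main_effect[b][lb]
            dev.append(row["size"] * d**2)
        ss[f"{a}:{b}"] = float(np.sum(dev))
        dfs[f"{a}:{b}"] = (len(main_effect[a]) - 1) * (len(main_effect[b]) - 1)
    total = float(((y - grand) ** 2).sum())
    rss = total - sum(ss.values())
    df_resid = n - 1 - sum(dfs.values())
    out = {}
    for term in ss:
        F = (ss[term] / dfs[term]) / (rss / df_resid)
        out[term] = (F, float(stats.f.sf(F, dfs[term], df_resid)), dfs[term])
    return out, df_resid


def per_base_feature_oracle(islands, shore_flank=2000, chrom_len=100_000):
    """Per-base shore membership on one toy chromosome.

    ``islands`` is a list of (start, end) half-open intervals. A base is a
    shore base iff it lies within ``shore_flank`` of some island's boundary
    flanks and inside no island.
    """
    in_island = np.zeros(chrom_len, dtype=bool)
    near = np.zeros(chrom_len, dtype=bool)
    for s, e in islands:
        in_island[max(s, 0):min(e, chrom_len)] = True
        near[max(s - shore_flank, 0):min(s, chrom_len)] = True
        near[max(e, 0):min(e + shore_flank, chrom_len)] = True
    return near & ~in_island


def per_base_domain_oracle(genes, chrom_len, basal_up=5000, basal_down=1000,
                           max_ext=1_000_000):
    """Per-base regulatory-domain gene membership on one toy chromosome.

    ``genes``: list of (gene_id, tss_1based, strand). Returns
    {gene_id: boolean array over bases} for the extended domains under the
    basal-plus-extension rule.
    """
    basal = {}
    for gid, tss, strand in genes:
        t0 = tss - 1
        if strand == "+":
            bs, be = t0 - basal_up, t0 + basal_down
        else:
            bs, be = t0 - basal_down + 1, t0 + basal_up + 1
        basal[gid] = (max(bs, 0), min(be, chrom_len))
    out = {}
    for gid, (bs, be) in basal.items():
        left = max(bs - max_ext, 0)
        right = min(be + max_ext, chrom_len)
        for oid, (obs, obe) in basal.items():
            if oid == gid:
                continue
            if obs < bs:
                left = max(left, min(obe, bs))
            if obe > be:
                right = min(right, max(obs, be))
        arr = np.zeros(chrom_len, dtype=bool)
        arr[left:right] = True
        out[gid] = arr
    return out


def coordinate_descent_enet(X, y, alpha, l1_ratio, max_iter=10_000, tol=1e-12):
    """Naive cyclic coordinate descent for the elastic net (sklearn objective
    1/(2n)||y - Xb||^2 + alpha*l1*||b||_1 + alpha*(1-l1)/2*||b||^2),
    with intercept handled by centering."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    b = np.zeros(p)
    col_sq = (Xc**2).sum(axis=0) / n
    lam1 = alpha * l1_ratio
    lam2 = alpha * (1 - l1_ratio)
    r = yc - Xc @ b
    for _ in range(max_iter):
        b_old = b.copy()
        for j in range(p):
            r += Xc[:, j] * b[j]
            rho = (Xc[:, j] @ r) / n
            bj = np.sign(rho) * max(abs(rho) - lam1, 0.0) / (col_sq[j] + lam2)
            b[j] = bj
            r -= Xc[:, j] * bj
        if np.max(np.abs(b - b_old)) < tol:
            break
    b0 = ym - xm @ b
    return b0, b
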