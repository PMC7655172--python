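"""Per-CpG factorial ANOVA and multivariate views of a methylation cohort.

Each fully observed locus is analyzed independently by ordinary-least-squares
factorial ANOVA with brain region, strain and (categorical) age as factors,
model = all main effects + all two-way interactions, no three-way term.
Type II sums of squares are used: the SS for a term compares the model of
all terms not containing it against that model plus the term, with the full
model's residual mean square as denominator. Because every locus shares one
design, the projection bases are computed once and applied to the whole
CpG x sample grid at once.

Selection mirrors raw-threshold practice: loci with p(term) below alpha,
no multiplicity correction (the table carries what callers need to correct).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.linalg import orth

from .io import MethylationMatrix

FACTOR_COLUMNS = {"region": "tissue", "strain": "strain", "age": "age"}


def _dummy_block(values: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level as reference)."""
    levels = sorted(pd.unique(values).tolist())
    return np.column_stack([(values == lv).astype(float) for lv in levels[1:]])


def _interaction_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [a[:, [i]] * b for i in range(a.shape[1])], axis=1
    )


def _design_terms(sample_frame: pd.DataFrame) -> dict[str, np.ndarray]:
    """Design-matrix block per retained term; single-level factors dropped."""
    factors = {}
    for term, col in FACTOR_COLUMNS.items():
        vals = sample_frame[col].to_numpy()
        if len(pd.unique(vals)) < 2:
            warnings.warn(f"factor {term!r} has one level; term dropped", stacklevel=3)
            continue
        factors[term] = _dummy_block(vals)
    blocks = dict(factors)
    for a, b in combinations(factors, 2):
        blocks[f"{a}:{b}"] = _interaction_block(factors[a], factors[b])
    return blocks


def _basis(blocks: list[np.ndarray], n: int) -> np.ndarray:
    """Orthonormal basis of span(intercept + blocks); rank-deficiency safe."""
    X = np.concatenate([np.ones((n, 1))] + blocks, axis=1)
    return orth(X)


def per_cpg_anova(m: MethylationMatrix) -> pd.DataFrame:
    """Factorial ANOVA per locus; returns one row per CpG.

    Columns: cpg_id, then F_<term> / p_<term> per retained term
    (region, strain, age and their two-way interactions), df_<term>,
    and df_resid. Requires a fully observed matrix (run
    :func:`tissueclock.io.drop_missing_cpgs` first).
    """
    if m.mask.any():
        raise ValueError("matrix contains missing values; run drop_missing_cpgs first")
    sf = m.sample_frame()
    n = len(m.samples)
    blocks = _design_terms(sf)
    if not blocks:
        raise ValueError("no factor with >= 2 levels; nothing to test")

    terms = list(blocks)
    Q_full = _basis([blocks[t] for t in terms], n)
    rank_full = Q_full.shape[1]
    df_resid = n - rank_full
    if df_resid < 1:
        raise ValueError(
            f"zero residual degrees of freedom (n={n}, model rank={rank_full}); "
            "use a reduced model or more replicates"
        )

    Y = m.values.T  # samples x loci
    total_ss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    rss_full = np.sum(Y**2, axis=0) - np.sum((Q_full.T @ Y) ** 2, axis=0)
    rss_full = np.maximum(rss_full, 0.0)
    mse = rss_full / df_resid

    out = {"cpg_id": m.locus_ids}
    for term in terms:
        # Type II: all terms not containing the tested term's factors
        def contains(other: str) -> bool:
            return set(term.split(":")) <= set(other.split(":"))

        others = [t for t in terms if not contains(t)]
        Q1 = _basis([blocks[t] for t in others], n)
        Q2 = _basis([blocks[t] for t in others + [term]], n)
        df_term = Q2.shape[1] - Q1.shape[1]
        ss = np.sum((Q2.T @ Y) ** 2, axis=0) - np.sum((Q1.T @ Y) ** 2, axis=0)
        ss = np.maximum(ss, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / df_term) / mse
        F = np.where((mse == 0) & (ss == 0), 0.0, F)
        p = stats.f.sf(F, df_term, df_resid)
        p = np.clip(np.where(np.isinf(F), 0.0, p), np.finfo(float).tiny, 1.0)
        out[f"F_{term}"] = F
        out[f"p_{term}"] = p
        out[f"df_{term}"] = df_term
    out["df_resid"] = df_resid
    out["total_ss"] = total_ss
    return pd.DataFrame(out)


def select_cpgs(table: pd.DataFrame, term: str, alpha: float) -> list[str]:
    """Loci with raw p(term) < alpha, sorted ascending by p."""
    col = f"p_{term}"
    if col not in table.columns:
        known = sorted(c[2:] for c in table.columns if c.startswith("p_"))
        raise ValueError(f"unknown term {term!r}; available: {known}")
    hits = table.loc[table[col] < alpha, ["cpg_id", col]]
    return hits.sort_values(col, kind="stable")["cpg_id"].tolist()


def pca_scores(m: MethylationMatrix, n_components: int = 3
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample principal-component scores on centered beta values.

    Centering is per CpG (feature), no variance scaling — beta values share
    a scale. Returns (scores frame indexed by sample_id with columns
    PC1..PCk, explained-variance fractions). Component signs are fixed so
    that each component's largest-magnitude loading is positive.
    """
    if m.mask.any():
        raise ValueError("matrix contains missing values; run drop_missing_cpgs first")
    X = m.values.T  # samples x loci
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds min(n-1, loci)")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("constant matrix: zero variance, no principal components")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic orientation
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U[:, :n_components] * S[:n_components]
    frac = (S**2) / np.sum(S**2)
    df = pd.DataFrame(
        scores, index=pd.Index(m.sample_ids, name="sample_id"),
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return df, frac[:n_components]


def hierarchical_clustering(m: MethylationMatrix, axis: str = "samples",
                            method: str = "ward") -> tuple[np.ndarray, list[str]]:
    """Agglomerative merge tree (scipy linkage matrix) over samples or loci.

    Euclidean distance, Ward linkage by default; deterministic for a fixed
    input order (ties resolved lowest-index-pair first by the distance
    computation order). Returns (linkage matrix with n-1 merges, item labels).
    """
    if m.mask.any():
        raise ValueError("matrix contains missing values; run drop_missing_cpgs first")
    if axis == "samples":
        X, labels = m.values.T, m.sample_ids
    elif axis == "loci":
        X, labels = m.values, m.locus_ids
    else:
        raise ValueError("axis must be 'samples' or 'loci'")
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    return linkage(X, method=method, metric="euclidean"), list(labels)


def cluster_cpgs_by_gene(selected, domains) -> dict[str, int]:
    """Count selected loci inside each gene's regulatory domain.

    ``selected`` is a list of CpGLocus; ``domains`` a RegulatoryDomainSet
    (see :mod:`tissueclock.annotation`). A locus inside several genes'
    domains is counted once per gene.
    """
    counts: dict[str, int] = {}
    for locus in selected:
        for gene in domains.genes_covering(locus.chrom, locus.pos):
            counts[gene] = counts.get(gene, 0) + 1
    return counts
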