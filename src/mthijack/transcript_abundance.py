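"""Expression normalisation, batch correction and group abundance tests.

The workflow mirrors a standard bulk RNA-seq comparison: median-of-ratios
size factors, a log2(x+1) transform of normalised counts, per-gene removal
of additive batch terms fitted by least squares jointly with group terms,
reversal of the log transform with per-gene grand-mean rescaling, and a
two-sided Mann-Whitney test on the pooled per-gene batch-corrected
abundances of the two groups.  The per-gene differential test is the same
rank test with Benjamini-Hochberg adjustment restricted to the supplied
gene list.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Gene x sample counts with gene classes and sample metadata.

    ``gene_classes`` labels each gene ("mtDNA", "nuclear", ...); ``samples``
    is a DataFrame indexed by sample id with columns ``group`` and ``batch``.
    """

    counts: pd.DataFrame
    gene_classes: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not set(self.counts.columns) <= set(self.samples.index):
            raise ValueError("every sample column needs metadata")
        for col in ("group", "batch"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing {col!r}")


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean one."""
    mat = counts.to_numpy(float)
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene is expressed in all samples")
    sub = mat[expressed]
    geo_mean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geo_mean[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalised_log_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(count / size factor + 1) per gene and sample."""
    sf = size_factors(counts)
    return np.log2(counts / sf + 1.0)


# ---------------------------------------------------------------------------
# Batch correction
# ---------------------------------------------------------------------------

def batch_correct(log_abundances: pd.DataFrame, batch_labels: pd.Series,
                  group_labels: pd.Series) -> pd.DataFrame:
    """Remove additive batch terms from log abundances, per gene.

    Fits ``abundance ~ group + batch`` by least squares for each gene,
    subtracts the (sample-mean-centred) fitted batch terms, reverses the
    log transform and rescales so the per-gene grand mean on the original
    scale is preserved.  A single batch is a no-op; a design in which group
    is perfectly confounded with batch raises.
    """
    batch = batch_labels.reindex(log_abundances.columns)
    group = group_labels.reindex(log_abundances.columns)
    if batch.isna().any() or group.isna().any():
        raise ValueError("batch/group labels missing for some samples")
    batches = sorted(batch.unique())
    counts = batch.value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs >= 2 samples")
    original = (2.0 ** log_abundances - 1.0).clip(lower=0)
    if len(batches) == 1:
        return original
    cross = pd.crosstab(group, batch)
    if ((cross > 0).sum(axis=1) < 2).any():
        raise ValueError(
            "group is confounded with batch: each group must span >= 2 batches")

    groups = sorted(group.unique())
    n = len(log_abundances.columns)
    design_cols = [np.ones(n)]
    for g in groups[1:]:
        design_cols.append((group == g).to_numpy(float))
    batch_dummies = [(batch == b).to_numpy(float) for b in batches[1:]]
    design = np.column_stack(design_cols + batch_dummies)
    y = log_abundances.to_numpy(float).T  # samples x genes
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)

    n_group_terms = len(design_cols)
    batch_part = np.column_stack(batch_dummies) @ coef[n_group_terms:]
    batch_part -= batch_part.mean(axis=0, keepdims=True)
    corrected_log = log_abundances - batch_part.T
    corrected = (2.0 ** corrected_log - 1.0).clip(lower=0)
    # preserve the per-gene grand mean on the original scale
    means = corrected.mean(axis=1)
    target = original.mean(axis=1)
    scale = np.where(means > 0, target / means.replace(0, np.nan), 1.0)
    return corrected.mul(pd.Series(scale, index=corrected.index), axis=0)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all group assignments when the pooled sample size
    is <= 16 (handles ties exactly); otherwise the normal approximation
    with tie and continuity corrections.  Returns (U of group a, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each group needs >= 1 value")
    na, nb = len(a), len(b)
    u_obs = _u_statistic(a, b)
    mean_u = na * nb / 2.0

    if na + nb <= 16:
        pooled = np.concatenate([a, b])
        # U via midranks: U_a = R_a - na(na+1)/2 holds with ties, so the
        # exact null enumerates rank sums over every group-a assignment
        ranks = _midranks(pooled)
        combos = _combination_index(na + nb, na)
        u_all = ranks[combos].sum(axis=1) - na * (na + 1) / 2.0
        dev_obs = abs(u_obs - mean_u)
        extreme = (np.abs(u_all - mean_u) >= dev_obs - 1e-12).sum()
        return u_obs, float(extreme / len(u_all))

    pooled = np.concatenate([a, b])
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var_u = na * nb / 12.0 * (n + 1 - tie_term)
    if var_u == 0:
        return u_obs, 1.0
    z = (abs(u_obs - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = float(2 * (1 - _normal_cdf(z)))
    return u_obs, min(p, 1.0)


@functools.lru_cache(maxsize=8)
def _combination_index(n: int, k: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    greater = (a[:, None] > b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float(greater + 0.5 * ties)


def _normal_cdf(z: float) -> float:
    return 0.5 * (1 + math.erf(z / math.sqrt(2)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def group_abundance_change(corrected: pd.DataFrame, samples: pd.DataFrame,
                           group_a: str, group_b: str,
                           gene_classes: pd.Series, gene_class: str = "mtDNA"
                           ) -> tuple[float, float]:
    """Percent change in mean class-gene abundance of group a vs group b.

    Percent change = ``(1 - mean_a / mean_b) * 100`` on group means of
    per-sample mean abundance over the class genes (positive = decrease in
    group a).  The p value is a two-sided Mann-Whitney test on the pooled
    per-gene abundances of the two groups (not the per-sample means).
    """
    genes = gene_classes[gene_classes == gene_class].index
    genes = [g for g in genes if g in corrected.index]
    if not genes:
        raise ValueError(f"no genes of class {gene_class!r}")
    cols_a = samples.index[samples["group"] == group_a]
    cols_b = samples.index[samples["group"] == group_b]
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError("both groups must be non-empty")
    sub = corrected.loc[genes]
    mean_a = sub[cols_a].mean(axis=0).mean()
    mean_b = sub[cols_b].mean(axis=0).mean()
    pct_change = (1.0 - mean_a / mean_b) * 100.0
    _, p = mann_whitney(sub[cols_a].to_numpy().ravel(),
                        sub[cols_b].to_numpy().ravel())
    return float(pct_change), float(p)


def per_gene_differential(corrected: pd.DataFrame, samples: pd.DataFrame,
                          group_a: str, group_b: str,
                          gene_list) -> pd.DataFrame:
    """Per-gene rank test between groups with BH adjustment over gene_list."""
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("gene list must be non-empty")
    missing = [g for g in gene_list if g not in corrected.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    cols_a = samples.index[samples["group"] == group_a]
    cols_b = samples.index[samples["group"] == group_b]
    rows = []
    for gene in gene_list:
        va = corrected.loc[gene, cols_a].to_numpy(float)
        vb = corrected.loc[gene, cols_b].to_numpy(float)
        u, p = mann_whitney(va, vb)
        rows.append({"gene": gene, "U": u, "p": p,
                     "direction": "down" if va.mean() < vb.mean() else "up"})
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
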