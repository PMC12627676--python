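"""Pseudobulk differential expression between predicted clones.

Raw counts are summed per donor x genotype group ("pseudobulk"), genes are
filtered on fragments per million (FPM), and each gene is tested with a
negative-binomial GLM (log link, size-factor offset, donor as fixed-effect
covariate) using a Wald test on the genotype coefficient and
Benjamini-Hochberg adjustment across tested genes. No effect-size
shrinkage is applied.

The dispersion model respects the pseudobulk structure: a group summing n
cells with per-cell NB2 dispersion alpha behaves like NB with dispersion
alpha/n (a sum of n iid NB(mu, alpha) draws is NB(n*mu, alpha/n)), so the
per-gene variance function is mu_j + (alpha/n_j) * mu_j^2 with n_j the
group's cell count. alpha is estimated per gene from the Pearson
chi-square moment equation at the residual degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from statsmodels.stats.multitest import multipletests

LN2 = math.log(2.0)
DISPERSION_FLOOR = 1e-8


class EmptySelectionError(ValueError):
    """No cells selected for pseudobulk aggregation."""


class RankDeficientDesignError(ValueError):
    """The design matrix is rank deficient (collinear columns)."""


@dataclass
class PseudobulkMatrix:
    """Donor x genotype pseudobulk: integer count sums plus group metadata.

    ``meta`` has one row per group with the grouping keys, the number of
    contributing cells and the group library size (total counts).
    """

    counts: pd.DataFrame              # groups x genes, integer sums
    meta: pd.DataFrame                # index = group ids

    @property
    def library_size(self) -> pd.Series:
        return self.meta["library_size"]


def pseudobulk(expr: ad.AnnData, cells: Sequence[str] | None = None,
               group_keys: tuple[str, ...] = ("donor", "genotype")) -> PseudobulkMatrix:
    """Sum raw counts per group (default donor x predicted genotype).

    Column sums over groups equal the summed counts of the contributing
    cells; groups with zero cells simply do not appear.
    """
    adata = expr[list(cells)] if cells is not None else expr
    if adata.n_obs == 0:
        raise EmptySelectionError("no cells selected for pseudobulk")
    for key in group_keys:
        if key not in adata.obs.columns:
            raise KeyError(f"cell metadata lacks grouping key {key!r}")
        if adata.obs[key].isna().any():
            raise ValueError(f"grouping key {key!r} has missing values")
    keys = adata.obs[list(group_keys)].astype(str)
    group_id = keys.agg("|".join, axis=1)
    codes, uniques = pd.factorize(group_id, sort=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    ind = sparse.csr_matrix(
        (np.ones(adata.n_obs), (codes, np.arange(adata.n_obs))),
        shape=(len(uniques), adata.n_obs))
    sums = np.asarray((ind @ X).todense()).astype(np.int64)
    counts = pd.DataFrame(sums, index=pd.Index(uniques, name="group"),
                          columns=adata.var_names)
    meta = keys.assign(group=group_id).drop_duplicates().set_index("group")
    meta = meta.loc[counts.index]
    meta["n_cells"] = pd.Series(group_id).value_counts().reindex(counts.index).values
    meta["library_size"] = counts.sum(axis=1).astype(float)
    return PseudobulkMatrix(counts=counts, meta=meta)


def filter_fpm(pb: PseudobulkMatrix, condition_groups: dict[str, Sequence[str]],
               min_fpm: float = 2.0, min_donor_frac: float = 0.5) -> pd.Index:
    """Genes with >= ``min_fpm`` fragments per million in at least
    ``ceil(min_donor_frac * n)`` donors of either condition.

    FPM = count / group library size x 1e6. ``condition_groups`` maps the
    two condition names to their pseudobulk group ids (one per donor).
    """
    if len(condition_groups) != 2:
        raise ValueError("exactly two condition group sets are required")
    for cond, groups in condition_groups.items():
        if len(groups) == 0:
            raise ValueError(f"condition {cond!r} has zero donors")
    lib = pb.library_size
    if (lib <= 0).any():
        raise ValueError("all pseudobulk groups need positive library size")
    fpm = pb.counts.div(lib, axis=0) * 1e6
    keep = np.zeros(pb.counts.shape[1], dtype=bool)
    for groups in condition_groups.values():
        sub = fpm.loc[list(groups)]
        need = math.ceil(min_donor_frac * len(groups))
        keep |= ((sub >= min_fpm).sum(axis=0) >= need).to_numpy()
    return pb.counts.columns[keep]


def size_factors(counts: pd.DataFrame, min_usable_genes: int = 10) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference.

    Genes with any zero count are excluded from the reference; when fewer
    than ``min_usable_genes`` remain, library-size factors (normalized to
    geometric mean 1) are used instead.
    """
    mat = counts.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=0)
    if usable.sum() >= min_usable_genes:
        logref = np.log(mat[:, usable]).mean(axis=0)
        sf = np.exp(np.median(np.log(mat[:, usable]) - logref, axis=1))
    else:
        lib = mat.sum(axis=1)
        sf = lib / np.exp(np.log(lib).mean())
    return pd.Series(sf, index=counts.index, name="size_factor")


def _design_matrix(meta: pd.DataFrame, contrast_key: str, contrast: tuple[str, str],
                   covariate: str | None) -> tuple[np.ndarray, list[str], np.ndarray]:
    test_level, ref_level = contrast
    levels = set(meta[contrast_key].astype(str))
    if not {test_level, ref_level} <= levels:
        raise ValueError(f"contrast levels {contrast} not both present in {contrast_key!r}")
    geno = (meta[contrast_key].astype(str) == test_level).astype(float).to_numpy()
    cols = [np.ones(len(meta)), ]
    names = ["intercept"]
    if covariate is not None:
        dummies = pd.get_dummies(meta[covariate].astype(str), prefix=covariate,
                                 drop_first=True, dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy())
            names.append(c)
    cols.append(geno)
    names.append(contrast_key)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify which columns are linear combinations of the preceding ones
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise RankDeficientDesignError(
            f"design is rank deficient; collinear columns: {bad}")
    return X, names, geno


def nb_de_test(pb: PseudobulkMatrix, genes: Sequence[str] | None = None,
               contrast_key: str = "genotype",
               contrast: tuple[str, str] = ("MUT", "WT"),
               covariate: str | None = "donor") -> pd.DataFrame:
    """Per-gene NB GLM Wald test of the genotype contrast.

    For each gene: a Poisson pilot IRLS fit provides fitted means; the
    per-cell NB2 dispersion alpha is estimated from the Pearson
    chi-square moment equation (floored at 1e-8) under the group-scaled
    variance mu + (alpha/n_cells) * mu^2; the quasi-NB GLM with log link
    and log size-factor offset is then refitted and the genotype
    coefficient tested with a Wald z statistic. P values are BH-adjusted
    over the tested genes.

    Returns a DataFrame with gene, log2 fold change (test vs reference
    level), its standard error, the Wald statistic, p and padj, sorted by
    p value.
    """
    counts = pb.counts if genes is None else pb.counts[list(genes)]
    for level in contrast:
        if (pb.meta[contrast_key].astype(str) == level).sum() < 2:
            raise ValueError(
                f"need >= 2 pseudobulk groups at {contrast_key}={level!r}")
    X, names, _ = _design_matrix(pb.meta, contrast_key, contrast, covariate)
    offset = np.log(size_factors(counts).to_numpy())
    j_geno = len(names) - 1
    df_resid = X.shape[0] - X.shape[1]
    if df_resid < 1:
        raise ValueError("design leaves no residual degrees of freedom")
    if "n_cells" in pb.meta.columns:
        inv_n = 1.0 / pb.meta["n_cells"].to_numpy(dtype=float)
    else:
        inv_n = np.ones(X.shape[0])

    rows = []
    for gene in counts.columns:
        y = counts[gene].to_numpy(dtype=float)
        if (y == 0).all():
            rows.append((gene, 0.0, np.nan, 0.0, 1.0))
            continue
        beta, se = _fit_one_gene(y, X, offset, inv_n, j_geno, df_resid)
        if not np.isfinite(se) or se == 0:
            stat, p = 0.0, 1.0
        else:
            stat = beta / se
            p = 2.0 * stats.norm.sf(abs(stat))
        rows.append((gene, beta / LN2, se / LN2 if np.isfinite(se) else np.nan,
                     stat, min(p, 1.0)))
    res = pd.DataFrame(rows, columns=["gene", "lfc", "se", "stat", "p"])
    res["padj"] = multipletests(res["p"], method="fdr_bh")[1]
    return res.sort_values("p", kind="stable").reset_index(drop=True)


def _irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray, var_fn,
          beta0: np.ndarray | None = None, tol: float = 1e-10,
          max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-link GLM by iteratively reweighted least squares.

    ``var_fn(mu)`` gives the variance function; returns (beta, se, mu)
    with Wald standard errors from the expected information.
    """
    if beta0 is None:
        beta = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)[0]
    else:
        beta = beta0.copy()
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu ** 2 / var_fn(mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            break
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu ** 2 / var_fn(mu)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, np.sqrt(np.diag(cov)), mu


def estimate_dispersion(y: np.ndarray, mu: np.ndarray, inv_n: np.ndarray,
                        df_resid: int) -> float:
    """Per-cell NB2 dispersion from the Pearson chi-square moment equation.

    Solves sum (y - mu)^2 / (mu + alpha * inv_n * mu^2) = df_resid for
    alpha; under-dispersed genes fall to the floor of 1e-8.
    """
    mu = np.maximum(mu, 1e-8)

    def pearson_gap(alpha: float) -> float:
        return float(np.sum((y - mu) ** 2 / (mu + alpha * inv_n * mu ** 2))
                     - df_resid)

    if pearson_gap(0.0) <= 0:
        return DISPERSION_FLOOR
    hi = 1.0
    while pearson_gap(hi) > 0 and hi < 1e12:
        hi *= 10.0
    alpha = optimize.brentq(pearson_gap, 0.0, hi)
    return max(float(alpha), DISPERSION_FLOOR)


def _fit_one_gene(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                  inv_n: np.ndarray, j_geno: int,
                  df_resid: int) -> tuple[float, float]:
    """Coefficient and SE (natural-log scale) of the tested column."""
    try:
        beta, se, mu = _irls(y, X, offset, lambda m: m)  # Poisson pilot
        alpha = estimate_dispersion(y, mu, inv_n, df_resid)
        beta, se, _ = _irls(y, X, offset,
                            lambda m: m + alpha * inv_n * m ** 2, beta0=beta)
        return float(beta[j_geno]), float(se[j_geno])
    except (np.linalg.LinAlgError, ValueError):
        return 0.0, np.nan


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]
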