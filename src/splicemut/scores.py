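"""Niche signature scoring and per-condition score correlation.

Module scores follow the control-gene-binned definition: genes are binned
by average expression across cells, each signature gene draws expression-
matched control genes from its bin, and a cell's score is the mean
expression of the signature genes minus the mean of the pooled control
genes. Scoring is done on a counts-per-10k log-normalized matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


class EmptySignatureError(ValueError):
    """No signature gene is present in the expression matrix."""


def lognormalize(expr: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Counts-per-``scale`` log transform: ln(1 + count/libsize * scale).

    Cells with zero library size cannot be normalized; they are left at
    zero and flagged with a warning.
    """
    X = expr.X
    if sparse.issparse(X):
        X = X.tocsr().astype(np.float64)
        if (X.data < 0).any():
            raise ValueError("counts must be non-negative")
        lib = np.asarray(X.sum(axis=1)).ravel()
    else:
        X = np.asarray(X, dtype=np.float64)
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        lib = X.sum(axis=1)
    zero = lib == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have zero library size; "
                      "their normalized profile is all zero")
    inv = np.where(zero, 0.0, scale / np.where(zero, 1.0, lib))
    if sparse.issparse(X):
        out = sparse.diags(inv) @ X
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(X * inv[:, None])
    norm = ad.AnnData(X=out, obs=expr.obs.copy(), var=expr.var.copy())
    return norm


@dataclass
class ScoreResult:
    """Per-cell signature scores with the parameters that produced them."""

    scores: pd.Series                 # index cell_id
    signature: str
    n_bins: int
    n_ctrl: int
    seed: int
    genes_used: list[str]
    genes_missing: list[str]


class ModuleScorer(BaseEstimator, TransformerMixin):
    """Control-gene-binned signature scorer (fit on a background, then
    transform any cell x gene matrix sharing that gene space).

    ``fit`` bins all genes into ``n_bins`` equal-frequency bins of average
    expression and draws, for each signature gene, ``n_ctrl`` control
    genes with replacement from its bin (seeded); ``transform`` returns
    per-cell scores: mean over signature genes minus mean over the pooled
    control draw. Ties at bin boundaries are broken by stable gene order.
    """

    def __init__(self, genes=(), n_bins: int = 24, n_ctrl: int = 100,
                 random_state: int = 0):
        self.genes = genes
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.random_state = random_state

    def fit(self, X, y=None, var_names=None):
        X, var_names = _as_matrix(X, var_names)
        n_genes = len(var_names)
        if n_genes < self.n_bins:
            raise ValueError(f"need >= n_bins={self.n_bins} genes, got {n_genes}")
        gene_pos = {g: i for i, g in enumerate(var_names)}
        used = [g for g in self.genes if g in gene_pos]
        missing = [g for g in self.genes if g not in gene_pos]
        if missing:
            logger.warning("signature genes absent from matrix, skipped: %s",
                           missing)
        if not used:
            raise EmptySignatureError("no signature gene present in the matrix")
        if len(set(used)) != len(used):
            raise ValueError("signature contains duplicate genes")

        means = np.asarray(X.mean(axis=0)).ravel()
        # equal-frequency bins on mean expression; stable order breaks ties
        order = np.argsort(means, kind="stable")
        ranks = np.empty(n_genes, dtype=int)
        ranks[order] = np.arange(n_genes)
        bins = (ranks * self.n_bins) // n_genes

        rng = np.random.default_rng(self.random_state)
        sig_idx = np.array([gene_pos[g] for g in used])
        ctrl = []
        for gi in sig_idx:
            pool = np.flatnonzero(bins == bins[gi])
            ctrl.append(rng.choice(pool, size=self.n_ctrl, replace=True))
        self.signature_idx_ = sig_idx
        self.control_idx_ = np.concatenate(ctrl)
        self.var_names_ = list(var_names)
        self.genes_used_ = used
        self.genes_missing_ = missing
        self.bins_ = bins
        return self

    def transform(self, X, var_names=None) -> np.ndarray:
        check_is_fitted(self, "signature_idx_")
        X, var_names = _as_matrix(X, var_names)
        if list(var_names) != self.var_names_:
            raise ValueError("gene space differs from the fitted background")
        dense = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
        sig_mean = dense[:, self.signature_idx_].mean(axis=1)
        ctrl_mean = dense[:, self.control_idx_].mean(axis=1)
        return sig_mean - ctrl_mean


def _as_matrix(X, var_names):
    if isinstance(X, ad.AnnData):
        return X.X, list(X.var_names)
    if var_names is None:
        raise ValueError("var_names required when X is not an AnnData")
    return X, list(var_names)


def module_score(norm: ad.AnnData, signature_genes, name: str = "signature",
                 n_bins: int = 24, n_ctrl: int = 100, seed: int = 0) -> ScoreResult:
    """Score one gene signature on a normalized matrix (thin wrapper over
    :class:`ModuleScorer`, fitted and applied on the same matrix)."""
    scorer = ModuleScorer(genes=list(signature_genes), n_bins=n_bins,
                          n_ctrl=n_ctrl, random_state=seed).fit(norm)
    vals = scorer.transform(norm)
    return ScoreResult(
        scores=pd.Series(vals, index=norm.obs_names, name=name),
        signature=name, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed,
        genes_used=scorer.genes_used_, genes_missing=scorer.genes_missing_,
    )


def read_signatures(path) -> dict[str, list[str]]:
    """Read a two-column TSV (signature, gene) into name -> gene list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"signature", "gene"} <= set(df.columns):
        raise ValueError("signature table needs 'signature' and 'gene' columns")
    return {s: g["gene"].tolist() for s, g in df.groupby("signature", sort=False)}


def pcc_by_condition(score_a: pd.Series, score_b: pd.Series,
                     condition: pd.Series) -> pd.DataFrame:
    """Pearson correlation between two per-cell scores, per condition.

    The two-sided p value comes from the t transform
    t = r * sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom. A
    zero-variance score vector leaves r undefined (NaN) for that
    condition.
    """
    idx = score_a.index
    if not (idx.equals(score_b.index) and idx.equals(condition.index)):
        raise ValueError("scores and condition labels must share the same cells")
    rows = []
    for cond, cells in condition.groupby(condition, observed=True).groups.items():
        a = score_a.loc[cells].to_numpy(dtype=float)
        b = score_b.loc[cells].to_numpy(dtype=float)
        n = len(a)
        if n < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 cells")
        if a.std() == 0 or b.std() == 0:
            rows.append((cond, np.nan, n, np.nan, np.nan))
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if abs(r) >= 1.0:
            t = np.inf * np.sign(r)
            p = 0.0
        else:
            t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
            p = 2.0 * stats.t.sf(abs(t), n - 2)
        rows.append((cond, r, n, t, p))
    return pd.DataFrame(rows, columns=["condition", "r", "n", "t", "p"])
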