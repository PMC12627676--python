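"""Cell-type composition tables, probit transformation and one-vs-rest
Fisher enrichment of cell types in a condition versus Control.

Each cell type is compared against all other types of the same general
population (stroma, T cells, HSPCs) between a condition and Control with
a two-sided Fisher exact test; p values are Benjamini-Hochberg adjusted
across cell types within the population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust


class UnknownPopulationError(KeyError):
    """Requested population label absent from the metadata."""


def composition_counts(meta: pd.DataFrame, population: str | None = None,
                       by_donor: bool = False) -> pd.DataFrame:
    """Contingency counts of cells per condition x cell type.

    When ``population`` is given, cells are first restricted to that
    general population (requires a ``population`` column). With
    ``by_donor`` the table is additionally stratified by donor.
    """
    required = {"condition", "cell_type"} | ({"donor"} if by_donor else set())
    missing = required - set(meta.columns)
    if missing:
        raise KeyError(f"cell metadata lacks columns: {sorted(missing)}")
    if population is not None:
        if "population" not in meta.columns:
            raise UnknownPopulationError(
                "metadata has no 'population' column to subset on")
        if population not in set(meta["population"].astype(str)):
            raise UnknownPopulationError(f"unknown population {population!r}")
        meta = meta[meta["population"].astype(str) == population]
    index = ["condition", "donor"] if by_donor else ["condition"]
    table = pd.crosstab([meta[c] for c in index], meta["cell_type"])
    return table


def proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Row-wise proportions of a composition table."""
    return table.div(table.sum(axis=1), axis=0)


def probit_transform(p, n: int | None = None, eps: float | None = None):
    """Standard-normal quantile of a proportion, clamped away from 0/1.

    The continuity adjustment defaults to eps = 1/(2N) with N the group
    size, keeping empty and full categories finite.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    if eps is None:
        if n is None:
            raise ValueError("provide either eps or the group size n")
        eps = 1.0 / (2.0 * n)
    return stats.norm.ppf(np.clip(p, eps, 1.0 - eps))


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    # convention: zero margins give 0 or inf rather than NaN
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)


def one_vs_rest_fisher(table: pd.DataFrame, condition: str,
                       reference: str = "Control") -> pd.DataFrame:
    """One-vs-rest Fisher enrichment of each cell type in ``condition``
    versus ``reference``.

    Per cell type the 2x2 table is [type, rest] x [condition, reference];
    p values are two-sided Fisher exact and BH-adjusted over the cell
    types of the table. Direction is "up" when the type's proportion is
    higher in ``condition`` than in ``reference``.
    """
    for cond in (condition, reference):
        if cond not in table.index:
            raise ValueError(f"condition {cond!r} absent from the table")
    row_c = table.loc[condition]
    row_r = table.loc[reference]
    if row_c.sum() == 0 or row_r.sum() == 0:
        raise ValueError("both conditions need at least one cell")
    rows = []
    for ct in table.columns:
        a, b = int(row_c[ct]), int(row_c.sum() - row_c[ct])
        c, d = int(row_r[ct]), int(row_r.sum() - row_r[ct])
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        orr = _sample_odds_ratio(a, b, c, d)
        prop_c = a / (a + b)
        prop_r = c / (c + d)
        rows.append((ct, condition, orr, p, "up" if prop_c > prop_r else "down"))
    res = pd.DataFrame(rows, columns=["cell_type", "condition", "odds_ratio",
                                      "p", "direction"])
    res["padj"] = bh_adjust(res["p"].to_numpy())
    return res[["cell_type", "condition", "odds_ratio", "p", "padj", "direction"]]


def one_vs_rest_fisher_by_donor(table: pd.DataFrame, condition: str,
                                reference: str = "Control") -> pd.DataFrame:
    """Donor-aggregate variant: donor-level proportions compared with a
    two-sided Mann-Whitney test instead of pooled cell counts, avoiding
    pseudoreplication across cells of the same donor."""
    if not isinstance(table.index, pd.MultiIndex):
        raise ValueError("need a (condition, donor) stratified table")
    props = proportions(table)
    rows = []
    for ct in table.columns:
        x = props.loc[condition][ct].to_numpy(dtype=float)
        y = props.loc[reference][ct].to_numpy(dtype=float)
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append((ct, condition, float(np.median(x) - np.median(y)), p))
    res = pd.DataFrame(rows, columns=["cell_type", "condition",
                                      "median_prop_diff", "p"])
    res["padj"] = bh_adjust(res["p"].to_numpy())
    res["direction"] = np.where(res["median_prop_diff"] > 0, "up", "down")
    return res
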