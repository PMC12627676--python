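"""Ligand-receptor cell-pair interaction scoring and condition shift tests.

For a sender cell s and receiver cell r, the score of a ligand-receptor
entry (L, R) is the product expr_L(s) * expr_R(r) on the normalized
matrix. Cell pairs are formed within donors (sender-type cell x
receiver-type cell), pairs with fewer than 5 nonzero ligand-receptor
scores are removed, and retained-pair counts are normalized by the number
of possible pairs (n_sender x n_receiver within each donor). Condition
shifts in sender-receiver usage are tested with Fisher's exact test on
retained versus non-retained possible pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

logger = logging.getLogger(__name__)


class EmptyLRIntersectionError(ValueError):
    """No ligand-receptor pair maps into the expression matrix."""


def read_lr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("LR table needs 'ligand' and 'receptor' columns")
    if df.duplicated(["ligand", "receptor"]).any():
        raise ValueError("duplicate ligand-receptor pairs in table")
    return df


@dataclass
class PairInteractions:
    """Sampled sender-receiver cell pairs with per-LR score vectors."""

    pairs: pd.DataFrame               # sender_cell, receiver_cell, donor, types
    scores: np.ndarray                # n_pairs x n_LR, >= 0
    lr_table: pd.DataFrame            # ligand, receptor rows used

    @property
    def n_nonzero(self) -> np.ndarray:
        return (self.scores > 0).sum(axis=1)


def lr_scores(norm: ad.AnnData, lr_table: pd.DataFrame,
              sender_types: Sequence[str], receiver_types: Sequence[str],
              max_pairs_per_donor: int | None = None,
              seed: int = 0) -> PairInteractions:
    """Score ligand-receptor products over within-donor cell pairs.

    All sender-type x receiver-type cell pairs within each donor are
    formed (exhaustively, or uniformly subsampled without replacement to
    ``max_pairs_per_donor``, seeded). LR entries whose ligand or receptor
    is absent from the matrix are dropped with a log message.
    """
    genes = set(norm.var_names)
    present = lr_table[lr_table["ligand"].isin(genes)
                       & lr_table["receptor"].isin(genes)].reset_index(drop=True)
    n_dropped = len(lr_table) - len(present)
    if n_dropped:
        logger.warning("%d LR pairs missing from the matrix, dropped", n_dropped)
    if present.empty:
        raise EmptyLRIntersectionError("no LR pair maps into the gene space")

    X = norm.X
    dense = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    col = {g: i for i, g in enumerate(norm.var_names)}
    lig_idx = present["ligand"].map(col).to_numpy()
    rec_idx = present["receptor"].map(col).to_numpy()

    obs = norm.obs
    rng = np.random.default_rng(seed)
    s_rows, r_rows = [], []
    for donor in pd.unique(obs["donor"]):
        in_d = obs["donor"] == donor
        send = np.flatnonzero(in_d & obs["cell_type"].isin(sender_types))
        recv = np.flatnonzero(in_d & obs["cell_type"].isin(receiver_types))
        n_pairs = len(send) * len(recv)
        if n_pairs == 0:
            continue
        if max_pairs_per_donor is not None and n_pairs > max_pairs_per_donor:
            flat = rng.choice(n_pairs, size=max_pairs_per_donor, replace=False)
            flat.sort()
            s_rows.append(send[flat // len(recv)])
            r_rows.append(recv[flat % len(recv)])
        else:
            si, ri = np.meshgrid(send, recv, indexing="ij")
            s_rows.append(si.ravel())
            r_rows.append(ri.ravel())
    if not s_rows:
        pairs = pd.DataFrame(columns=["sender_cell", "receiver_cell", "donor",
                                      "sender_type", "receiver_type"])
        return PairInteractions(pairs, np.zeros((0, len(present))), present)
    s_idx = np.concatenate(s_rows)
    r_idx = np.concatenate(r_rows)
    scores = dense[s_idx][:, lig_idx] * dense[r_idx][:, rec_idx]
    pairs = pd.DataFrame({
        "sender_cell": np.asarray(norm.obs_names)[s_idx],
        "receiver_cell": np.asarray(norm.obs_names)[r_idx],
        "donor": obs["donor"].to_numpy()[s_idx],
        "sender_type": obs["cell_type"].astype(str).to_numpy()[s_idx],
        "receiver_type": obs["cell_type"].astype(str).to_numpy()[r_idx],
    })
    return PairInteractions(pairs=pairs, scores=scores, lr_table=present)


def filter_min_interactions(pi: PairInteractions, min_n: int = 5) -> PairInteractions:
    """Remove cell pairs with fewer than ``min_n`` nonzero LR scores."""
    keep = pi.n_nonzero >= min_n
    return replace(pi, pairs=pi.pairs[keep].reset_index(drop=True),
                   scores=pi.scores[keep])


def summarize_interactions(pi: PairInteractions, meta: pd.DataFrame,
                           condition_of_donor: pd.Series | None = None) -> pd.DataFrame:
    """Retained-pair counts per donor, sender type and receiver type,
    normalized by the possible pairs of that donor.

    The possible-pair denominator is n_sender_cells x n_receiver_cells
    within the donor (from ``meta``: index cell_id, columns donor and
    cell_type). A zero-cell denominator leaves the normalized value
    missing. Condition-level aggregation pools donors as a ratio of sums.
    """
    required = {"donor", "cell_type"}
    if not required <= set(meta.columns):
        raise KeyError(f"meta needs columns {sorted(required)}")
    counts = (pi.pairs.groupby(["donor", "sender_type", "receiver_type"],
                               observed=True)
              .size().rename("n_retained").reset_index())
    type_counts = meta.groupby(["donor", "cell_type"], observed=True).size()

    sender_types = sorted(pi.pairs["sender_type"].unique()) or []
    receiver_types = sorted(pi.pairs["receiver_type"].unique()) or []
    donors = sorted(meta["donor"].unique())
    grid = pd.MultiIndex.from_product(
        [donors, sender_types, receiver_types],
        names=["donor", "sender_type", "receiver_type"]).to_frame(index=False)
    out = grid.merge(counts, how="left").fillna({"n_retained": 0})
    out["n_retained"] = out["n_retained"].astype(int)
    out["n_possible"] = [
        int(type_counts.get((d, s), 0)) * int(type_counts.get((d, r), 0))
        for d, s, r in out[["donor", "sender_type", "receiver_type"]].itertuples(index=False)
    ]
    out["normalized"] = np.where(out["n_possible"] > 0,
                                 out["n_retained"] / np.maximum(out["n_possible"], 1),
                                 np.nan)
    if condition_of_donor is not None:
        out["condition"] = out["donor"].map(condition_of_donor)
    return out


def aggregate_by_condition(summary: pd.DataFrame) -> pd.DataFrame:
    """Pool donor summaries per condition: sum of retained counts over sum
    of possible pairs."""
    if "condition" not in summary.columns:
        raise KeyError("summary lacks a 'condition' column")
    agg = (summary.groupby(["condition", "sender_type", "receiver_type"],
                           observed=True)[["n_retained", "n_possible"]]
           .sum().reset_index())
    agg["normalized"] = np.where(agg["n_possible"] > 0,
                                 agg["n_retained"] / np.maximum(agg["n_possible"], 1),
                                 np.nan)
    return agg


def interaction_shift_test(summary: pd.DataFrame, sender_type: str,
                           receiver_type: str, condition_a: str,
                           condition_b: str) -> tuple[float, float]:
    """Fisher exact test of retained-pair usage between two conditions.

    The 2x2 table is [retained, possible - retained] x [A, B] for the
    requested sender-receiver pair; returns (odds ratio, two-sided p).
    """
    agg = aggregate_by_condition(summary)
    rows = {}
    for cond in (condition_a, condition_b):
        sel = agg[(agg["condition"] == cond)
                  & (agg["sender_type"] == sender_type)
                  & (agg["receiver_type"] == receiver_type)]
        if sel.empty or sel["n_possible"].iloc[0] == 0:
            raise ValueError(
                f"no possible pairs for {sender_type}->{receiver_type} in {cond!r}")
        ret = int(sel["n_retained"].iloc[0])
        poss = int(sel["n_possible"].iloc[0])
        rows[cond] = (ret, poss - ret)
    table = [list(rows[condition_a]), list(rows[condition_b])]
    orr, p = stats.fisher_exact(table, alternative="two-sided")
    a, b = rows[condition_a]
    c, d = rows[condition_b]
    if b * c == 0:
        orr = np.inf if a * d > 0 else np.nan
    else:
        orr = (a * d) / (b * c)
    return float(orr), float(p)
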