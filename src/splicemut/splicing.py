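"""Mis-splicing events, per-cell cryptic-usage features, coverage filter
and mean imputation.

Each mis-splicing event pairs a canonical splice junction with the cryptic
junction used preferentially in mutant cells. The per-cell feature is the
bounded usage fraction u = cryptic / (cryptic + canonical), defined only
where the event has read coverage in that cell; the signed alternative
(cryptic - canonical) / (cryptic + canonical) is an affine transform of u
and classifier-equivalent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

EVENT_CLASSES = ("A3SS", "SE")

EVENT_TABLE_COLUMNS = (
    "event_id", "gene", "event_class", "canonical_junction", "cryptic_junction",
)


class ShapeMismatchError(ValueError):
    """Canonical and cryptic layers disagree in shape."""


class EmptyMatrixError(ValueError):
    """Operation received a matrix with no cells or no events."""


def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    """Check a mis-splicing event table (one row per event)."""
    missing = set(EVENT_TABLE_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if events["event_id"].duplicated().any():
        raise ValueError("duplicate event_id in event table")
    bad = ~events["event_class"].isin(EVENT_CLASSES)
    if bad.any():
        raise ValueError(
            f"unknown event_class values: {sorted(events.loc[bad, 'event_class'].unique())}")
    same = events["canonical_junction"] == events["cryptic_junction"]
    if same.any():
        raise ValueError("canonical and cryptic junction must differ per event")
    return events


def read_event_table(path) -> pd.DataFrame:
    return validate_event_table(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class UsageMatrix:
    """Cells x events cryptic-usage fractions with a coverage mask.

    ``usage`` is NaN where an event has zero reads in a cell (undefined
    ratio, not zero usage); ``covered_events`` counts covered events per
    cell and drives the classifiability filter.
    """

    usage: np.ndarray                 # float, NaN where uncovered
    covered: np.ndarray               # bool mask, same shape
    covered_events: np.ndarray        # per-cell count of covered events
    cell_ids: pd.Index
    event_ids: pd.Index

    def __post_init__(self):
        if self.usage.shape != self.covered.shape:
            raise ShapeMismatchError("usage and coverage mask differ in shape")
        if self.usage.shape != (len(self.cell_ids), len(self.event_ids)):
            raise ShapeMismatchError("usage shape does not match id vectors")

    @property
    def shape(self) -> tuple[int, int]:
        return self.usage.shape

    def is_complete(self) -> bool:
        return not np.isnan(self.usage).any()


def _dense(layer) -> np.ndarray:
    if sparse.issparse(layer):
        return np.asarray(layer.todense())
    return np.asarray(layer)


def compute_usage(junctions: ad.AnnData) -> UsageMatrix:
    """Per-cell, per-event cryptic-usage fraction u = c / (c + n).

    Entries with zero total coverage are missing (NaN), never zero: an
    uncovered event carries no information about splice-site choice.
    """
    if "canonical" not in junctions.layers or "cryptic" not in junctions.layers:
        raise ValueError("junction matrix needs 'canonical' and 'cryptic' layers")
    canonical = _dense(junctions.layers["canonical"]).astype(np.float64)
    cryptic = _dense(junctions.layers["cryptic"]).astype(np.float64)
    if canonical.shape != cryptic.shape:
        raise ShapeMismatchError(
            f"layer shapes differ: canonical {canonical.shape} vs cryptic {cryptic.shape}")
    if (canonical < 0).any() or (cryptic < 0).any():
        raise ValueError("junction counts must be non-negative")
    total = canonical + cryptic
    covered = total > 0
    usage = np.full(total.shape, np.nan)
    np.divide(cryptic, total, out=usage, where=covered)
    return UsageMatrix(
        usage=usage,
        covered=covered,
        covered_events=covered.sum(axis=1),
        cell_ids=junctions.obs_names.copy(),
        event_ids=junctions.var_names.copy(),
    )


def filter_classifiable(um: UsageMatrix, min_events: int = 2) -> pd.Index:
    """Cells with at least ``min_events`` covered mis-splicing events.

    Cells below the threshold carry too little splicing information to be
    genotyped and are reported unclassified downstream. Order of the
    retained cells follows the input.
    """
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    keep = um.covered_events >= min_events
    return um.cell_ids[keep]


def impute_mean(um: UsageMatrix) -> UsageMatrix:
    """Fill uncovered entries with the per-event mean over covered cells.

    Covered entries are untouched. Events covered in zero cells have no
    defensible fill value; they are dropped with a warning rather than
    filled with a constant.
    """
    if um.usage.size == 0:
        raise EmptyMatrixError("cannot impute an empty usage matrix")
    n_cov = um.covered.sum(axis=0)
    keep = n_cov > 0
    if not keep.all():
        dropped = list(um.event_ids[~keep])
        logger.warning("dropping %d events with zero coverage: %s",
                       len(dropped), dropped)
    usage = um.usage[:, keep].copy()
    covered = um.covered[:, keep]
    with np.errstate(invalid="ignore"):
        col_means = np.nanmean(np.where(covered, usage, np.nan), axis=0)
    fill = np.broadcast_to(col_means, usage.shape)
    usage[~covered] = fill[~covered]
    return UsageMatrix(
        usage=usage,
        covered=covered,
        covered_events=um.covered_events.copy(),
        cell_ids=um.cell_ids,
        event_ids=um.event_ids[keep],
    )
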