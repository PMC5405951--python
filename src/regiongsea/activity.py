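"""Per-sample pathway activity scores.

A pathway's activity in a sample is its enrichment score computed on the
genes ranked by their z-transformed expression *within that sample*: the
samples with the highest ES are those with the highest relative
expression of the set's genes among all samples in the matrix.  The
gene-wise z-transform makes values comparable across genes so a
within-sample ranking is meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import _score_sets
from .expression import ExpressionMatrix
from .geneset import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["ActivityMatrix", "sample_activity", "group_activity_summary"]

_Z_TOL = 1e-6


@dataclass(frozen=True)
class ActivityMatrix:
    """Gene sets x samples per-sample enrichment scores in [-1, 1]."""

    values: pd.DataFrame            # sets x samples
    weight_exponent: float

    @property
    def set_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def sample_activity(
    zm: ExpressionMatrix,
    collection: GeneSetCollection,
    weight_exponent: float = 1.0,
) -> ActivityMatrix:
    """Enrichment score of every set within every sample.

    ``zm`` must be gene-wise z-transformed (row means ~0, population sd
    ~1); anything else raises.  Within each sample genes are ranked
    descending by z-value (ties broken by gene symbol ascending) and the
    running-sum ES is computed with |z|^weight_exponent hit weights —
    the same statistic as the contrast-level engine, applied per sample.
    """
    vals = zm.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    if np.abs(mu).max() > _Z_TOL or np.abs(sd - 1.0).max() > _Z_TOL:
        raise ValueError("input matrix is not gene-wise z-transformed")

    order = np.argsort(np.asarray(zm.gene_symbols))
    genes_sorted = np.asarray(zm.gene_symbols)[order]
    z = vals[order]                                  # (G, S): samples play the list role
    rank_order = np.argsort(-z, axis=0, kind="stable")
    inv_rank = np.empty_like(rank_order)
    np.put_along_axis(inv_rank, rank_order, np.arange(z.shape[0])[:, None], axis=0)
    es = _score_sets(genes_sorted, inv_rank, z, collection, weight_exponent)
    values = pd.DataFrame(es, index=collection.names, columns=zm.sample_ids)
    return ActivityMatrix(values=values, weight_exponent=weight_exponent)


def group_activity_summary(a: ActivityMatrix, annotations: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd/n of activity per set x region x group.

    ``annotations`` is indexed by sample id with group and region
    columns; every sample of the activity matrix must be annotated.  For
    single-sample cells sd is reported as NaN.
    """
    missing = [s for s in a.sample_ids if s not in annotations.index]
    if missing:
        raise ValueError(f"samples missing from annotations: {missing}")
    long = (
        a.values.T
        .join(annotations.loc[a.sample_ids, ["group", "region"]])
        .melt(id_vars=["group", "region"], var_name="set", value_name="activity")
    )
    out = (
        long.groupby(["set", "region", "group"], sort=True)["activity"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan, n="size")
        .reset_index()
    )
    return out
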