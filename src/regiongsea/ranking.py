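"""Welch two-sample t statistics and the signed log-p gene ranking metric.

For a two-group contrast within one brain region, every gene gets a
Welch t statistic S (test group minus reference group, unequal
variances, Welch-Satterthwaite degrees of freedom) and a two-sided
p-value, combined into the ranking metric

    metric = -1 * sign(S) * log10(p)

so genes up in the test group receive a positive metric and genes down a
negative one.  The full gene list sorted descending by this metric is
the input to the running-sum enrichment statistic.

Contrasts are named "test-ref" (e.g. "B-A"): the first-named group is
the test group and a positive metric means higher expression in it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["TestResult", "RankedList", "welch_t", "ranking_metric", "rank_genes"]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class TestResult:
    """Welch t-test outcome: statistic S, Welch-Satterthwaite dof, two-sided p."""

    statistic: float
    dof: float
    pvalue: float


@dataclass(frozen=True)
class RankedList:
    """Genes sorted descending by the ranking metric for one contrast.

    ``contrast`` is (test_group, ref_group, region).  Metric ties are
    broken by gene symbol ascending, so the order is deterministic.
    """

    genes: tuple[str, ...]
    metrics: np.ndarray
    contrast: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metrics):
            raise ValueError("genes and metrics length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def label(self) -> str:
        t, r, region = self.contrast
        return f"{t}-{r}@{region}"

    def to_rnk(self, path: str | Path) -> None:
        """Write the 2-column RNK interchange format (gene<TAB>metric)."""
        with Path(path).open("w", encoding="utf-8") as fh:
            for g, v in zip(self.genes, self.metrics):
                fh.write(f"{g}\t{v:.10g}\n")


def welch_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Welch t-test of test group ``x`` against reference group ``y``.

    S = (mean(x) - mean(y)) / sqrt(var(x)/nx + var(y)/ny) with sample
    (ddof=1) variances; p two-sided.  Both groups need >= 2 values.  When
    both variances are zero and the means are equal the degenerate
    convention S=0, p=1 applies; zero variances with unequal means give
    an infinite statistic and p clamped to the smallest positive float.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires >= 2 values per group")
    s, d, p = _welch_arrays(
        x[None, :], y[None, :]
    )
    return TestResult(statistic=float(s[0]), dof=float(d[0]), pvalue=float(p[0]))


def _welch_arrays(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch t over the last axis of 2-D arrays (rows = genes)."""
    nx, ny = x.shape[-1], y.shape[-1]
    mx, my = x.mean(axis=-1), y.mean(axis=-1)
    vx, vy = x.var(axis=-1, ddof=1), y.var(axis=-1, ddof=1)
    return _welch_from_moments(mx, vx, nx, my, vy, ny)


def _welch_from_moments(
    mx: np.ndarray, vx: np.ndarray, nx: int,
    my: np.ndarray, vy: np.ndarray, ny: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch statistic, dof and two-sided p from per-group moments.

    Handles the degenerate zero-variance cases element-wise: equal means
    give S=0, p=1; unequal means give an infinite S and the smallest
    positive p.
    """
    a = vx / nx
    b = vy / ny
    denom2 = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (mx - my) / np.sqrt(denom2)
        dof = denom2**2 / (a**2 / (nx - 1) + b**2 / (ny - 1))
    degenerate = denom2 == 0
    if np.any(degenerate):
        equal = degenerate & (mx == my)
        unequal = degenerate & (mx != my)
        s = np.where(equal, 0.0, s)
        s = np.where(unequal, np.sign(mx - my) * np.inf, s)
        dof = np.where(degenerate, nx + ny - 2, dof)
    p = 2.0 * stats.t.sf(np.abs(s), dof)
    p = np.clip(p, _TINY, 1.0)
    return s, dof, p


def ranking_metric(t: TestResult) -> float:
    """The signed log-p metric: -1 * sign(S) * log10(p).

    A gene up in the test group (S>0, small p) gets a positive value;
    sign(0) = 0.  Underflowed p=0 is clamped to the smallest positive
    float with a warning.
    """
    p = t.pvalue
    if p <= 0:
        logger.warning("p-value underflow (p=%g); clamping to %g", p, _TINY)
        p = _TINY
    return float(-np.sign(t.statistic) * np.log10(p))


def _metric_from_sp(s: np.ndarray, p: np.ndarray) -> np.ndarray:
    return -np.sign(s) * np.log10(np.clip(p, _TINY, 1.0))


def rank_genes(
    m: ExpressionMatrix, test_group: str, ref_group: str, region: str
) -> RankedList:
    """Rank all genes of one region by the signed log-p Welch metric.

    Genes are sorted descending by metric, ties broken by gene symbol
    ascending.  Both groups need >= 2 samples in the region.
    """
    x_ids = m.samples_in(test_group, region)
    y_ids = m.samples_in(ref_group, region)
    for label, ids in ((test_group, x_ids), (ref_group, y_ids)):
        if len(ids) < 2:
            raise ValueError(
                f"group {label!r} has {len(ids)} sample(s) in region {region!r}; need >= 2"
            )
    # Pre-sorting rows alphabetically makes a stable sort on the metric
    # break ties by gene symbol ascending.
    order = np.argsort(np.asarray(m.gene_symbols))
    genes = np.asarray(m.gene_symbols)[order]
    x = m.values[x_ids].to_numpy(dtype=float)[order]
    y = m.values[y_ids].to_numpy(dtype=float)[order]
    s, _, p = _welch_arrays(x, y)
    metric = _metric_from_sp(s, p)
    idx = np.argsort(-metric, kind="stable")
    return RankedList(
        genes=tuple(genes[idx]),
        metrics=metric[idx],
        contrast=(test_group, ref_group, region),
    )
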