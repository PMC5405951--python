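"""Running-sum enrichment score, phenotype-permutation null, NES and FDR.

The enrichment score (ES) of a gene set on a ranked gene list is the
maximal deviation from zero of a running sum walked down the list:
members of the set (hits) increment the sum by |metric|^w / NR (NR =
sum of |metric|^w over in-list members), non-members decrement it by
1/(N - k).  With w = 1 this is the weighted Kolmogorov-Smirnov-style
statistic of standard GSEA; w = 0 gives the classic unweighted form.

Significance comes from a phenotype-permutation null: sample group
labels are shuffled (group sizes preserved), the full Welch ranking is
recomputed, and every set is scored on each permuted list.  Sharing the
same label shufflings across sets preserves inter-gene correlation in
the null.  ES values are normalised by the mean same-sign null ES (NES)
and false-discovery rates are estimated by comparing each observed NES
against the pooled null NES distribution of all sets.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .geneset import GeneSet, GeneSetCollection, restrict_and_filter
from .ranking import RankedList, _metric_from_sp, _welch_from_moments, rank_genes

logger = logging.getLogger(__name__)

__all__ = [
    "EsProfile",
    "GseaResult",
    "NullDistributions",
    "enrichment_score",
    "phenotype_null",
    "normalize_scores",
    "fdr_q",
    "run_gsea",
]


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EsProfile:
    """Full running-sum profile of one set on one ranked list."""

    es: float
    peak_index: int
    running: np.ndarray
    leading_edge: tuple[str, ...]


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_exponent: float = 1.0
) -> EsProfile:
    """Weighted running-sum enrichment score with leading edge.

    Walks the ranked list once, incrementing at hits by |metric|^w / NR
    and decrementing at misses by 1/(N-k); ES is the running-sum value of
    maximal absolute deviation from zero.  Peak ties take the smallest
    index for positive candidates and the largest for negative ones; an
    exact cross-sign tie resolves positive.  The leading edge contains
    the set members at or before the peak for ES > 0 and at or after it
    for ES < 0.

    If every in-list member has metric zero (NR = 0) the set falls back
    to the unweighted (w = 0) statistic with a warning.
    """
    genes = np.asarray(ranked.genes)
    n = len(genes)
    hit = np.isin(genes, list(gene_set.genes))
    k = int(hit.sum())
    if k == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no gene in the ranked list")
    if k >= n:
        raise ValueError(f"gene set {gene_set.name!r} covers the whole ranked list")

    w = np.abs(ranked.metrics) ** weight_exponent
    nr = w[hit].sum()
    if nr == 0:
        logger.warning(
            "set %s: all in-list metrics zero; falling back to weight_exponent=0",
            gene_set.name,
        )
        w = np.ones(n)
        nr = float(k)

    steps = np.where(hit, w / nr, -1.0 / (n - k))
    running = np.cumsum(steps)

    imax = int(np.argmax(running))                       # first occurrence
    imin = n - 1 - int(np.argmax(running[::-1] == running.min()))  # last occurrence
    vmax, vmin = running[imax], running[imin]
    pos_cand = max(vmax, 0.0)
    neg_cand = min(vmin, 0.0)
    if pos_cand >= -neg_cand and pos_cand > 0:
        es, peak = float(pos_cand), imax
        leading = tuple(genes[:peak + 1][hit[:peak + 1]])
    elif neg_cand < 0:
        es, peak = float(neg_cand), imin
        leading = tuple(genes[peak:][hit[peak:]])
    else:
        es, peak, leading = 0.0, imax, ()
    return EsProfile(es=es, peak_index=peak, running=running, leading_edge=leading)


def _es_batch(pos: np.ndarray, w: np.ndarray, n: int) -> np.ndarray:
    """ES for one set across many ranked lists at once.

    ``pos``: (P, k) hit positions sorted ascending per row; ``w``: the
    corresponding hit weights.  Returns the P enrichment scores using the
    same extremum/tie conventions as :func:`enrichment_score`.
    """
    p_, k = pos.shape
    nr = w.sum(axis=1)
    flat = nr == 0
    if flat.any():
        w = np.where(flat[:, None], 1.0, w)
        nr = np.where(flat, float(k), nr)
    cum = np.cumsum(w, axis=1) / nr[:, None]
    miss = 1.0 / (n - k)
    idx = np.arange(k)
    decrement = (pos - idx) * miss          # misses seen before each hit
    after = cum - decrement                 # running value just after each hit
    before = cum - w / nr[:, None] - decrement  # value just before each hit
    pos_cand = np.maximum(after.max(axis=1), 0.0)
    neg_cand = np.minimum(before.min(axis=1), 0.0)
    return np.where(pos_cand >= -neg_cand, pos_cand, neg_cand)


# ---------------------------------------------------------------------------
# Phenotype-permutation null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullDistributions:
    """Per-set permutation ES values under sample-label shuffling."""

    set_names: tuple[str, ...]
    es: np.ndarray                 # (n_sets, n_perm)
    scheme: str
    seed: int
    exhaustive: bool

    @property
    def n_perm(self) -> int:
        return self.es.shape[1]

    def for_set(self, name: str) -> np.ndarray:
        return self.es[self.set_names.index(name)]


def _assignment_masks(n: int, n1: int, n_perm: int, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Boolean (n, P) test-group membership masks for label shufflings.

    When fewer than ``n_perm`` distinct assignments exist, all of them
    (identity included) are enumerated instead of sampled.
    """
    total = math.comb(n, n1)
    if total <= n_perm:
        logger.info("exhaustive permutation mode: %d distinct assignments", total)
        masks = np.zeros((n, total), dtype=float)
        for j, combo in enumerate(itertools.combinations(range(n), n1)):
            masks[list(combo), j] = 1.0
        return masks, True
    masks = np.zeros((n, n_perm), dtype=float)
    for j in range(n_perm):
        masks[rng.permutation(n)[:n1], j] = 1.0
    return masks, False


def _permuted_rank_arrays(
    m: ExpressionMatrix,
    contrast: tuple[str, str, str],
    n_perm: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Gene order and metric arrays for every label shuffling.

    Returns (genes_sorted, inv_rank (G, P), metric (G, P), exhaustive):
    ``inv_rank[g, j]`` is the 0-based rank position of gene g in
    permutation j; rows of ``genes_sorted`` are alphabetical so stable
    sorting reproduces the tie-break of :func:`ranking.rank_genes`.
    """
    test_group, ref_group, region = contrast
    x_ids = m.samples_in(test_group, region)
    y_ids = m.samples_in(ref_group, region)
    if len(x_ids) < 2 or len(y_ids) < 2:
        raise ValueError(f"contrast {test_group}-{ref_group}@{region}: need >= 2 samples per group")
    order = np.argsort(np.asarray(m.gene_symbols))
    genes_sorted = np.asarray(m.gene_symbols)[order]
    x_all = m.values[x_ids + y_ids].to_numpy(dtype=float)[order]
    n1, n = len(x_ids), len(x_ids) + len(y_ids)

    rng = np.random.default_rng(seed)
    masks, exhaustive = _assignment_masks(n, n1, n_perm, rng)
    n2 = n - n1

    sum1 = x_all @ masks
    sumsq1 = (x_all**2) @ masks
    tot = x_all.sum(axis=1, keepdims=True)
    totsq = (x_all**2).sum(axis=1, keepdims=True)
    mean1 = sum1 / n1
    mean2 = (tot - sum1) / n2
    var1 = np.clip((sumsq1 - n1 * mean1**2) / (n1 - 1), 0.0, None)
    var2 = np.clip(((totsq - sumsq1) - n2 * mean2**2) / (n2 - 1), 0.0, None)
    s, _, p = _welch_from_moments(mean1, var1, n1, mean2, var2, n2)
    metric = _metric_from_sp(s, p)

    rank_order = np.argsort(-metric, axis=0, kind="stable")   # (G, P): gene index at each rank
    inv_rank = np.empty_like(rank_order)
    np.put_along_axis(inv_rank, rank_order, np.arange(metric.shape[0])[:, None], axis=0)
    return genes_sorted, inv_rank, metric, exhaustive


def phenotype_null(
    m: ExpressionMatrix,
    contrast: tuple[str, str, str],
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> NullDistributions:
    """Null ES for every set under sample-label shuffling.

    The same ``n_perm`` shuffled label vectors (group sizes preserved)
    are used for all sets; the full Welch ranking is recomputed per
    shuffle.  If fewer distinct assignments exist than ``n_perm``, all of
    them are enumerated.  Deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes_sorted, inv_rank, metric, exhaustive = _permuted_rank_arrays(
        m, contrast, n_perm, seed
    )
    es = _score_sets(genes_sorted, inv_rank, metric, collection, weight_exponent)
    return NullDistributions(
        set_names=tuple(collection.names),
        es=es,
        scheme="phenotype",
        seed=seed,
        exhaustive=exhaustive,
    )


def _score_sets(
    genes_sorted: np.ndarray,
    inv_rank: np.ndarray,
    metric: np.ndarray,
    collection: GeneSetCollection,
    weight_exponent: float,
) -> np.ndarray:
    """ES of every set on every ranked list encoded by ``inv_rank``."""
    n = len(genes_sorted)
    gene_index = {g: i for i, g in enumerate(genes_sorted)}
    w_full = np.abs(metric) ** weight_exponent
    out = np.empty((len(collection), inv_rank.shape[1]))
    for si, s in enumerate(collection):
        members = np.array(sorted(gene_index[g] for g in s.genes if g in gene_index))
        if members.size == 0:
            raise ValueError(f"gene set {s.name!r} has no gene in the matrix")
        pos = inv_rank[members, :]          # (k, P)
        ws = w_full[members, :]
        srt = np.argsort(pos, axis=0)
        pos_s = np.take_along_axis(pos, srt, axis=0).T
        ws_s = np.take_along_axis(ws, srt, axis=0).T
        out[si] = _es_batch(pos_s, ws_s, n)
    return out


# ---------------------------------------------------------------------------
# Normalisation and FDR
# ---------------------------------------------------------------------------

def normalize_scores(es: float, null_es: np.ndarray) -> tuple[float, float]:
    """Normalised enrichment score and nominal p for one set.

    NES = es / mean(|null ES with the same sign as es|); the nominal p is
    the fraction of same-sign null ES at least as extreme, floored at
    1/(n_perm + 1).  es = 0 gives NES 0, p 1; with no same-sign null
    values NES is a signed infinity sentinel at the p floor.
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise ValueError("empty null distribution")
    floor = 1.0 / (null_es.size + 1)
    if es == 0:
        return 0.0, 1.0
    same = null_es[null_es > 0] if es > 0 else null_es[null_es < 0]
    if same.size == 0:
        logger.warning("no same-sign null ES; NES reported as signed infinity")
        return math.copysign(math.inf, es), floor
    nes = es / np.abs(same).mean()
    p = max(float((np.abs(same) >= abs(es)).mean()), floor)
    return float(nes), p


def _null_nes(null_es: np.ndarray) -> np.ndarray:
    """Normalise each set's null ES by its own same-sign null means."""
    pos = null_es > 0
    neg = null_es < 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pos_mean = np.where(pos, null_es, 0.0).sum(axis=1) / pos.sum(axis=1)
        neg_mean = np.where(neg, -null_es, 0.0).sum(axis=1) / neg.sum(axis=1)
        out = np.zeros_like(null_es)
        out = np.where(pos, null_es / pos_mean[:, None], out)
        out = np.where(neg, null_es / neg_mean[:, None], out)
    return out


def fdr_q(observed_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """GSEA-style FDR q per set from pooled null NES.

    For a set with NES* >= 0, q = [fraction of pooled null NES >= NES*
    among null NES >= 0] / [fraction of observed NES >= NES* among
    observed NES >= 0], clipped to [0, 1]; mirrored for NES* < 0.
    Within each sign, q is made non-increasing in |NES| by a running
    minimum taken from the least extreme set toward the most extreme.
    """
    obs = np.asarray(observed_nes, dtype=float)
    pooled = np.asarray(null_nes, dtype=float).ravel()
    pooled = pooled[np.isfinite(pooled)]
    q = np.empty_like(obs)

    for sign in (1, -1):
        if sign == 1:
            sel = obs >= 0
            null_side = pooled[pooled >= 0]
            obs_side = obs[sel]
        else:
            sel = obs < 0
            null_side = -pooled[pooled <= 0]
            obs_side = -obs[sel]
        if not sel.any():
            continue
        qs = np.empty(obs_side.size)
        for i, v in enumerate(obs_side):
            if null_side.size == 0:
                logger.warning("no null NES on this sign; q set to 0")
                qs[i] = 0.0
                continue
            num = (null_side >= v).mean()
            den = (obs_side >= v).mean()
            if den == 0:            # unreachable: v counts itself
                qs[i] = 0.0
            else:
                qs[i] = min(max(num / den, 0.0), 1.0)
        # enforce q non-increasing in |NES|: running min from least extreme up
        order = np.argsort(obs_side, kind="stable")   # ascending |NES|
        qs[order] = np.minimum.accumulate(qs[order])
        q[sel] = qs
    return q


# ---------------------------------------------------------------------------
# Full per-contrast run
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GseaResult:
    """One gene set's enrichment outcome for one contrast and region."""

    set_name: str
    size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: tuple[str, ...]
    contrast: tuple[str, str, str]


def run_gsea(
    m: ExpressionMatrix,
    test_group: str,
    ref_group: str,
    region: str,
    collection: GeneSetCollection,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 10,
    max_size: int | None = None,
) -> list[GseaResult]:
    """Rank genes, score every retained set, and attach NES / p / FDR q.

    The collection is restricted to the matrix's gene universe and
    filtered at ``min_size`` first.  Results are sorted by NES descending
    (ties by set name).  Deterministic for fixed inputs and seed.
    """
    filtered = restrict_and_filter(collection, m.gene_symbols, min_size=min_size, max_size=max_size)
    if len(filtered) == 0:
        logger.warning("no gene sets retained after filtering; empty result")
        return []
    contrast = (test_group, ref_group, region)
    ranked = rank_genes(m, test_group, ref_group, region)
    profiles = {
        s.name: enrichment_score(ranked, s, weight_exponent=weight_exponent)
        for s in filtered
    }
    null = phenotype_null(
        m, contrast, filtered, n_perm=n_perm, seed=seed, weight_exponent=weight_exponent
    )
    nes = np.empty(len(filtered))
    p_nom = np.empty(len(filtered))
    for i, s in enumerate(filtered):
        nes[i], p_nom[i] = normalize_scores(profiles[s.name].es, null.es[i])
    q = fdr_q(nes, _null_nes(null.es))

    results = [
        GseaResult(
            set_name=s.name,
            size=len(s),
            es=profiles[s.name].es,
            nes=float(nes[i]),
            p_nominal=float(p_nom[i]),
            fdr_q=float(q[i]),
            leading_edge=profiles[s.name].leading_edge,
            contrast=contrast,
        )
        for i, s in enumerate(filtered)
    ]
    results.sort(key=lambda r: (-r.nes, r.set_name))
    return results


def results_to_frame(results: list[GseaResult]) -> pd.DataFrame:
    """GSEA results as the TSV-ready table (leading edge comma-joined)."""
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "size": r.size,
                "ES": r.es,
                "NES": r.nes,
                "p_nominal": r.p_nominal,
                "FDR_q": r.fdr_q,
                "leading_edge": ",".join(r.leading_edge),
            }
            for r in results
        ],
        columns=["set_name", "size", "ES", "NES", "p_nominal", "FDR_q", "leading_edge"],
    )


def frame_to_results(df: pd.DataFrame, contrast: tuple[str, str, str]) -> list[GseaResult]:
    """Rebuild :class:`GseaResult` objects from a results table."""
    out = []
    for _, row in df.iterrows():
        le = row["leading_edge"]
        leading = tuple(str(le).split(",")) if isinstance(le, str) and le else ()
        out.append(
            GseaResult(
                set_name=str(row["set_name"]),
                size=int(row["size"]),
                es=float(row["ES"]),
                nes=float(row["NES"]),
                p_nominal=float(row["p_nominal"]),
                fdr_q=float(row["FDR_q"]),
                leading_edge=leading,
                contrast=contrast,
            )
        )
    return out
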