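"""Cross-region integration: common and region-specific pathway calls.

A contrast is analysed independently in each of the three brain regions
(WM, FC, BG).  A pathway is *common* to a contrast when its FDR q is
below a threshold (default 0.01) in at least two of the three regions,
optionally requiring the qualifying regions' NES to share a sign
(concordance).  A pathway is *specific* to one region when q < 0.01
there and q > 0.25 in both other regions.  Strict inequalities apply at
the boundaries exactly as stated.

The leading-edge gene table pools, over the qualifying pathways, the
genes driving their enrichment, keeping genes whose per-region Welch
p-value passes a cut (default 0.01) in at least one qualifying region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import GseaResult
from .expression import ExpressionMatrix
from .ranking import _welch_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "RegionResults",
    "ConsensusCall",
    "common_pathways",
    "region_specific_pathways",
    "leading_edge_gene_table",
]

REGIONS = ("WM", "FC", "BG")


@dataclass(frozen=True)
class RegionResults:
    """Per-region GSEA results for one contrast (same collection/params)."""

    contrast: tuple[str, str]               # (test_group, ref_group)
    results: dict[str, list[GseaResult]]    # region -> results

    def __post_init__(self) -> None:
        missing = [r for r in REGIONS if r not in self.results]
        if missing:
            raise ValueError(f"missing region results: {missing}")

    def table(self) -> pd.DataFrame:
        """Wide per-set table of NES and q for the three regions."""
        frames = []
        for region in REGIONS:
            rows = {
                r.set_name: (r.nes, r.fdr_q) for r in self.results[region]
            }
            frames.append(
                pd.DataFrame.from_dict(
                    rows, orient="index", columns=[f"NES_{region}", f"q_{region}"]
                )
            )
        out = pd.concat(frames, axis=1, join="inner").sort_index()
        return out

    def leading_edge(self, set_name: str, region: str) -> tuple[str, ...]:
        for r in self.results[region]:
            if r.set_name == set_name:
                return r.leading_edge
        raise KeyError(f"{set_name!r} not in {region} results")


@dataclass(frozen=True)
class ConsensusCall:
    """One pathway's cross-region call for one contrast."""

    set_name: str
    category: str                     # "common" or "specific_<region>"
    direction: int                    # +1 / -1 (0 when discordant and allowed)
    regions: tuple[str, ...]          # regions satisfying the qualifying rule
    nes: dict[str, float]
    q: dict[str, float]


def common_pathways(
    r: RegionResults,
    fdr_threshold: float = 0.01,
    min_regions: int = 2,
    require_concordance: bool = True,
) -> list[ConsensusCall]:
    """Pathways with q < ``fdr_threshold`` in >= ``min_regions`` regions.

    With ``require_concordance`` (default) the qualifying regions' NES
    must share one sign; that sign is the call's direction.
    """
    tab = r.table()
    calls: list[ConsensusCall] = []
    for set_name, row in tab.iterrows():
        qual = [reg for reg in REGIONS if row[f"q_{reg}"] < fdr_threshold]
        if len(qual) < min_regions:
            continue
        signs = {int(np.sign(row[f"NES_{reg}"])) for reg in qual}
        if require_concordance and len(signs) != 1:
            continue
        direction = signs.pop() if len(signs) == 1 else 0
        calls.append(
            ConsensusCall(
                set_name=str(set_name),
                category="common",
                direction=direction,
                regions=tuple(qual),
                nes={reg: float(row[f"NES_{reg}"]) for reg in REGIONS},
                q={reg: float(row[f"q_{reg}"]) for reg in REGIONS},
            )
        )
    return calls


def region_specific_pathways(
    r: RegionResults,
    fdr_in: float = 0.01,
    fdr_out: float = 0.25,
) -> list[ConsensusCall]:
    """Pathways with q < ``fdr_in`` in exactly one region and q >
    ``fdr_out`` in both others."""
    tab = r.table()
    calls: list[ConsensusCall] = []
    for set_name, row in tab.iterrows():
        for reg in REGIONS:
            others = [o for o in REGIONS if o != reg]
            if row[f"q_{reg}"] < fdr_in and all(row[f"q_{o}"] > fdr_out for o in others):
                calls.append(
                    ConsensusCall(
                        set_name=str(set_name),
                        category=f"specific_{reg}",
                        direction=int(np.sign(row[f"NES_{reg}"])),
                        regions=(reg,),
                        nes={r_: float(row[f"NES_{r_}"]) for r_ in REGIONS},
                        q={r_: float(row[f"q_{r_}"]) for r_ in REGIONS},
                    )
                )
    return calls


def calls_to_frame(calls: list[ConsensusCall]) -> pd.DataFrame:
    """Flatten consensus calls into the TSV-ready wide table."""
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "set": c.set_name,
            "category": c.category,
            "direction": c.direction,
            "regions": ",".join(c.regions),
        }
        for reg in REGIONS:
            row[f"NES_{reg}"] = c.nes[reg]
            row[f"q_{reg}"] = c.q[reg]
        rows.append(row)
    cols = ["set", "category", "direction", "regions"] + [
        f"{k}_{reg}" for reg in REGIONS for k in ("NES", "q")
    ]
    return pd.DataFrame(rows, columns=cols)


def leading_edge_gene_table(
    calls: list[ConsensusCall],
    r: RegionResults,
    m: ExpressionMatrix,
    p_cut: float = 0.01,
) -> pd.DataFrame:
    """Pooled leading-edge genes of qualifying pathways, filtered by
    per-region Welch p.

    For every call, the leading edges of its pathway in each qualifying
    region are pooled (union, no duplicates).  Each gene is annotated
    with its Welch p in each region of the contrast; a gene is retained
    when p < ``p_cut`` in at least one region where one of its pathways
    qualified.  Sorted by best (smallest) qualifying p.
    """
    if not calls:
        raise ValueError("no consensus calls supplied")
    test_group, ref_group = r.contrast

    pvals: dict[str, pd.Series] = {}
    for region in REGIONS:
        x_ids = m.samples_in(test_group, region)
        y_ids = m.samples_in(ref_group, region)
        _, _, p = _welch_arrays(
            m.values[x_ids].to_numpy(dtype=float),
            m.values[y_ids].to_numpy(dtype=float),
        )
        pvals[region] = pd.Series(p, index=m.gene_symbols)

    gene_regions: dict[str, set[str]] = {}
    gene_sets: dict[str, set[str]] = {}
    for c in calls:
        for region in c.regions:
            for g in r.leading_edge(c.set_name, region):
                gene_regions.setdefault(g, set()).add(region)
                gene_sets.setdefault(g, set()).add(c.set_name)

    rows = []
    for g, regs in gene_regions.items():
        qualifying = sorted(reg for reg in regs if pvals[reg][g] < p_cut)
        if not qualifying:
            continue
        best_p = min(float(pvals[reg][g]) for reg in qualifying)
        row = {
            "gene": g,
            "best_p": best_p,
            "regions": ",".join(qualifying),
            "pathways": ",".join(sorted(gene_sets[g])),
        }
        for reg in REGIONS:
            row[f"p_{reg}"] = float(pvals[reg][g])
        rows.append(row)
    cols = ["gene", "best_p", "regions", "pathways"] + [f"p_{reg}" for reg in REGIONS]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["best_p", "gene"]).reset_index(drop=True)
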