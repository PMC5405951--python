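"""End-to-end orchestration of the five-contrast, three-region analysis.

The default comparison design covers the disease transitions B-A, C-A,
C-B, D-B and D-C (test group first; positive NES = up in the test
group), each analysed independently in white matter, frontal cortex and
basal ganglia, followed by cross-region consensus calls, a per-contrast
counts summary, and (optionally) the per-sample pathway activity matrix.

One global seed drives everything; per-contrast x region child seeds are
derived with ``numpy.random.SeedSequence([seed, contrast_idx,
region_idx])`` so contrasts are independent yet reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .activity import group_activity_summary, sample_activity
from .consensus import (
    REGIONS,
    RegionResults,
    calls_to_frame,
    common_pathways,
    leading_edge_gene_table,
    region_specific_pathways,
)
from .enrichment import GseaResult, results_to_frame, run_gsea
from .expression import (
    ExpressionMatrix,
    collapse_probes_by_cv,
    read_expression,
    read_probe_map,
    z_transform,
)
from .geneset import GeneSetCollection, read_gmt, restrict_and_filter

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "DEFAULT_CONTRASTS", "analyze_study", "run_pipeline"]

#: The five disease-transition contrasts, test group first.
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("B", "A"), ("C", "A"), ("C", "B"), ("D", "B"), ("D", "C"),
)


@dataclass
class RunConfig:
    """File paths, comparison design and statistical parameters for a run."""

    matrix_path: str
    annotation_path: str
    gmt_path: str
    out_dir: str
    probe_map_path: str | None = None          # None: matrix is already gene-level
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    n_perm: int = 1000
    weight_exponent: float = 1.0
    min_size: int = 10
    seed: int = 0
    fdr_common: float = 0.01
    min_regions: int = 2
    require_concordance: bool = True
    fdr_in: float = 0.01
    fdr_out: float = 0.25
    leading_edge_p_cut: float = 0.01
    activity: bool = True

    def __post_init__(self) -> None:
        for t in (self.fdr_common, self.fdr_in, self.fdr_out):
            if not (0 < t < 1):
                raise ValueError("FDR thresholds must be in (0, 1)")


def child_seed(seed: int, contrast_idx: int, region_idx: int) -> int:
    """Deterministic per-contrast x region seed derived from the global one."""
    import numpy as np

    return int(np.random.SeedSequence([seed, contrast_idx, region_idx]).generate_state(1)[0])


def analyze_study(
    m: ExpressionMatrix,
    collection: GeneSetCollection,
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    min_size: int = 10,
    seed: int = 0,
    fdr_common: float = 0.01,
    min_regions: int = 2,
    require_concordance: bool = True,
    fdr_in: float = 0.01,
    fdr_out: float = 0.25,
) -> tuple[dict[tuple[str, str], RegionResults], dict[tuple[str, str], list], pd.DataFrame]:
    """Run GSEA for every contrast x region and derive consensus calls.

    Returns (region results per contrast, consensus calls per contrast,
    the per-contrast counts table).  The counts table reports, per
    contrast: significant sets per region at ``fdr_common``, common
    calls, and region-specific calls.
    """
    region_results: dict[tuple[str, str], RegionResults] = {}
    calls: dict[tuple[str, str], list] = {}
    count_rows = []
    for ci, (test_group, ref_group) in enumerate(contrasts):
        per_region: dict[str, list[GseaResult]] = {}
        for rj, region in enumerate(REGIONS):
            t0 = time.perf_counter()
            per_region[region] = run_gsea(
                m, test_group, ref_group, region, collection,
                weight_exponent=weight_exponent, n_perm=n_perm,
                seed=child_seed(seed, ci, rj), min_size=min_size,
            )
            logger.info("GSEA %s-%s@%s: %d sets, %.1fs",
                        test_group, ref_group, region, len(per_region[region]),
                        time.perf_counter() - t0)
        rr = RegionResults(contrast=(test_group, ref_group), results=per_region)
        region_results[(test_group, ref_group)] = rr
        common = common_pathways(rr, fdr_threshold=fdr_common, min_regions=min_regions,
                                 require_concordance=require_concordance)
        specific = region_specific_pathways(rr, fdr_in=fdr_in, fdr_out=fdr_out)
        calls[(test_group, ref_group)] = common + specific
        row = {"contrast": f"{test_group}-{ref_group}"}
        for region in REGIONS:
            row[f"sig_{region}"] = sum(r.fdr_q < fdr_common for r in per_region[region])
        row["common"] = len(common)
        for region in REGIONS:
            row[f"specific_{region}"] = sum(c.category == f"specific_{region}" for c in specific)
        count_rows.append(row)
    counts = pd.DataFrame(count_rows)
    return region_results, calls, counts


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Read inputs, run the full design, and write the output directory.

    Outputs: per contrast x region GSEA TSVs, per-contrast consensus and
    leading-edge gene TSVs, the counts table, activity matrix + group
    summary (when enabled), and a JSON manifest with config, seeds, set
    sizes and input digests.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("regiongsea")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t_start = time.perf_counter()
    try:
        probes = read_expression(cfg.matrix_path, cfg.annotation_path)
        if cfg.probe_map_path:
            probe_map = read_probe_map(cfg.probe_map_path)
            m = collapse_probes_by_cv(probes, probe_map)
        else:
            m = ExpressionMatrix(values=probes.values, annotations=probes.annotations)
        collection = read_gmt(cfg.gmt_path)
        filtered = restrict_and_filter(collection, m.gene_symbols, min_size=cfg.min_size)
        logger.info("loaded %d genes x %d samples; %d gene sets after filtering",
                    len(m.gene_symbols), len(m.sample_ids), len(filtered))

        region_results, calls, counts = analyze_study(
            m, filtered, contrasts=cfg.contrasts, n_perm=cfg.n_perm,
            weight_exponent=cfg.weight_exponent, min_size=cfg.min_size, seed=cfg.seed,
            fdr_common=cfg.fdr_common, min_regions=cfg.min_regions,
            require_concordance=cfg.require_concordance,
            fdr_in=cfg.fdr_in, fdr_out=cfg.fdr_out,
        )

        for (test_group, ref_group), rr in region_results.items():
            label = f"{test_group}-{ref_group}"
            for region, results in rr.results.items():
                results_to_frame(results).to_csv(
                    out / f"gsea_{label}_{region}.tsv", sep="\t", index=False
                )
            calls_to_frame(calls[(test_group, ref_group)]).to_csv(
                out / f"consensus_{label}.tsv", sep="\t", index=False
            )
            if calls[(test_group, ref_group)]:
                genes = leading_edge_gene_table(
                    calls[(test_group, ref_group)], rr, m, p_cut=cfg.leading_edge_p_cut
                )
                genes.to_csv(out / f"leading_edge_genes_{label}.tsv", sep="\t", index=False)
        counts.to_csv(out / "counts.tsv", sep="\t", index=False)

        if cfg.activity:
            zm = z_transform(m)
            act_collection = restrict_and_filter(filtered, zm.gene_symbols,
                                                 min_size=cfg.min_size)
            act = sample_activity(zm, act_collection, weight_exponent=cfg.weight_exponent)
            act.values.to_csv(out / "activity.tsv", sep="\t")
            group_activity_summary(act, m.annotations).to_csv(
                out / "activity_summary.tsv", sep="\t", index=False
            )

        manifest = {
            "package_version": __version__,
            "config": asdict(cfg),
            "child_seeds": {
                f"{t}-{r}@{region}": child_seed(cfg.seed, ci, rj)
                for ci, (t, r) in enumerate(cfg.contrasts)
                for rj, region in enumerate(REGIONS)
            },
            "set_sizes": {s.name: len(s) for s in filtered},
            "n_genes": len(m.gene_symbols),
            "n_samples": len(m.sample_ids),
            "input_digests": {
                "matrix": _sha256(cfg.matrix_path),
                "annotations": _sha256(cfg.annotation_path),
                "gmt": _sha256(cfg.gmt_path),
                **({"probe_map": _sha256(cfg.probe_map_path)} if cfg.probe_map_path else {}),
            },
            "elapsed_seconds": round(time.perf_counter() - t_start, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    except Exception:
        logger.exception("pipeline aborted; partial outputs in %s", out)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
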