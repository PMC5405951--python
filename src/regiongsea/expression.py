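"""Expression matrices, sample annotations, probe collapse, z-transform.

The pipeline consumes an already-normalised log-scale matrix (probes or
genes x samples, TSV) plus a sample annotation table assigning each
sample to a clinical group (A = uninfected controls, B = HIV without
neurocognitive impairment, C = HIV with NCI without encephalitis,
D = HIV with NCI and encephalitis) and a brain region (WM = white
matter, FC = frontal cortex, BG = basal ganglia).  Upstream array QC and
normalisation are out of scope.

Probe-level matrices are collapsed to one representative probe per gene
by the highest coefficient of variation across all samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeMatrix",
    "ExpressionMatrix",
    "read_expression",
    "read_probe_map",
    "collapse_probes_by_cv",
    "z_transform",
    "flag_region_marker_conflicts",
]

VALID_GROUPS = ("A", "B", "C", "D")
VALID_REGIONS = ("WM", "FC", "BG")

#: |mean| below this is treated as a zero-mean probe when computing CV.
ZERO_MEAN_TOL = 1e-12


def _check_annotations(annotations: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    missing = [s for s in sample_ids if s not in annotations.index]
    if missing:
        raise ValueError(f"samples missing from annotations: {missing}")
    ann = annotations.loc[sample_ids, ["group", "region"]].copy()
    bad_groups = sorted(set(ann["group"]) - set(VALID_GROUPS))
    if bad_groups:
        raise ValueError(f"invalid group labels {bad_groups}; allowed: {list(VALID_GROUPS)}")
    bad_regions = sorted(set(ann["region"]) - set(VALID_REGIONS))
    if bad_regions:
        raise ValueError(f"invalid region labels {bad_regions}; allowed: {list(VALID_REGIONS)}")
    return ann


@dataclass
class ProbeMatrix:
    """Probe-level log-scale intensities with sample annotations.

    ``values``: probes x samples DataFrame (no missing entries);
    ``annotations``: per-sample group/region, indexed by sample id.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.stack()  # noqa: F841 - force index computation below
            r, c = np.where(self.values.isna().to_numpy())
            raise ValueError(
                f"missing values in matrix, first at "
                f"({self.values.index[r[0]]!r}, {self.values.columns[c[0]]!r})"
            )
        self.annotations = _check_annotations(self.annotations, list(self.values.columns))

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ExpressionMatrix:
    """Gene-level log-scale expression (genes x samples) with annotations."""

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol: {dup!r}")
        self.annotations = _check_annotations(self.annotations, list(self.values.columns))

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str, region: str) -> list[str]:
        ann = self.annotations
        mask = (ann["group"] == group) & (ann["region"] == region)
        return list(ann.index[mask])


def read_expression(matrix_path: str | Path, annotation_path: str | Path) -> ProbeMatrix:
    """Read a TSV matrix (header = sample ids, first column = probe ids)
    plus a TSV annotation table with columns sample_id, group, region.

    Every matrix sample must have an annotation row; non-numeric cells
    raise a parse error with coordinates.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    non_numeric = [c for c in values.columns if not pd.api.types.is_numeric_dtype(values[c])]
    if non_numeric:
        col = non_numeric[0]
        coerced = pd.to_numeric(values[col], errors="coerce")
        row = values.index[coerced.isna().to_numpy().nonzero()[0][0]]
        raise ValueError(f"non-numeric cell at ({row!r}, {col!r}) in {matrix_path}")
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    required = {"sample_id", "group", "region"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    ann = ann.set_index("sample_id")
    return ProbeMatrix(values=values.astype(float), annotations=ann)


def read_probe_map(path: str | Path) -> pd.DataFrame:
    """Read a 2-column TSV mapping probe_id -> gene_symbol.

    A probe may map to at most one gene; a gene may own many probes.
    """
    pm = pd.read_csv(path, sep="\t", dtype=str)
    if pm.shape[1] < 2:
        raise ValueError("probe map must have two columns: probe_id, gene_symbol")
    pm = pm.iloc[:, :2]
    pm.columns = ["probe_id", "gene_symbol"]
    if pm["probe_id"].duplicated().any():
        dup = pm.loc[pm["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"probe {dup!r} maps to more than one gene")
    return pm


def collapse_probes_by_cv(m: ProbeMatrix, probe_map: pd.DataFrame) -> ExpressionMatrix:
    """Collapse probes to genes, keeping per gene the probe with the highest
    coefficient of variation (sample sd / mean across all samples).

    Unmapped probes are dropped.  Exact CV ties are broken by the
    lexicographically smallest probe id.  Zero-mean probes (|mean| <
    ``ZERO_MEAN_TOL``) with positive sd get CV = +inf and are retained
    only when no probe of that gene has a finite CV; a gene whose every
    probe is constant at zero mean has no defined CV and raises.
    """
    pm = probe_map.set_index("probe_id")["gene_symbol"]
    mapped = [p for p in m.probe_ids if p in pm.index]
    if not mapped:
        raise ValueError("no mapped probes")
    vals = m.values.loc[mapped]
    means = vals.mean(axis=1)
    sds = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sds / means).to_numpy()
    zero_mean = means.abs().to_numpy() < ZERO_MEAN_TOL
    cv = np.where(zero_mean & (sds.to_numpy() > 0), np.inf, cv)
    cv = np.where(zero_mean & (sds.to_numpy() == 0), np.nan, cv)
    cv_s = pd.Series(cv, index=vals.index)

    chosen: dict[str, str] = {}
    for gene, probes in pm.loc[mapped].groupby(pm.loc[mapped]).groups.items():
        probe_ids = sorted(probes)  # lexicographic order makes argmax ties deterministic
        cvs = cv_s.loc[probe_ids]
        finite = cvs[np.isfinite(cvs)]
        if len(finite):
            chosen[str(gene)] = finite.idxmax()
        else:
            infinite = cvs[np.isinf(cvs)]
            if len(infinite):
                logger.warning(
                    "gene %s: only zero-mean probes; retaining %s (CV=inf)",
                    gene, infinite.index[0],
                )
                chosen[str(gene)] = infinite.index[0]
            else:
                raise ValueError(f"gene {gene!r}: CV undefined for every probe")

    genes = sorted(chosen)
    out = vals.loc[[chosen[g] for g in genes]]
    out.index = pd.Index(genes, name="gene")
    return ExpressionMatrix(values=out, annotations=m.annotations)


def z_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise each gene row to mean 0, sd 1 across samples.

    Uses the population (ddof=0) standard deviation so rows come out with
    sd exactly 1.  Constant rows carry no ranking information and are
    dropped with a warning.  Requires at least two samples.
    """
    if m.values.shape[1] < 2:
        raise ValueError("z_transform requires >= 2 samples")
    vals = m.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        dropped = [g for g, c in zip(m.gene_symbols, constant) if c]
        logger.warning("z_transform: dropping %d constant gene(s): %s%s",
                       len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    keep = ~constant
    z = (vals[keep] - mu[keep]) / sd[keep]
    out = pd.DataFrame(z, index=m.values.index[keep], columns=m.values.columns)
    return ExpressionMatrix(values=out, annotations=m.annotations)


def flag_region_marker_conflicts(
    m: ExpressionMatrix,
    neuron_marker: str = "RBFOX3",
    oligo_marker: str = "MBP",
    threshold: float = 1.0,
) -> list[tuple[str, str]]:
    """Flag WM/FC samples whose neuron/oligodendrocyte marker balance
    conflicts with their region label.

    Using z-scores of the two markers across all samples: a white-matter
    sample is flagged when z(neuron) - z(oligo) > threshold (it looks
    cortical), a frontal-cortex sample when z(oligo) - z(neuron) >
    threshold.  Basal-ganglia samples are never flagged.  The list is
    advisory; exclusion is the caller's decision.
    """
    for marker in (neuron_marker, oligo_marker):
        if marker not in m.values.index:
            raise ValueError(f"marker gene {marker!r} not in matrix")

    def _z(row: pd.Series) -> pd.Series:
        sd = row.std(ddof=0)
        if sd == 0:
            return row * 0.0
        return (row - row.mean()) / sd

    zn = _z(m.values.loc[neuron_marker])
    zo = _z(m.values.loc[oligo_marker])
    flags: list[tuple[str, str]] = []
    for sample in m.sample_ids:
        region = m.annotations.loc[sample, "region"]
        diff = zn[sample] - zo[sample]
        if region == "WM" and diff > threshold:
            flags.append((sample, f"WM sample with neuronal marker excess "
                                  f"(z[{neuron_marker}]-z[{oligo_marker}]={diff:.2f})"))
        elif region == "FC" and -diff > threshold:
            flags.append((sample, f"FC sample with oligodendrocyte marker excess "
                                  f"(z[{oligo_marker}]-z[{neuron_marker}]={-diff:.2f})"))
    return flags
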