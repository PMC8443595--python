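"""Gene x brain-region expression matrices and region gene-set construction.

A region's gene set contains the genes whose expression passes a
threshold in that region (TPM >= 9 for GTEx-style matrices, log(RPKM) > 2
for Allen-style matrices), minus housekeeping genes — genes detected at
TPM >= 1 in every region, which carry no regional information.  The
boundary operator (``ge`` vs ``gt``) travels with the threshold in
``ThresholdConfig`` rather than being hard-coded, because the two source
conventions differ.  Missing values never satisfy a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Set

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection


@dataclass
class ThresholdConfig:
    """Thresholds steering region-set construction and downstream stages.

    expr_threshold / threshold_op: regional-expression cutoff and its
        boundary semantics (``ge`` includes the boundary, ``gt`` excludes).
    housekeeping_min: floor defining housekeeping genes (expressed at or
        above it in *every* region).
    min_score: seed-table association-score filter.
    missing_frac: rows/columns with at least this fraction of missing
        cells are removed before PCA.
    alpha: BH-adjusted significance level for overlap and enrichment calls.
    """

    expr_threshold: float = 9.0
    threshold_op: str = "ge"
    housekeeping_min: float = 1.0
    min_score: float = 0.01
    missing_frac: float = 0.70
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.threshold_op not in ("ge", "gt"):
            raise ValueError(f"threshold_op must be 'ge' or 'gt', got {self.threshold_op!r}")
        for name in ("expr_threshold", "housekeeping_min", "min_score", "alpha"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0 < self.missing_frac <= 1:
            raise ValueError("missing_frac must lie in (0, 1]")


def read_expression_table(path: str | Path, units: str = "TPM") -> pd.DataFrame:
    """Read a genes x regions TSV (first column gene labels, header row).

    Blank cells become NaN.  Duplicate gene or region labels are an error
    naming the offender.  Returns a float DataFrame indexed by gene with
    ``df.attrs['units']`` set.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene row {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate region column {dup!r}")
    df = df.astype(float)
    if units == "TPM" and (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative TPM values")
    df.attrs["units"] = units
    return df


def write_expression_table(expr: pd.DataFrame, path: str | Path) -> None:
    values = expr.to_numpy()
    with Path(path).open("w") as fh:
        fh.write("gene\t" + "\t".join(map(str, expr.columns)) + "\n")
        for gene, row in zip(expr.index, values):
            cells = "\t".join("" if np.isnan(v) else format(v, ".6g") for v in row)
            fh.write(f"{gene}\t{cells}\n")


def housekeeping_genes(expr: pd.DataFrame, min_level: float = 1.0) -> Set[str]:
    """Genes at/above ``min_level`` in every region; missing counts as below."""
    if expr.empty:
        raise ValueError("housekeeping_genes: empty expression matrix")
    values = expr.to_numpy()
    ok = np.all(np.nan_to_num(values, nan=-np.inf) >= min_level, axis=1)
    return set(expr.index[ok])


def region_gene_sets(
    expr: pd.DataFrame,
    cfg: ThresholdConfig,
    exclude: Iterable[str] = (),
) -> GeneSetCollection:
    """One gene set per region: genes passing the expression threshold there.

    Genes in ``exclude`` (typically housekeeping genes) are removed from
    every set.  Empty sets are retained, with a warning, so that region
    labels survive into downstream matrices.
    """
    exclude_set = set(exclude)
    coll = GeneSetCollection()
    values = expr.to_numpy()
    filled = np.nan_to_num(values, nan=-np.inf)
    for j, region in enumerate(expr.columns):
        col = filled[:, j]
        if cfg.threshold_op == "ge":
            mask = col >= cfg.expr_threshold
        else:
            mask = col > cfg.expr_threshold
        genes = [g for g in expr.index[mask] if g not in exclude_set]
        if not genes:
            warnings.warn(f"region {region!r}: empty gene set after thresholding")
        coll.add(str(region), genes, description=f"expr {cfg.threshold_op} {cfg.expr_threshold:g}")
    return coll
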