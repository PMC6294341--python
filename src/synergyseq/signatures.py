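"""Non-perturbational signatures: disease, cell-line baseline, and sample QC.

Disease signatures come from differential-expression output (tumor vs
same-tissue control) ternarized at a significance/fold-change cutoff.
Cell-line baseline signatures come from RPKM-like expression tables
normalized as log2 fold change against the per-gene median across lines.
Sample-level Spearman/Pearson correlation supports the QC heatmap comparing
e.g. PDX lines to tumor cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import LandmarkGeneSet, SignedSignature

__all__ = [
    "ExpressionTable",
    "DifferentialExpressionResult",
    "subset_landmark",
    "pdx_normalize",
    "signature_from_fold_change",
    "disease_signature_from_de",
    "sample_correlation",
    "differential_expression",
]

_SPACES = ("counts", "rpkm", "log2fc")


@dataclass
class ExpressionTable:
    """Genes x samples abundance matrix with a space tag.

    ``space`` is one of ``counts`` (raw, non-negative integers), ``rpkm``
    (non-negative abundances), or ``log2fc`` (signed, already normalized).
    """

    values: pd.DataFrame
    space: str = "rpkm"

    def __post_init__(self) -> None:
        if self.space not in _SPACES:
            raise ValueError(f"space must be one of {_SPACES}, got {self.space!r}")
        if self.space in ("counts", "rpkm") and (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError(f"{self.space} table contains negative values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class DifferentialExpressionResult:
    """Per-gene (log2_fold_change, adjusted_p) table from any DE engine."""

    table: pd.DataFrame  # columns: log2_fold_change, adjusted_p; index: gene_id

    def __post_init__(self) -> None:
        missing = {"log2_fold_change", "adjusted_p"} - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table lacks columns: {sorted(missing)}")
        p = self.table["adjusted_p"].to_numpy(dtype=float)
        if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
            raise ValueError("adjusted p-values outside [0, 1]")


def subset_landmark(table: ExpressionTable, genes: LandmarkGeneSet) -> ExpressionTable:
    """Restrict and reorder a table to the canonical landmark gene axis.

    Landmarks absent from the table are dropped (with a warning listing how
    many); extra genes are discarded.  Join is by identifier.
    """
    landmark = genes.as_pandas()
    present = landmark[landmark.isin(table.values.index)]
    if len(present) == 0:
        raise ValueError("no overlap between table genes and the landmark panel")
    missing = len(landmark) - len(present)
    if missing:
        absent = landmark[~landmark.isin(table.values.index)].tolist()
        warnings.warn(
            f"{missing} landmark genes absent from expression table: {absent[:10]}"
            + ("..." if missing > 10 else ""),
            UserWarning,
            stacklevel=2,
        )
    return ExpressionTable(values=table.values.loc[present], space=table.space)


def pdx_normalize(table: ExpressionTable, pseudocount: float = 1.0) -> ExpressionTable:
    """log2 fold change of each sample against the per-gene median abundance.

    out[g, s] = log2((x[g, s] + eps) / (median_g(x) + eps)) with the median
    taken across samples (mean of the central pair for even counts).  The
    pseudocount eps (default 1 RPKM) guards log(0).
    """
    if table.space != "rpkm":
        raise ValueError(f"pdx_normalize expects an rpkm-space table, got {table.space!r}")
    if table.n_samples < 2:
        raise ValueError("median normalization needs at least 2 samples")
    x = table.values.to_numpy(dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    out = np.log2((x + pseudocount) / (med + pseudocount))
    return ExpressionTable(
        values=pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        space="log2fc",
    )


def signature_from_fold_change(
    log2fc: pd.Series, threshold: float = 1.0
) -> SignedSignature:
    """Ternarize a log2 fold-change vector into a cell-line baseline signature.

    +1 above ``threshold``, -1 below ``-threshold``, else 0.  The default
    |log2fc| > 1 mirrors the z-threshold of 1 used in consensus aggregation.
    """
    vals = np.zeros(len(log2fc), dtype=np.int8)
    x = log2fc.to_numpy(dtype=float)
    vals[x > threshold] = 1
    vals[x < -threshold] = -1
    return SignedSignature(values=pd.Series(vals, index=log2fc.index), role="cell_line")


def disease_signature_from_de(
    de: DifferentialExpressionResult,
    genes: LandmarkGeneSet,
    alpha: float = 0.05,
    min_abs_lfc: float = 0.0,
) -> SignedSignature:
    """Disease signature over the landmark axis from a DE table.

    A landmark gets sign(log2_fold_change) when adjusted_p < alpha and
    |log2_fold_change| >= min_abs_lfc; landmarks not covered by the DE table
    (or not significant) are 0.
    """
    landmark = genes.as_pandas()
    covered = de.table.index.intersection(landmark)
    if len(covered) == 0:
        raise ValueError("DE result covers no landmark genes")
    sig = pd.Series(np.zeros(len(landmark), dtype=np.int8), index=landmark)
    sub = de.table.loc[covered]
    hit = (sub["adjusted_p"] < alpha) & (sub["log2_fold_change"].abs() >= min_abs_lfc)
    sig.loc[covered[hit]] = np.sign(sub.loc[hit, "log2_fold_change"]).astype(np.int8)
    return SignedSignature(values=sig, role="disease")


def sample_correlation(
    a: ExpressionTable, b: ExpressionTable, method: str = "spearman"
) -> pd.DataFrame:
    """Cross-correlation of every sample of ``a`` with every sample of ``b``.

    Computed over the genes shared by both tables (join by identifier);
    ``spearman`` ranks each sample first, ``pearson`` uses the values
    directly.  Returns an S_a x S_b DataFrame.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be spearman or pearson, got {method!r}")
    shared = a.values.index.intersection(b.values.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need at least 3")
    xa = a.values.loc[shared].to_numpy(dtype=float)
    xb = b.values.loc[shared].to_numpy(dtype=float)
    if method == "spearman":
        xa = np.apply_along_axis(stats.rankdata, 0, xa)
        xb = np.apply_along_axis(stats.rankdata, 0, xb)
    xa = (xa - xa.mean(axis=0)) / xa.std(axis=0)
    xb = (xb - xb.mean(axis=0)) / xb.std(axis=0)
    corr = xa.T @ xb / xa.shape[0]
    return pd.DataFrame(corr, index=a.values.columns, columns=b.values.columns)


def differential_expression(
    counts: ExpressionTable,
    group_a: list[str],
    group_b: list[str],
) -> DifferentialExpressionResult:
    """Two-sample DE on log2(count + 1) with Benjamini-Hochberg adjustment.

    A deliberately simple engine used by the synthetic pipeline to turn
    generated tumor/control count tables into a DE table; real analyses
    should supply their own DE output.  Fold change is group_a minus
    group_b on the log2 scale.
    """
    if counts.space != "counts":
        raise ValueError("differential_expression expects a counts-space table")
    xa = np.log2(counts.values[group_a].to_numpy(dtype=float) + 1.0)
    xb = np.log2(counts.values[group_b].to_numpy(dtype=float) + 1.0)
    lfc = xa.mean(axis=1) - xb.mean(axis=1)
    t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {"log2_fold_change": lfc, "adjusted_p": padj}, index=counts.values.index
    )
    return DifferentialExpressionResult(table=table)
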