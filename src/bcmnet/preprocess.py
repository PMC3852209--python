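"""Normalization, variance filtering, and co-expression graph construction.

Input is a pair of gene-expression matrices (genes x samples, log-scale
intensities) measured on the *same* specimens in two tissue compartments,
e.g. laser-capture-microdissected tumor and stroma.  The pipeline is:

1. match the two matrices' global medians with a linear map (the tissues
   are typically normalized separately upstream);
2. drop low-variation genes, whose correlation estimates are unstable;
3. connect tumor gene i to stroma gene j whenever the Pearson correlation
   of their profiles across the matched samples reaches ``min_weight``;
   the correlation becomes the edge weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .graph import WeightedBipartiteGraph

__all__ = [
    "PairedTissueDataset",
    "validate_expression",
    "median_match_normalize",
    "filter_low_variation",
    "pearson",
    "build_coexpression_bipartite",
]


def validate_expression(df: pd.DataFrame, name: str = "matrix") -> pd.DataFrame:
    """Validate a genes x samples expression matrix."""
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{name}: empty expression matrix")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{name}: duplicate gene id {dup!r}")
    if df.isna().any().any():
        raise ValueError(f"{name}: missing values present")
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise ValueError(f"{name}: non-numeric columns present")
    return df


@dataclass
class PairedTissueDataset:
    """Matched tumor and stroma matrices over identically ordered samples."""

    tumor: pd.DataFrame
    stroma: pd.DataFrame

    def __post_init__(self) -> None:
        validate_expression(self.tumor, "tumor")
        validate_expression(self.stroma, "stroma")
        if list(self.tumor.columns) != list(self.stroma.columns):
            raise ValueError("tumor and stroma sample ids differ or are reordered")

    @property
    def n_samples(self) -> int:
        return self.tumor.shape[1]


def median_match_normalize(
    paired: PairedTissueDataset, scale: float = 1.0
) -> PairedTissueDataset:
    """Linearly shift the stroma matrix so its global median matches tumor's.

    The map is ``stroma * scale + offset`` with the offset solved so that
    the median over all stroma entries equals the median over all tumor
    entries; with the default ``scale=1`` this is a pure shift.  A global
    linear map preserves ranks and all linear relationships within the
    matrix, so downstream correlations are unaffected by it.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    med_t = float(np.median(paired.tumor.to_numpy()))
    scaled = paired.stroma * scale
    offset = med_t - float(np.median(scaled.to_numpy()))
    return PairedTissueDataset(paired.tumor, scaled + offset)


def filter_low_variation(
    matrix: pd.DataFrame,
    threshold: float = 0.2,
    mode: Literal["cv", "quantile"] = "cv",
) -> pd.DataFrame:
    """Drop genes with small variation in their expression profile.

    mode="cv" removes genes whose coefficient of variation sd/|mean| is
    below ``threshold`` (a gene with zero mean is treated as
    zero-variation and removed).  mode="quantile" removes the
    bottom-``threshold`` fraction of genes ranked by variance.  Sample
    ordering is preserved either way.
    """
    validate_expression(matrix)
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    values = matrix.to_numpy()
    if mode == "cv":
        means = values.mean(axis=1)
        sds = values.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(means != 0, sds / np.abs(means), 0.0)
        keep = cv >= threshold
    elif mode == "quantile":
        variances = values.var(axis=1, ddof=1)
        n_remove = int(np.floor(threshold * matrix.shape[0] + 1e-12))
        order = np.argsort(variances, kind="stable")
        keep = np.ones(matrix.shape[0], dtype=bool)
        keep[order[:n_remove]] = False
        keep &= variances > 0  # zero-variation genes never survive
    else:
        raise ValueError("mode must be 'cv' or 'quantile'")
    if not keep.any():
        warnings.warn("all genes removed by the variation filter", stacklevel=2)
    return matrix.loc[keep]


def pearson(x, y) -> float:
    """Sample Pearson correlation of two profiles of equal length >= 3.

    Constant profiles have undefined correlation and raise; variance
    filtering upstream is expected to have removed them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant profile")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def _cross_correlation(tumor: np.ndarray, stroma: np.ndarray, block: int = 512) -> np.ndarray:
    """All tumor-gene x stroma-gene Pearson correlations, blockwise.

    Identical to the naive all-pairs computation; the block loop only
    bounds peak memory for large gene sets.
    """
    n = tumor.shape[1]
    zt = tumor - tumor.mean(axis=1, keepdims=True)
    zs = stroma - stroma.mean(axis=1, keepdims=True)
    st = np.sqrt((zt**2).sum(axis=1))
    ss = np.sqrt((zs**2).sum(axis=1))
    if np.any(st == 0) or np.any(ss == 0):
        raise ValueError(
            "constant gene profile encountered; run filter_low_variation first"
        )
    zt /= st[:, None]
    zs /= ss[:, None]
    out = np.empty((tumor.shape[0], stroma.shape[0]))
    for start in range(0, tumor.shape[0], block):
        out[start : start + block] = zt[start : start + block] @ zs.T
    return np.clip(out, -1.0, 1.0)


def build_coexpression_bipartite(
    paired: PairedTissueDataset,
    min_weight: float = 0.6,
    absolute: bool = False,
    prune: bool = False,
) -> WeightedBipartiteGraph:
    """Threshold the tumor x stroma correlation matrix into a weighted graph.

    An edge (tumor gene i, stroma gene j) is present iff rho_ij >=
    ``min_weight``; its weight is rho_ij.  With ``absolute=True`` the
    weight is |rho_ij| (folding anticorrelation in); the default keeps only
    positive correlations, which is what the density-bound arithmetic
    presupposes.  Correlations below the threshold count as weight 0 in
    every downstream density sum.  ``prune`` drops vertices left with no
    edges from the vertex lists.
    """
    if not (0 < min_weight < 1):
        raise ValueError("min_weight must be in (0, 1)")
    if paired.n_samples < 3:
        raise ValueError("need at least 3 matched samples")
    rho = _cross_correlation(paired.tumor.to_numpy(), paired.stroma.to_numpy())
    if absolute:
        rho = np.abs(rho)
    weights = np.where(rho >= min_weight, rho, 0.0)
    if not weights.any():
        warnings.warn("no correlation reaches min_weight; graph is empty", stacklevel=2)
    x_ids = list(paired.tumor.index)
    y_ids = list(paired.stroma.index)
    if prune:
        keep_x = weights.any(axis=1)
        keep_y = weights.any(axis=0)
        weights = weights[np.ix_(keep_x, keep_y)]
        x_ids = [g for g, k in zip(x_ids, keep_x) if k]
        y_ids = [g for g, k in zip(y_ids, keep_y) if k]
    return WeightedBipartiteGraph(x_ids, y_ids, weights)
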