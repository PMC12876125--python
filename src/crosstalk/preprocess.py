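"""Normalisation stand-in and QC: log2 transform, quantile normalisation,
per-sample box statistics and PCA.

True RMA (background correction + probe-set median polish on raw array data)
operates on files this pipeline deliberately does not read; log2 transform
followed by classic quantile normalisation is the documented stand-in that
brings per-sample distributions onto a common scale, which is what the
downstream two-group tests rely on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PCAResult
from .errors import ParameterError

__all__ = ["log2_transform", "quantile_normalize", "column_summaries", "pca"]


def log2_transform(mat: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise ``log2(value + offset)``; labels preserved.

    Raises if any shifted value is non-positive, naming the first offending
    cell.
    """
    if offset < 0:
        raise ParameterError("offset must be >= 0")
    shifted = mat.values.to_numpy(dtype=float) + offset
    if (shifted <= 0).any():
        i, j = np.argwhere(shifted <= 0)[0]
        raise ParameterError(
            f"non-positive value after offset at gene {mat.gene_ids[i]!r}, "
            f"sample {mat.sample_ids[j]!r}"
        )
    out = pd.DataFrame(np.log2(shifted), index=mat.values.index, columns=mat.values.columns)
    return mat.with_values(out)


def quantile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Classic quantile normalisation across samples.

    Within each sample, values are ranked and replaced by the across-sample
    mean of each rank's values (the reference distribution). Ties within a
    sample receive the mean of the reference values they span, so tied inputs
    stay tied. Idempotent, and afterwards every sample shares the same sorted
    value multiset.
    """
    if mat.n_samples < 2:
        raise ParameterError("quantile normalisation needs at least 2 samples")
    x = mat.values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_vals = col[order]
        assigned = reference.copy()
        # average the reference over runs of tied input values
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_genes]))
        sums = np.add.reduceat(assigned, starts)
        means = sums / (ends - starts)
        assigned = np.repeat(means, ends - starts)
        out[order, j] = assigned
    df = pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns)
    return mat.with_values(df)


def column_summaries(mat: ExpressionMatrix) -> pd.DataFrame:
    """Five-number summary (min, q1, median, q3, max) per sample.

    Quartiles use linear interpolation (the type-7 convention), matching what
    standard box plots draw.
    """
    if mat.n_genes == 0 or mat.n_samples == 0:
        raise ParameterError("cannot summarise an empty matrix")
    x = mat.values.to_numpy(dtype=float)
    q = np.quantile(x, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0, method="linear")
    return pd.DataFrame(
        q.T, index=mat.values.columns, columns=["min", "q1", "median", "q3", "max"]
    )


def pca(mat: ExpressionMatrix, k: int, scale: bool = False) -> PCAResult:
    """Principal components of samples in gene space.

    Samples are observations and genes features. Features are centred;
    ``scale=True`` additionally divides by the per-gene standard deviation
    (FactoMineR-style). Scores come from the SVD of the centred matrix; the
    sign convention makes each loading column's largest-magnitude entry
    positive so results are reproducible across SVD implementations.
    """
    if mat.n_samples < 2:
        raise ParameterError("PCA needs at least 2 samples")
    if not 1 <= k <= min(mat.n_genes, mat.n_samples):
        raise ParameterError(f"k={k} must lie in [1, min(genes, samples)]")
    x = mat.values.to_numpy(dtype=float).T  # samples x genes
    xc = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    u = u * flip
    vt = vt * flip[:, None]
    var = s**2
    total = var.sum()
    ratio = var[:k] / total if total > 0 else np.zeros(k)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((u[:, :k] * s[:k]), index=mat.values.columns, columns=comp_names)
    loadings = pd.DataFrame(vt[:k].T, index=mat.values.index, columns=comp_names)
    return PCAResult(scores=scores, explained_variance_ratio=ratio, component_loadings=loadings)
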