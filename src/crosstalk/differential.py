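"""Per-gene two-group differential expression between healthy controls (HC)
and osteoarthritis (OA) samples.

Two test statistics are offered:

``welch``
    Welch's unequal-variance two-sided t-test per gene, the assumption-light
    default. t = (mean_OA - mean_HC) / sqrt(s_HC^2/n_HC + s_OA^2/n_OA) with
    Welch-Satterthwaite degrees of freedom.

``moderated``
    Empirical-Bayes moderated t in the microarray tradition: per-gene pooled
    variances are shrunk towards a scaled inverse-chi-square prior whose
    parameters (d0, s0^2) are fitted by method of moments on the log
    variances (digamma/trigamma matching). The posterior variance is
    (d0*s0^2 + df*s^2) / (d0 + df) and the statistic gains d0 degrees of
    freedom. As d0 -> 0 this reduces to the pooled-variance t; as d0 -> inf
    every gene shares s0^2.

The log2 fold change is defined OA - HC, so "up" always means higher in OA.
Multiplicity is handled by Benjamini-Hochberg over all tested genes; the DEG
filter applies a strict ``< alpha`` cut on raw p-values by default, with the
stricter adjusted-p variant behind a flag. Genes with zero variance in both
groups and equal means report t = 0, p = 1 rather than being dropped, which
keeps the gene universe stable for enrichment backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import DEGSet, ExpressionMatrix
from .errors import ParameterError
from .enrichment import bh_adjust

__all__ = [
    "DEGConfig",
    "welch_t",
    "fit_variance_prior",
    "moderated_t",
    "differential_expression",
    "filter_degs",
    "volcano_annotations",
]

DE_COLUMNS = ["mean_hc", "mean_oa", "log2fc", "t_stat", "df", "p_value", "adj_p", "direction"]


@dataclass
class DEGConfig:
    """Differential-screening configuration.

    alpha: significance threshold (strict ``<``); use_adjusted: filter on
    BH-adjusted instead of raw p; method: ``welch`` or ``moderated``.
    """

    alpha: float = 0.05
    use_adjusted: bool = False
    method: str = "welch"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must lie strictly in (0, 1), got {self.alpha}")
        if self.method not in ("welch", "moderated"):
            raise ParameterError(f"method must be 'welch' or 'moderated', got {self.method!r}")


def _welch_arrays(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch t over rows: a, b are genes x samples blocks."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = mb - ma
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, diff / np.sqrt(se2), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        df_num = se2**2
        df_den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        df = np.where(df_den > 0, df_num / df_den, na + nb - 2)
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df), 0.0)
    p = np.where((se2 == 0) & (diff == 0), 1.0, p)
    return t, df, p


def welch_t(group_a: list[float], group_b: list[float]) -> tuple[float, float, float]:
    """Welch's two-sample t-test: returns (t, df, p), t signed b - a.

    Both groups need >= 2 finite values. If both variances are zero and the
    means are equal, (0, n_a + n_b - 2, 1) is returned.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ParameterError("groups must contain finite values only")
    t, df, p = _welch_arrays(a[None, :], b[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        raise ParameterError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_variance_prior(sample_variances, residual_df: float) -> tuple[float, float]:
    """Fit the scaled inverse-chi-square variance prior (d0, s0^2).

    Method of moments on z = log(s^2): under the hierarchical model,
    E[z] = log(s0^2) + digamma(df/2) - log(df/2) + log(d0/2) - digamma(d0/2)
    and Var[z] = trigamma(df/2) + trigamma(d0/2); the excess of the empirical
    log-variance spread over trigamma(df/2) identifies d0 via the trigamma
    inverse. When the empirical spread does not exceed the theoretical
    sampling minimum, d0 = inf and every gene shares s0^2. A degenerate input
    with literally zero spread returns (inf, the common variance).
    """
    s2 = np.asarray(list(sample_variances), dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        raise ParameterError("variance prior needs at least 10 positive variances")
    if residual_df <= 0:
        raise ParameterError("residual_df must be positive")
    z = np.log(s2)
    if np.ptp(z) < 1e-12:
        return float("inf"), float(np.exp(z.mean()))
    half_df = residual_df / 2.0
    e = z - special.digamma(half_df) + np.log(half_df)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, half_df))
    if evar <= 0:
        return float("inf"), float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def moderated_t(
    hc: np.ndarray,
    oc: np.ndarray,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Empirical-Bayes moderated t over rows of two genes x samples blocks.

    The prior (d0, s0^2) is fitted from the pooled per-gene variances unless
    supplied explicitly (useful for studying the d0 -> 0 / d0 -> inf limits).
    Returns (t, df, p, d0, s0_sq).
    """
    n1, n2 = hc.shape[1], oc.shape[1]
    df_resid = n1 + n2 - 2
    v1, v2 = hc.var(axis=1, ddof=1), oc.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
    if d0 is None or s0_sq is None:
        d0, s0_sq = fit_variance_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = np.full_like(s2, df_resid + d0)
    diff = oc.mean(axis=1) - hc.mean(axis=1)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    finite_t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(finite_t)),
        2.0 * stats.t.sf(np.abs(finite_t), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    p = np.where(np.isfinite(t), p, 0.0)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return t, df_total, p, d0, s0_sq


def differential_expression(mat: ExpressionMatrix, config: DEGConfig | None = None) -> pd.DataFrame:
    """Per-gene HC-vs-OA test over the whole matrix.

    Returns a DataFrame indexed by gene with columns ``mean_hc, mean_oa,
    log2fc, t_stat, df, p_value, adj_p, direction`` (log2fc = OA - HC; adj_p
    by Benjamini-Hochberg over all genes).
    """
    config = config or DEGConfig()
    hc_cols = mat.group_samples("HC")
    oa_cols = mat.group_samples("OA")
    if len(hc_cols) < 2 or len(oa_cols) < 2:
        raise ParameterError("both HC and OA need at least 2 samples")
    hc = mat.values[hc_cols].to_numpy(dtype=float)
    oc = mat.values[oa_cols].to_numpy(dtype=float)
    if config.method == "welch":
        t, df, p = _welch_arrays(hc, oc)
    else:
        t, df, p, _, _ = moderated_t(hc, oc)
    mean_hc, mean_oa = hc.mean(axis=1), oc.mean(axis=1)
    log2fc = mean_oa - mean_hc
    table = pd.DataFrame(
        {
            "mean_hc": mean_hc,
            "mean_oa": mean_oa,
            "log2fc": log2fc,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "adj_p": bh_adjust(p),
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=pd.Index(mat.gene_ids, name="gene"),
    )
    return table


def filter_degs(table: pd.DataFrame, config: DEGConfig | None = None) -> DEGSet:
    """Strict threshold filter: keep genes with p (or adjusted p) < alpha."""
    config = config or DEGConfig()
    col = "adj_p" if config.use_adjusted else "p_value"
    hit = table[table[col] < config.alpha]
    return DEGSet(directions=dict(zip(hit.index, hit["direction"])))


def volcano_annotations(table: pd.DataFrame, top_n: int = 20) -> pd.DataFrame:
    """Volcano-plot coordinates with the most significant genes flagged.

    Returns the full table of (log2fc, -log10 p) coordinates with a boolean
    ``label`` column marking the ``top_n/2`` smallest-p up-regulated and
    ``top_n/2`` smallest-p down-regulated genes (fewer if a side runs short).
    Ties in p break by |log2fc| descending, then symbol ascending.
    """
    if top_n < 0:
        raise ParameterError("top_n must be >= 0")
    coords = table[["log2fc", "p_value", "direction"]].copy()
    with np.errstate(divide="ignore"):
        coords["neg_log10_p"] = -np.log10(coords["p_value"])
    coords["label"] = False
    half = top_n // 2
    for direction in ("up", "down"):
        side = coords[coords["direction"] == direction].copy()
        side["abs_fc"] = side["log2fc"].abs()
        # stable three-pass sort: p asc, then |log2fc| desc, then symbol asc
        side = side.sort_index(kind="mergesort")
        side = side.sort_values("abs_fc", ascending=False, kind="mergesort")
        side = side.sort_values("p_value", ascending=True, kind="mergesort")
        coords.loc[side.index[:half], "label"] = True
    return coords[["log2fc", "p_value", "neg_log10_p", "direction", "label"]]
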