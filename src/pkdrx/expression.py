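"""Count normalization and differential expression for bulk RNA-seq.

Implements the upstream half of the repurposing pipeline: counts-per-million
(CPM) scaling, TMM (trimmed mean of M-values) between-sample normalization,
a low-expression noise filter, a moderated two-group t-test on log2-CPM with
empirical-Bayes variance shrinkage, Benjamini–Hochberg FDR control, and PCA
of the expression matrix.

The moderated t-test is a deliberately self-contained stand-in for the
voom/limma engine: a per-gene two-group linear model on ``log2(cpm + 0.5)``
whose residual variance is shrunk toward the across-gene consensus with a
prior degrees-of-freedom estimated by method of moments. It keeps the two
properties the pipeline relies on — well-calibrated null p-values and
stabilized variances at small n — without precision weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionError(ValueError):
    """Invalid input to an expression-level computation."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples raw count matrix.

    Requires unique gene and sample identifiers, non-negative values and at
    least two samples.
    """
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ExpressionError(f"duplicate gene ids: {dup[:5]}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ExpressionError(f"duplicate sample ids: {dup[:5]}")
    if counts.shape[1] < 2:
        raise ExpressionError("count matrix needs at least 2 samples")
    if (counts.to_numpy() < 0).any():
        raise ExpressionError("counts must be non-negative")
    return counts


@dataclass
class ExpressionMatrix:
    """log2-CPM expression values with the normalization that produced them.

    Attributes
    ----------
    logcpm : DataFrame
        ``log2(cpm + 0.5)`` values, genes x samples, on TMM-adjusted
        effective library sizes.
    lib_size : Series
        Raw per-sample library size (column sums of the count matrix).
    tmm : Series
        Per-sample TMM factor; geometric mean 1.
    """

    logcpm: pd.DataFrame
    lib_size: pd.Series
    tmm: pd.Series

    def __post_init__(self) -> None:
        if (self.tmm <= 0).any():
            raise ExpressionError("TMM factors must be strictly positive")
        gm = float(np.exp(np.mean(np.log(self.tmm.to_numpy()))))
        if abs(gm - 1.0) > 1e-6:
            raise ExpressionError(f"TMM factors must have geometric mean 1, got {gm}")


# ---------------------------------------------------------------------------
# CPM / TMM
# ---------------------------------------------------------------------------


def compute_cpm(
    counts: pd.DataFrame, tmm: pd.Series | None = None, log: bool = False, prior: float = 0.5
) -> pd.DataFrame:
    """Counts per million on (optionally TMM-adjusted) library sizes.

    cpm[g, s] = counts[g, s] / (lib_size[s] * tmm[s]) * 1e6.  With
    ``log=True`` returns ``log2(cpm + prior)``.
    """
    validate_counts(counts)
    lib = counts.sum(axis=0).astype(float)
    if tmm is not None:
        lib = lib * tmm.reindex(counts.columns).astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise ExpressionError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = counts.div(lib, axis=1) * 1e6
    if log:
        return np.log2(cpm + prior)
    return cpm


def _choose_reference(counts: pd.DataFrame) -> str:
    """Sample whose upper quartile of library-scaled counts is closest to the
    mean upper quartile across samples."""
    scaled = counts.div(counts.sum(axis=0), axis=1)
    uq = scaled.quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample against the reference, genes with zero counts in either
    are excluded; per-gene log2 ratios of library-scaled abundance (M) and
    average log2 abundance (A) are computed; the top/bottom ``trim_m``
    fraction by M and ``trim_a`` by A are trimmed; the factor is the
    exponentiated inverse-variance-weighted mean of the remaining M values.
    Factors are rescaled to geometric mean 1.
    """
    validate_counts(counts)
    lib = counts.sum(axis=0).astype(float)
    empty = lib[lib <= 0]
    if len(empty):
        raise ExpressionError(f"all genes zero in sample(s): {list(empty.index)}")
    if reference is None:
        reference = _choose_reference(counts)
    y_r = counts[reference].to_numpy(float)
    n_r = float(lib[reference])

    log_factors = {}
    for s in counts.columns:
        if s == reference:
            log_factors[s] = 0.0
            continue
        y_s = counts[s].to_numpy(float)
        n_s = float(lib[s])
        ok = (y_s > 0) & (y_r > 0)
        ys, yr = y_s[ok], y_r[ok]
        m = np.log2((ys / n_s) / (yr / n_r))
        a = 0.5 * np.log2((ys / n_s) * (yr / n_r))
        # asymptotic inverse variance of M (binomial delta method)
        w = 1.0 / ((n_s - ys) / (n_s * ys) + (n_r - yr) / (n_r * yr))
        n = len(m)
        if n == 0:
            log_factors[s] = 0.0
            continue
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any() or w[keep].sum() == 0:
            log_factors[s] = 0.0
        else:
            log_factors[s] = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    f = pd.Series({s: 2.0 ** lf for s, lf in log_factors.items()}).reindex(counts.columns)
    # center on geometric mean 1 so factors are relative, not anchored on the reference
    f = f / np.exp(np.mean(np.log(f)))
    return f


def noise_filter(cpm: pd.DataFrame, threshold: float = 2.0, fraction: float = 0.5) -> pd.Index:
    """Genes retained above the noise level.

    A gene is removed iff its CPM is below ``threshold`` in strictly more
    than ``fraction`` of the samples. The retained set also serves as the
    enrichment background downstream.
    """
    low = (cpm < threshold).sum(axis=1)
    keep = low <= fraction * cpm.shape[1]
    return cpm.index[keep]


def normalize(counts: pd.DataFrame, **tmm_kwargs) -> ExpressionMatrix:
    """Full normalization: library sizes, TMM factors, log2-CPM."""
    validate_counts(counts)
    tmm = tmm_factors(counts, **tmm_kwargs)
    logcpm = compute_cpm(counts, tmm=tmm, log=True)
    return ExpressionMatrix(logcpm=logcpm, lib_size=counts.sum(axis=0).astype(float), tmm=tmm)


# ---------------------------------------------------------------------------
# moderated two-group t
# ---------------------------------------------------------------------------


def _moment_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F model for gene variances.

    Under the hierarchical model s2_g ~ s0^2 * F(df, d0), the ratio
    r = Var(s2)/E(s2)^2 identifies the prior degrees of freedom d0; s0^2
    follows from the mean.  Returns (d0, s0sq); d0 = inf denotes complete
    shrinkage (variances indistinguishable from homogeneous).
    """
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1)) if len(s2) > 1 else 0.0
    if m <= 0:
        return np.inf, max(m, 1e-8)
    r = v / (m * m)
    # r = 2*(df + d0 - 2) / (df * (d0 - 4)); solve for d0, valid when r*df > 2
    if r * df <= 2.0:
        return np.inf, m
    d0 = (2.0 * df - 4.0 + 4.0 * r * df) / (r * df - 2.0)
    if d0 <= 4.0 or not np.isfinite(d0):
        d0 = 4.0 + 1e-6
    s0sq = m * (d0 - 2.0) / d0
    return d0, max(s0sq, 1e-8)


def differential_expression(
    expr: ExpressionMatrix | pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    contrast: str = "A_vs_B",
    var_floor: float = 1e-8,
) -> pd.DataFrame:
    """Moderated two-group t-test per gene on log2-CPM.

    ``log2FC`` is mean(group_a) - mean(group_b).  The pooled residual
    variance is shrunk toward the across-gene consensus with a
    method-of-moments prior df; p-values come from the t distribution at
    the moderated degrees of freedom; a BH-adjusted FDR column is appended.

    Returns a DataFrame indexed by gene with columns
    ``log2fc, t, p, fdr, contrast``.
    """
    logcpm = expr.logcpm if isinstance(expr, ExpressionMatrix) else expr
    for name, grp in (("A", group_a), ("B", group_b)):
        if len(grp) < 2:
            raise ExpressionError(f"group {name} has fewer than 2 samples")
        missing = [s for s in grp if s not in logcpm.columns]
        if missing:
            raise ExpressionError(f"group {name} samples not in matrix: {missing}")
    xa = logcpm[list(group_a)].to_numpy(float)
    xb = logcpm[list(group_b)].to_numpy(float)
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    lfc = ma - mb
    df_resid = na + nb - 2
    ss = ((xa - ma[:, None]) ** 2).sum(axis=1) + ((xb - mb[:, None]) ** 2).sum(axis=1)
    s2 = np.maximum(ss / df_resid, var_floor)

    d0, s0sq = _moment_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, max(float(np.mean(s2)), var_floor))
        df_total = min(1e6, 1e6)  # effectively normal tails
    else:
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    s2_post = np.maximum(s2_post, var_floor)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = lfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {"log2fc": lfc, "t": t, "p": p, "fdr": bh_fdr(p), "contrast": contrast},
        index=logcpm.index,
    )
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values with monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ExpressionError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame      # samples x components
    loadings: pd.DataFrame    # genes x components
    variance_fraction: np.ndarray = field(default_factory=lambda: np.array([]))


def pca(expr: ExpressionMatrix | pd.DataFrame, center: bool = True, scale: bool = False) -> PCAResult:
    """PCA of the expression matrix via SVD on samples x genes.

    Genes are the variables (columns after transposition); variance
    fractions come from the squared singular values.
    """
    logcpm = expr.logcpm if isinstance(expr, ExpressionMatrix) else expr
    x = logcpm.to_numpy(float).T  # samples x genes
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    if not np.any(x != 0):
        raise ExpressionError("constant matrix: no variance to decompose")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=logcpm.columns, columns=comp),
        loadings=pd.DataFrame(vt.T, index=logcpm.index, columns=comp),
        variance_fraction=var / var.sum(),
    )


def top_loading_genes(res: PCAResult, component: int = 1, n: int = 20) -> dict[str, list[str]]:
    """The n most positively and n most negatively loaded genes on a component.

    ``component`` is 1-based (PC1 is the first component).
    """
    key = f"PC{component}"
    if key not in res.loadings.columns:
        raise ExpressionError(f"component {component} not available (have {res.loadings.shape[1]})")
    if n > res.loadings.shape[0]:
        raise ExpressionError(f"n={n} exceeds gene count {res.loadings.shape[0]}")
    ld = res.loadings[key].sort_values()
    return {"down": list(ld.index[:n]), "up": list(ld.index[::-1][:n])}
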