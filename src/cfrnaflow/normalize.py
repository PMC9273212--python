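"""Between-sample normalization and removal of unwanted variation.

The normalization stack mirrors the standard bulk RNA-seq recipe for
cohort-level count tables and is applied identically to human gene/circRNA
matrices and microbial genus matrices:

1. **TMM** (trimmed mean of M-values) scale factors: per sample, log2
   expression ratios (M) and average log2 abundances (A) against a reference
   library are doubly trimmed (30% on M, 5% on A by default) and the
   remaining M values averaged with inverse delta-method variance weights;
   factors are rescaled to geometric mean 1.
2. **CPM** on the effective (TMM-scaled) library sizes, then ``log2(CPM+1)``.
3. **Empirical control genes**: the 25% of features with the least
   between-group signal — largest one-way ANOVA p-values across sample
   groups on log-CPM — assumed to carry only unwanted variation.
4. **RUVg**: latent nuisance factors W are the leading factors of the
   centered control-gene submatrix (via SVD) and are regressed out of every
   feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

import numpy as np
import pandas as pd
from scipy import stats


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class TMMParams:
    """Trimming parameters for TMM factor estimation.

    ``logratio_trim`` is the two-sided trim fraction on M values,
    ``abundance_trim`` the trim on A values.  The reference library is the
    sample whose 75th-percentile CPM is closest to the mean of those
    percentiles.
    """

    logratio_trim: float = 0.30
    abundance_trim: float = 0.05

    def __post_init__(self) -> None:
        for name in ("logratio_trim", "abundance_trim"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise NormalizationError(f"{name} must be in [0, 0.5)")


@dataclass
class NormalizationResult:
    """Output bundle of :func:`normalize_counts`."""

    tmm_factors: pd.Series
    effective_library_sizes: pd.Series
    control_genes: list[str] = field(default_factory=list)
    W: pd.DataFrame | None = None
    adjusted_logexpr: pd.DataFrame | None = None


def _pick_reference(counts: np.ndarray, libsize: np.ndarray) -> int:
    f75 = np.percentile(counts / libsize[None, :], 75, axis=0)
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    params: TMMParams,
) -> float:
    """TMM factor of one library against the reference library."""
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        raise NormalizationError(
            "sample shares no positively expressed feature with the reference"
        )
    o = obs[mask].astype(float)
    r = ref[mask].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # inverse delta-method variance of M
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    n = m.size
    lo_m = floor(n * params.logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = floor(n * params.abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    weights = 1.0 / w[keep]
    f = np.sum(m[keep] * weights) / np.sum(weights)
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def compute_tmm_factors(
    counts: pd.DataFrame, params: TMMParams | None = None
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    ``counts`` is a feature x sample non-negative matrix with at least two
    samples, each with positive library size.
    """
    params = params or TMMParams()
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise NormalizationError("TMM needs at least two samples")
    if (x < 0).any():
        raise NormalizationError("counts must be non-negative")
    libsize = x.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(counts.columns[libsize <= 0])
        raise NormalizationError(f"samples with zero library size: {bad}")

    ref = _pick_reference(x, libsize)
    factors = np.array([
        _tmm_pair(x[:, k], x[:, ref], libsize[k], libsize[ref], params)
        for k in range(x.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on effective (factor-scaled) library sizes."""
    x = counts.to_numpy(dtype=float)
    libsize = x.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(counts.columns[libsize <= 0])
        raise NormalizationError(f"samples with zero library size: {bad}")
    if factors is not None:
        f = factors.reindex(counts.columns).to_numpy(dtype=float)
        if np.isnan(f).any() or (f <= 0).any():
            raise NormalizationError("normalization factors must be positive "
                                     "and cover every sample")
        libsize = libsize * f
    return pd.DataFrame(x / libsize[None, :] * 1e6,
                        index=counts.index, columns=counts.columns)


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """``log2(CPM + 1)`` convenience transform."""
    return np.log2(cpm(counts, factors) + 1.0)


def _anova_pvalues(x: np.ndarray, group_index: list[np.ndarray]) -> np.ndarray:
    """Vectorized one-way fixed-effects ANOVA p-value per feature (row).

    Degenerate features get deterministic p-values: zero variance everywhere
    -> p = 1 (no evidence of group signal); zero within-group variance with
    between-group differences -> p = 0.
    """
    n = x.shape[1]
    k = len(group_index)
    grand = x.mean(axis=1)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    for idx in group_index:
        sub = x[:, idx]
        gmean = sub.mean(axis=1)
        ssb += idx.size * (gmean - grand) ** 2
        ssw += ((sub - gmean[:, None]) ** 2).sum(axis=1)
    dfb, dfw = k - 1, n - k
    scale = np.maximum((x ** 2).mean(axis=1), 1.0)
    tol = 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
        p = stats.f.sf(f, dfb, dfw)
    degenerate_within = ssw <= tol
    p[degenerate_within & (ssb > tol)] = 0.0
    p[degenerate_within & (ssb <= tol)] = 1.0
    return p


def select_control_genes(
    logexpr: pd.DataFrame, groups: pd.Series, fraction: float = 0.25
) -> list[str]:
    """Empirical control genes: the least group-informative features.

    Runs a per-feature one-way ANOVA of ``logexpr`` (log2(CPM+1)) across the
    sample groups and returns the ``ceil(fraction * n_features)`` features
    with the LARGEST p-values, ties broken by stable feature order.  Features
    returned in input row order.
    """
    if not 0.0 < fraction <= 1.0:
        raise NormalizationError("fraction must be in (0, 1]")
    g = groups.reindex(logexpr.columns)
    if g.isna().any():
        missing = list(logexpr.columns[g.isna()])
        raise NormalizationError(f"samples without group label: {missing[:5]}")
    levels = list(dict.fromkeys(g))
    if len(levels) < 2:
        raise NormalizationError("control-gene selection needs >= 2 groups")
    group_index = []
    for lev in levels:
        idx = np.flatnonzero((g == lev).to_numpy())
        if idx.size < 2:
            raise NormalizationError(
                f"group {lev!r} has fewer than 2 samples"
            )
        group_index.append(idx)

    p = _anova_pvalues(logexpr.to_numpy(dtype=float), group_index)
    n_controls = int(np.ceil(fraction * len(logexpr)))
    # stable argsort on -p keeps input order among ties
    order = np.argsort(-p, kind="stable")[:n_controls]
    chosen = np.zeros(len(logexpr), dtype=bool)
    chosen[order] = True
    return list(logexpr.index[chosen])


def ruvg_adjust(
    logexpr: pd.DataFrame, control_genes: list[str], k: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate and remove unwanted-variation factors from control genes.

    The control genes' log-expression is centered per gene across samples;
    the rank-``k`` SVD of the centered control submatrix yields the sample
    loadings W (scaled by the singular values, sign-fixed so the largest
    absolute loading of each factor is positive).  Every feature is then
    regressed on ``[1, W]`` and the W component subtracted.

    Returns ``(W, adjusted_logexpr)`` with W of shape samples x k.
    """
    if k < 1:
        raise NormalizationError("k must be >= 1")
    if not control_genes:
        raise NormalizationError("control gene set is empty")
    missing = [g for g in control_genes if g not in logexpr.index]
    if missing:
        raise NormalizationError(f"control genes absent from matrix: {missing[:5]}")
    n_samples = logexpr.shape[1]
    if k >= min(n_samples, len(control_genes)):
        raise NormalizationError(
            f"k={k} must be smaller than min(n_samples={n_samples}, "
            f"n_controls={len(control_genes)})"
        )

    z = logexpr.loc[control_genes].to_numpy(dtype=float)
    zc = z - z.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    w = vt[:k].T * s[:k]
    # deterministic sign: largest-|loading| sample positive per factor
    for j in range(k):
        col = w[:, j]
        if np.abs(col).max() > 0 and col[np.argmax(np.abs(col))] < 0:
            w[:, j] = -col

    if np.allclose(s[:k], 0.0):
        w_df = pd.DataFrame(np.zeros((n_samples, k)), index=logexpr.columns,
                            columns=[f"W{j + 1}" for j in range(k)])
        return w_df, logexpr.copy()

    y = logexpr.to_numpy(dtype=float)
    design = np.column_stack([np.ones(n_samples), w])
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    adjusted = y - (w @ beta[1:, :]).T
    w_df = pd.DataFrame(w, index=logexpr.columns,
                        columns=[f"W{j + 1}" for j in range(k)])
    return w_df, pd.DataFrame(adjusted, index=logexpr.index,
                              columns=logexpr.columns)


def normalize_counts(
    counts: pd.DataFrame,
    groups: pd.Series,
    k: int = 1,
    params: TMMParams | None = None,
    control_fraction: float = 0.25,
) -> NormalizationResult:
    """TMM -> log2(CPM+1) -> empirical controls -> RUVg, in one call.

    The adjusted expression is returned on the log2(CPM+1) scale; downstream
    differential analysis and classification consume this matrix.
    """
    factors = compute_tmm_factors(counts, params)
    libsize = counts.sum(axis=0).astype(float)
    eff = libsize * factors
    logexpr = log_cpm(counts, factors)
    controls = select_control_genes(logexpr, groups, control_fraction)
    w, adjusted = ruvg_adjust(logexpr, controls, k)
    return NormalizationResult(
        tmm_factors=factors,
        effective_library_sizes=eff.rename("effective_library_size"),
        control_genes=controls,
        W=w,
        adjusted_logexpr=adjusted,
    )
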