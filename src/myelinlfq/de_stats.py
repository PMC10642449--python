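"""Normalization and differential-abundance testing.

The moderated two-sample t-test shrinks each protein's pooled residual
variance s^2 toward a prior variance s0^2 with prior degrees of freedom
d0, both estimated across the whole proteome by moment-matching on
log sample variances (the empirical-Bayes scheme of moderated
t-statistics):

    s_post^2 = (d0 * s0^2 + df * s^2) / (d0 + df)
    t_mod    = log2FC / sqrt(s_post^2 * (1/n1 + 1/n2))

with t_mod referred to a Student t distribution on d0 + df degrees of
freedom (fractional d0 allowed; d0 = inf means full shrinkage and a
normal reference). This borrows strength across proteins and stabilizes
the denominators of low-replicate (n=3 per group) comparisons.

Multiple testing is corrected by Benjamini-Hochberg q-values (default)
or Storey q-values (BH scaled by the lambda-grid estimate of the null
proportion pi0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConfigError,
    DegenerateInputError,
    InsufficientDataError,
    InvalidDesignError,
    PipelineOrderError,
    TransformError,
)
from .types import LOG2, NORMALIZED, RAW, IntensityMatrix, SampleDesign, two_group_arrays


@dataclass
class ModerationPrior:
    """Prior degrees of freedom and prior variance for variance shrinkage."""

    d0: float      # may be np.inf
    s0_sq: float

    def __post_init__(self) -> None:
        # d0 = 0 is the shrinkage-free limit (ordinary t); d0 = inf is full
        # shrinkage toward s0_sq
        if not self.d0 >= 0:
            raise ConfigError("d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ConfigError("s0_sq must be positive")


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Cell-wise log2; missing cells preserved; rejects non-positive values."""
    vals = matrix.values
    bad = (vals <= 0).stack()
    bad = bad[bad]
    if len(bad):
        pid, sample = bad.index[0]
        raise TransformError(
            f"non-positive observed value at ({pid}, {sample}); cannot log2-transform"
        )
    return IntensityMatrix(np.log2(vals), LOG2)


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Force every sample column onto the common distribution of sorted-row
    means, preserving within-column rank order. Requires a complete matrix
    (impute first)."""
    if matrix.n_missing():
        raise PipelineOrderError("matrix has missing cells; impute before normalizing")
    arr = matrix.values.to_numpy(float)
    order = np.argsort(arr, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n, m = arr.shape
    rows = np.arange(n)
    for j in range(m):
        ranks[order[:, j], j] = rows
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = mean_sorted[ranks]
    return IntensityMatrix(
        pd.DataFrame(out, index=matrix.proteins, columns=matrix.samples), NORMALIZED
    )


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone decreasing convexity of trigamma; initialized from
    the asymptotic relation trigamma(x) ~ 1/x.
    """
    if y <= 0:
        raise ConfigError("trigamma inverse requires y > 0")
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_moderation_prior(s_sq: np.ndarray, df_residual: float) -> ModerationPrior:
    """Estimate (d0, s0^2) by moment-matching on log sample variances.

    Given s^2 ~ s0^2 * F(df_residual, d0), the mean and variance of
    log(s^2) are closed forms in digamma/trigamma; matching the empirical
    moments and inverting trigamma numerically recovers the prior. If the
    empirical spread of log variances does not exceed the expected
    sampling spread, the prior is reported as d0 = inf with s0^2 at the
    bias-corrected geometric-mean location (full shrinkage).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq) & (s_sq > 0)]
    if len(s_sq) < 10:
        raise InsufficientDataError("need >= 10 positive finite variances to fit prior")
    if df_residual <= 0:
        raise ConfigError("df_residual must be positive")

    z = np.log(s_sq)
    half_df = df_residual / 2.0
    e = z - special.digamma(half_df) + np.log(half_df)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    expected_spread = float(special.polygamma(1, half_df))
    excess = e_var - expected_spread
    if excess <= 0:
        return ModerationPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def pooled_variances(
    matrix: IntensityMatrix, design: SampleDesign
) -> tuple[np.ndarray, float]:
    """Per-protein pooled two-group residual variance and its df."""
    _, _, x1, x2 = two_group_arrays(matrix, design)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise InvalidDesignError("each group needs >= 2 samples")
    df = n1 + n2 - 2
    v1 = np.var(x1, axis=1, ddof=1)
    v2 = np.var(x2, axis=1, ddof=1)
    s_sq = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    return s_sq, float(df)


def moderated_t_test(
    matrix: IntensityMatrix,
    design: SampleDesign,
    prior: ModerationPrior,
    n_imputed_cells: pd.Series | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test, protein-wise.

    log2FC is mean(group2) - mean(group1), i.e. second group versus the
    design's first (reference) group. Zero-variance proteins (posterior
    variance 0, only possible with d0 = 0-like degenerate priors) get
    p = 1 and a ``zero_variance`` flag rather than being dropped.

    Returns a DataFrame indexed by protein id with columns mean_g1,
    mean_g2, log2fc, s_sq, s_post_sq, t_ordinary, t_moderated,
    df_residual, df_total, p, zero_variance, n_imputed_cells.
    """
    g1, g2, x1, x2 = two_group_arrays(matrix, design)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise InvalidDesignError("each group needs >= 2 samples")
    s_sq, df = pooled_variances(matrix, design)
    mean1 = x1.mean(axis=1)
    mean2 = x2.mean(axis=1)
    log2fc = mean2 - mean1
    se_factor = 1.0 / n1 + 1.0 / n2

    if np.isinf(prior.d0):
        s_post = np.full_like(s_sq, prior.s0_sq)
        df_total = np.inf
    else:
        s_post = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
        df_total = df + prior.d0

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = log2fc / np.sqrt(s_sq * se_factor)
        t_mod = log2fc / np.sqrt(s_post * se_factor)

    zero_var = s_post <= 0
    p = np.ones_like(log2fc)
    ok = ~zero_var
    p[ok] = 2.0 * stats.t.sf(np.abs(t_mod[ok]), df_total)
    t_mod = np.where(zero_var, np.nan, t_mod)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} proteins with zero posterior variance; p set to 1",
            stacklevel=2,
        )

    out = pd.DataFrame(
        {
            "mean_g1": mean1,
            "mean_g2": mean2,
            "log2fc": log2fc,
            "s_sq": s_sq,
            "s_post_sq": s_post,
            "t_ordinary": t_ord,
            "t_moderated": t_mod,
            "df_residual": df,
            "df_total": df_total,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
            "zero_variance": zero_var,
        },
        index=matrix.proteins,
    )
    out.attrs["groups"] = (g1, g2)
    out["n_imputed_cells"] = (
        n_imputed_cells.reindex(out.index).fillna(0).astype(int)
        if n_imputed_cells is not None
        else 0
    )
    return out


def paired_t_test(matrix: IntensityMatrix, design: SampleDesign) -> pd.DataFrame:
    """Two-sided paired t-test on within-pair log2 differences.

    Differences are second condition minus first (crush - intact for the
    default injury design). Proteins whose pairwise-complete difference
    count is < 2 get NaN statistics and a ``dropped`` flag; zero-variance
    nonzero differences get p = 1 and a ``zero_variance`` flag.
    """
    pair_table = design.pair_table()
    conditions = list(pair_table.columns)
    if len(conditions) != 2:
        raise InvalidDesignError("paired test needs exactly 2 conditions")
    # preserve design group order: first group = reference
    ordered = [g for g in design.groups if g in conditions]
    c1, c2 = ordered
    if len(pair_table) < 2:
        raise InvalidDesignError("need >= 2 pairs")
    x1 = matrix.values[pair_table[c1]].to_numpy(float)
    x2 = matrix.values[pair_table[c2]].to_numpy(float)
    d = x2 - x1
    n_complete = np.sum(~np.isnan(d), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_d = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=1)
        sd_d = np.array([np.std(row[~np.isnan(row)], ddof=1) if (len(row[~np.isnan(row)]) >= 2) else np.nan for row in d])

    dropped = n_complete < 2
    zero_var = (~dropped) & (sd_d == 0)
    df = n_complete - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(n_complete))
    p = np.full(len(d), np.nan)
    ok = ~dropped & ~zero_var
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    # all-zero differences: t = 0, p = 1 (well-defined); nonzero constant
    # differences: degenerate, flagged with p = 1
    allzero = zero_var & (mean_d == 0)
    t[allzero], p[allzero] = 0.0, 1.0
    p[zero_var & ~allzero] = 1.0
    t[zero_var & ~allzero] = np.nan

    out = pd.DataFrame(
        {
            "log2fc": mean_d,
            "sd_diff": sd_d,
            "n_pairs": n_complete,
            "df": df,
            "t": t,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
            "zero_variance": zero_var,
            "dropped": dropped,
        },
        index=matrix.proteins,
    )
    out.attrs["conditions"] = (c1, c2)
    return out


def storey_pi0(p: np.ndarray, lambda_grid: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 by the lambda-grid smoother.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) is smoothed with a
    cubic spline over the grid and evaluated at the largest lambda;
    clipped into (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    m = len(p)
    pi0_lambda = np.array([np.sum(p > lam) / (m * (1 - lam)) for lam in lambda_grid])
    if len(lambda_grid) < 4:
        pi0 = pi0_lambda[-1]
    else:
        from scipy.interpolate import UnivariateSpline

        spline = UnivariateSpline(lambda_grid, pi0_lambda, k=3)
        pi0 = float(spline(lambda_grid.max()))
    return float(np.clip(pi0, np.nextafter(0, 1), 1.0))


def adjust_fdr(
    p: np.ndarray | pd.Series,
    method: str = "bh",
    lambda_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, float | None]:
    """FDR q-values: Benjamini-Hochberg step-up, or Storey (BH * pi0).

    Returns (q, pi0) with pi0 = None for plain BH.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ConfigError("p-values must lie in (0, 1]")
    if method == "bh":
        q = multipletests(arr, method="fdr_bh")[1]
        return q, None
    if method == "storey":
        pi0 = storey_pi0(arr, lambda_grid)
        q = np.minimum(multipletests(arr, method="fdr_bh")[1] * pi0, 1.0)
        return q, pi0
    raise ConfigError(f"unknown FDR method {method!r}")
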