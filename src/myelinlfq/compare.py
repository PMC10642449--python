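"""Cross-dataset and descriptive comparisons: proteome overlap, Spearman
rank correlations, the fold-change-versus-abundance association, and
row-wise z-scoring for heatmap-style displays."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .types import IntensityMatrix

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_intersection: int
    n_a_only: int
    n_b_only: int


@dataclass
class CorrelationResult:
    rho: float
    p: float | None
    n_pairs: int


def normalize_accession(acc: str) -> str:
    """Uppercase and strip an isoform suffix (``P12345-2`` -> ``P12345``)."""
    acc = acc.strip().upper()
    return acc.split("-")[0]


def proteome_overlap(
    ids_a, ids_b, normalize: bool = True
) -> OverlapResult:
    """Exact set arithmetic on two accession collections.

    Duplicates within a collection are de-duplicated with a logged warning.
    """
    la, lb = list(ids_a), list(ids_b)
    if normalize:
        la = [normalize_accession(a) for a in la]
        lb = [normalize_accession(b) for b in lb]
    sa, sb = set(la), set(lb)
    if len(sa) < len(la):
        logger.warning("proteome_overlap: %d duplicate ids in set A removed", len(la) - len(sa))
    if len(sb) < len(lb):
        logger.warning("proteome_overlap: %d duplicate ids in set B removed", len(lb) - len(sb))
    inter = sa & sb
    return OverlapResult(
        n_a=len(sa),
        n_b=len(sb),
        n_intersection=len(inter),
        n_a_only=len(sa - sb),
        n_b_only=len(sb - sa),
    )


def spearman(x, y) -> CorrelationResult:
    """Spearman's rho: product-moment correlation of mid-ranks (average
    ranks for ties), p by the large-sample t approximation.

    Pairs with any missing value are dropped first. A constant vector
    leaves the correlation undefined (rho = NaN, p = None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InsufficientDataError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=np.nan, p=None, n_pairs=n)
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return CorrelationResult(rho=float(np.sign(rho)), p=0.0, n_pairs=n)
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p=p, n_pairs=n)


def fc_vs_abundance(
    de: pd.DataFrame, baseline_abundance: pd.Series | dict
) -> CorrelationResult:
    """Spearman correlation of per-protein log2FC against log2 baseline
    abundance (e.g. reference-group mean iBAQ). A negative rho means the
    more abundant proteins tend to be downregulated."""
    base = pd.Series(baseline_abundance, dtype=float)
    shared = de.index.intersection(base.index)
    if len(shared) < 3:
        raise InsufficientDataError("fewer than 3 proteins shared between inputs")
    return spearman(de.loc[shared, "log2fc"], np.log2(base.loc[shared]))


def row_zscore(matrix: IntensityMatrix) -> tuple[IntensityMatrix, pd.Index]:
    """Row-wise z-score (mean 0, sample sd 1 per protein).

    Zero-sd rows cannot be scaled; they are emitted as all-zero rows and
    returned in the flagged index alongside a logged warning.
    """
    vals = matrix.values
    if vals.shape[1] < 2:
        raise InsufficientDataError("row z-scoring needs >= 2 samples")
    means = vals.mean(axis=1)
    sds = vals.std(axis=1, ddof=1)
    flagged = vals.index[sds == 0]
    if len(flagged):
        logger.warning("row_zscore: %d constant rows emitted as zeros", len(flagged))
    safe_sd = sds.replace(0, np.nan)
    out = vals.sub(means, axis=0).div(safe_sd, axis=0)
    out.loc[flagged] = 0.0
    return IntensityMatrix(out, matrix.scale), flagged
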