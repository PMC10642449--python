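"""Enrichment statistics: the binomial subset test against an empirically
calibrated null, Fisher-exact over-representation against a proteome
background, and Cohen's d effect sizes.

The binomial test asks whether a protein subset (e.g. the myelin
proteins) is regulated more often than the proteome at large: the
"ground probability" p0 is the fraction of *all* quantified proteins
meeting the regulation criterion (sign of log2FC and q below alpha), and
the subset's count of qualifying proteins is referred to a one-sided
Binomial(n_subset, p0) upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigError,
    DegenerateInputError,
    EmptyInputError,
    InsufficientDataError,
    MembershipError,
)
from .de_stats import adjust_fdr

DOWN = "down"
UP = "up"


@dataclass
class BinomialEnrichment:
    n_subset: int
    k_regulated: int
    p0_ground: float
    direction: str
    p_value: float


def _qualifies(de: pd.DataFrame, direction: str, alpha: float) -> pd.Series:
    if direction not in (DOWN, UP):
        raise ConfigError(f"direction must be 'down' or 'up', got {direction!r}")
    if "q" not in de.columns:
        raise ConfigError("DE table lacks a 'q' column; run adjust_fdr first")
    sign_ok = de["log2fc"] < 0 if direction == DOWN else de["log2fc"] > 0
    return sign_ok & (de["q"] < alpha)


def ground_probability(de_universe: pd.DataFrame, direction: str = DOWN, alpha: float = 0.05) -> float:
    """Fraction of universe proteins regulated in ``direction`` at q < alpha."""
    if len(de_universe) == 0:
        raise EmptyInputError("empty DE universe")
    return float(_qualifies(de_universe, direction, alpha).mean())


def binomial_subset_test(
    subset: pd.DataFrame,
    p0: float,
    direction: str = DOWN,
    alpha: float = 0.05,
) -> BinomialEnrichment:
    """One-sided exact binomial upper tail P(X >= k | n, p0) for the number
    of subset proteins meeting the regulation criterion."""
    if len(subset) == 0:
        raise EmptyInputError("empty subset")
    if not 0 < p0 < 1:
        raise DegenerateInputError("ground probability must lie strictly in (0, 1)")
    n = len(subset)
    k = int(_qualifies(subset, direction, alpha).sum())
    # exact upper tail; survival function of k-1 accumulates pmf from k..n
    p = float(stats.binom.sf(k - 1, n, p0)) if k > 0 else 1.0
    return BinomialEnrichment(n_subset=n, k_regulated=k, p0_ground=p0, direction=direction, p_value=min(p, 1.0))


def fisher_ora(
    study_set,
    background,
    gene_sets: dict[str, set],
    p_threshold: float = 0.1,
) -> pd.DataFrame:
    """One-sided Fisher-exact over-representation per gene set.

    Gene sets are intersected with the background before tabulation; the
    2x2 table per set is [[in study & in set, in study not in set],
    [in set not study, in neither]]. Per-set p-values are reported raw
    (the enrichment criterion here is an unadjusted threshold) plus a
    BH-adjusted column for transparency.
    """
    study = set(study_set)
    bg = set(background)
    offenders = study - bg
    if offenders:
        raise MembershipError(
            f"study set not contained in background; offenders: {sorted(offenders)[:5]}"
        )
    rows = []
    for set_id, members in sorted(gene_sets.items()):
        in_bg = set(members) & bg
        a = len(study & in_bg)
        b = len(study - in_bg)
        c = len(in_bg - study)
        d = len(bg) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        odds = np.inf if b * c == 0 and a * d > 0 else (a * d) / (b * c) if b * c else np.nan
        rows.append((set_id, a, b, c, d, odds, float(p)))
    out = pd.DataFrame(
        rows,
        columns=["set_id", "a_in_study", "b_study_not_set", "c_set_not_study", "d_neither", "odds_ratio", "fisher_p"],
    )
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["fisher_p_bh"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
        out["enriched"] = out["fisher_p"] <= p_threshold
    return out


def cohens_d(group1, group2) -> float:
    """Pooled-SD standardized mean difference (group1 - group2).

    Undefined (NaN) when the pooled standard deviation is zero.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    n1, n2 = len(x), len(y)
    pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    if pooled == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / pooled)
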