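"""Missingness classification and mechanism-aware imputation.

For a pairwise two-group comparison every protein row is assigned exactly
one label:

* ``COMPLETE`` — no missing values;
* ``MNAR`` — missing not at random: heavily missing in one group while
  well observed in the other, interpreted as a real depletion and imputed
  with the MinDet rule (each missing cell gets the minimum observed value
  of its own sample column — left-censored detection-limit imputation);
* ``MAR`` — missing at random: a light, group-balanced sprinkling of
  missing values, imputed by k-nearest-neighbour rows;
* ``FILTERED`` — too little information (fewer than 2 observed values in
  both groups, or any presence pattern matching none of the above);
  dropped from the analysis with an audit record.

The thresholds are a :class:`MissingnessRule`, parameterized because the
appropriate counts depend on the group size. The shipped default for
n=3 replicate groups: MNAR needs >=2/3 missing in the depleted group and
3/3 present in the other; MAR tolerates at most 1 missing per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ImputationError
from .types import IntensityMatrix, SampleDesign, two_group_arrays

logger = logging.getLogger(__name__)

COMPLETE = "COMPLETE"
MNAR = "MNAR"
MAR = "MAR"
FILTERED = "FILTERED"


@dataclass(frozen=True)
class MissingnessRule:
    group_size: int
    mnar_min_missing: int        # missing count in the depleted group
    mnar_min_present_other: int  # observed count required in the other group
    mar_max_missing: int         # per-group ceiling for the MAR label

    def __post_init__(self) -> None:
        if not 1 <= self.mnar_min_missing <= self.group_size:
            raise ConfigError("mnar_min_missing out of range")
        if not 1 <= self.mnar_min_present_other <= self.group_size:
            raise ConfigError("mnar_min_present_other out of range")
        if not 0 <= self.mar_max_missing <= self.group_size:
            raise ConfigError("mar_max_missing out of range")

    @classmethod
    def for_group_size(cls, n: int) -> "MissingnessRule":
        """Proportional transcription of the published 5-replicate rule.

        n=5: MNAR = missing in >=3/5 of one group and present in >=3/5 of
        the other; MAR = at most 2 missing per group. n=3 scales to
        MNAR >=2/3 missing vs. 3/3 present, MAR <=1 missing.
        """
        if n == 5:
            return cls(5, 3, 3, 2)
        if n == 3:
            return cls(3, 2, 3, 1)
        # general proportional fallback
        return cls(n, max(1, int(np.ceil(0.6 * n))), max(1, int(np.ceil(0.6 * n))), max(0, n // 2 - 1))


@dataclass
class MissingnessLabel:
    label: str
    depleted_group: str | None = None  # set when label == MNAR
    reason: str | None = None          # set when label == FILTERED


def classify_missingness(
    obs1: np.ndarray | list,
    obs2: np.ndarray | list,
    rule: MissingnessRule,
    group_names: tuple[str, str] = ("group1", "group2"),
) -> MissingnessLabel:
    """Classify one protein row's presence pattern for a two-group comparison.

    ``obs1``/``obs2`` are the per-sample values (NaN = missing) of the two
    groups. Precedence: COMPLETE, FILTERED (<2 observed in both groups),
    MNAR, MAR; any remaining pattern is FILTERED as uninformative.
    """
    a = np.asarray(obs1, dtype=float)
    b = np.asarray(obs2, dtype=float)
    if len(a) != rule.group_size or len(b) != rule.group_size:
        raise ConfigError(
            f"rule is for group size {rule.group_size}, got {len(a)} and {len(b)}"
        )
    miss_a, miss_b = int(np.isnan(a).sum()), int(np.isnan(b).sum())
    obs_a, obs_b = len(a) - miss_a, len(b) - miss_b
    if miss_a == 0 and miss_b == 0:
        return MissingnessLabel(COMPLETE)
    if obs_a < 2 and obs_b < 2:
        return MissingnessLabel(FILTERED, reason="fewer than 2 observed in both groups")
    if miss_a >= rule.mnar_min_missing and obs_b >= rule.mnar_min_present_other:
        return MissingnessLabel(MNAR, depleted_group=group_names[0])
    if miss_b >= rule.mnar_min_missing and obs_a >= rule.mnar_min_present_other:
        return MissingnessLabel(MNAR, depleted_group=group_names[1])
    if miss_a <= rule.mar_max_missing and miss_b <= rule.mar_max_missing:
        return MissingnessLabel(MAR)
    return MissingnessLabel(FILTERED, reason="pattern matches neither MNAR nor MAR rule")


def classify_matrix(
    matrix: IntensityMatrix, design: SampleDesign, rule: MissingnessRule
) -> pd.DataFrame:
    """Per-protein labels for a two-group matrix.

    Returns a DataFrame indexed by protein with columns ``label``,
    ``depleted_group`` and ``reason``.
    """
    g1, g2, x1, x2 = two_group_arrays(matrix, design)
    rows = []
    for i in range(x1.shape[0]):
        lab = classify_missingness(x1[i], x2[i], rule, (g1, g2))
        rows.append((lab.label, lab.depleted_group, lab.reason))
    return pd.DataFrame(
        rows, index=matrix.proteins, columns=["label", "depleted_group", "reason"]
    )


def impute_mindet(
    matrix: IntensityMatrix, targets: list[tuple[str, str]]
) -> IntensityMatrix:
    """Replace each target cell with the minimum observed value of its own
    sample column (detection-limit surrogate for left-censored MNAR cells)."""
    out = matrix.values.copy()
    col_min = out.min(axis=0, skipna=True)
    for pid, sample in targets:
        if np.isnan(col_min[sample]):
            raise ImputationError(f"column {sample!r} has no observed values")
        out.loc[pid, sample] = col_min[sample]
    return IntensityMatrix(out, matrix.scale)


def impute_knn(
    matrix: IntensityMatrix, targets: list[tuple[str, str]], k: int = 10
) -> IntensityMatrix:
    """Row-wise k-nearest-neighbour imputation for MAR cells.

    For a target cell (protein p, sample s), candidate neighbours are the
    other protein rows with an observed value at s; distance is Euclidean
    over the columns observed in both rows; the imputed value is the mean
    of the k nearest candidates' values at s. Ties broken by protein id
    for determinism. If fewer than k candidates exist, all are used and a
    warning is logged (never silent).
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    values = matrix.values
    arr = values.to_numpy(float)
    ids = list(values.index)
    id_pos = {pid: i for i, pid in enumerate(ids)}
    col_pos = {s: j for j, s in enumerate(values.columns)}
    out = values.copy()

    for pid, sample in targets:
        i, j = id_pos[pid], col_pos[sample]
        row = arr[i]
        dists: list[tuple[float, str, float]] = []
        for c, cid in enumerate(ids):
            if c == i or np.isnan(arr[c, j]):
                continue
            shared = ~np.isnan(row) & ~np.isnan(arr[c])
            if not shared.any():
                continue
            d = float(np.sqrt(np.sum((row[shared] - arr[c][shared]) ** 2)))
            dists.append((d, cid, arr[c, j]))
        if not dists:
            raise ImputationError(f"no knn candidates for cell ({pid}, {sample})")
        if len(dists) < k:
            logger.warning(
                "knn: only %d candidates for cell (%s, %s); using all (k=%d requested)",
                len(dists), pid, sample, k,
            )
        dists.sort(key=lambda t: (t[0], t[1]))
        neighbours = dists[:k]
        out.loc[pid, sample] = float(np.mean([v for _, _, v in neighbours]))
    return IntensityMatrix(out, matrix.scale)


def apply_imputation(
    matrix: IntensityMatrix,
    design: SampleDesign,
    rule: MissingnessRule,
    k: int = 10,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Classify, filter and impute a two-group matrix.

    FILTERED rows are dropped; missing cells in MNAR rows are
    MinDet-imputed; missing cells in MAR rows are knn-imputed. The audit
    table records one row per imputed cell (protein, sample, mechanism,
    imputed value) and one row per filtered protein (with its reason).
    """
    labels = classify_matrix(matrix, design, rule)
    audit_rows = []

    keep = labels["label"] != FILTERED
    for pid in labels.index[~keep]:
        audit_rows.append((pid, "", FILTERED, np.nan, labels.loc[pid, "reason"]))
    kept = IntensityMatrix(matrix.values.loc[keep].copy(), matrix.scale)

    def _missing_cells(pids) -> list[tuple[str, str]]:
        cells = []
        for pid in pids:
            row = kept.values.loc[pid]
            cells.extend((pid, s) for s in row.index[row.isna()])
        return cells

    mnar_cells = _missing_cells(labels.index[labels["label"] == MNAR].intersection(kept.proteins))
    mar_cells = _missing_cells(labels.index[labels["label"] == MAR].intersection(kept.proteins))

    imputed = impute_mindet(kept, mnar_cells)
    imputed = impute_knn(imputed, mar_cells, k=k) if mar_cells else imputed

    for pid, s in mnar_cells:
        audit_rows.append((pid, s, MNAR, float(imputed.values.loc[pid, s]), "MinDet"))
    for pid, s in mar_cells:
        audit_rows.append((pid, s, MAR, float(imputed.values.loc[pid, s]), f"knn(k={k})"))
    audit = pd.DataFrame(
        audit_rows, columns=["protein_id", "sample", "mechanism", "imputed_value", "detail"]
    )
    return imputed, audit
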