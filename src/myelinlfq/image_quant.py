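"""Mask-based two-channel fluorescence quantification.

Three measures for a collagen (Col4a1) / myelin (MBP) stained section:

1. ``intensity_per_area`` — raw integrated density of the collagen
   channel inside the collagen-positive mask, normalized to that mask's
   area (mean in-mask intensity);
2. ``coverage_within_mask`` — the percentage of collagen-positive area
   lying inside the myelin mask (colocalization of the collagen signal
   with myelin);
3. ``overlap_intensity_normalized`` — integrated collagen density within
   the overlap, divided first by the coverage percentage and then by the
   myelin-mask area. Units are arbitrary; only between-group ratios are
   meaningful.

Masks are user inputs; a fixed-threshold convenience builder is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .enrich import cohens_d
from .errors import DegenerateInputError, EmptyMaskError, SchemaError


@dataclass
class MaskedImagePair:
    channel_col: np.ndarray
    channel_mbp: np.ndarray
    mask_col: np.ndarray
    mask_mbp: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.channel_col, self.channel_mbp, self.mask_col, self.mask_mbp)}
        if len(shapes) != 1:
            raise SchemaError(f"channel/mask shapes differ: {shapes}")
        if self.mask_col.dtype != bool or self.mask_mbp.dtype != bool:
            raise SchemaError("masks must be boolean arrays")


@dataclass
class ImageQuantResult:
    intensity_per_area: float
    coverage_pct: float
    overlap_intensity_norm: float


def threshold_mask(channel: np.ndarray, threshold: float) -> np.ndarray:
    """Fixed-threshold mask builder: pixel > threshold."""
    return np.asarray(channel) > threshold


def intensity_per_area(channel: np.ndarray, mask: np.ndarray) -> float:
    """Raw integrated density within the mask, per mask pixel."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise EmptyMaskError("mask contains no positive pixels")
    return float(np.asarray(channel, dtype=float)[mask].sum() / n)


def coverage_within_mask(
    mask_col: np.ndarray, mask_mbp: np.ndarray, denominator: str = "col"
) -> float:
    """Percentage of collagen-positive area inside the myelin mask.

    ``denominator="col"`` (default) normalizes by the collagen mask area;
    ``"mbp"`` by the myelin mask area.
    """
    mask_col = np.asarray(mask_col, dtype=bool)
    mask_mbp = np.asarray(mask_mbp, dtype=bool)
    if mask_col.shape != mask_mbp.shape:
        raise SchemaError("mask shapes differ")
    denom_mask = mask_col if denominator == "col" else mask_mbp
    denom = int(denom_mask.sum())
    if denom == 0:
        raise EmptyMaskError("denominator mask is empty")
    return float(100.0 * np.logical_and(mask_col, mask_mbp).sum() / denom)


def overlap_intensity_normalized(
    channel_col: np.ndarray, mask_col: np.ndarray, mask_mbp: np.ndarray
) -> float:
    """Collagen density within the collagen/myelin overlap, normalized by
    the coverage percentage and then by the myelin mask area."""
    mask_col = np.asarray(mask_col, dtype=bool)
    mask_mbp = np.asarray(mask_mbp, dtype=bool)
    if mask_col.sum() == 0 or mask_mbp.sum() == 0:
        raise EmptyMaskError("both masks must be non-empty")
    overlap = mask_col & mask_mbp
    if overlap.sum() == 0:
        raise DegenerateInputError("zero overlap between masks; measure undefined")
    density = float(np.asarray(channel_col, dtype=float)[overlap].sum())
    coverage = coverage_within_mask(mask_col, mask_mbp, denominator="col")
    return density / coverage / float(mask_mbp.sum())


def quantify_pair(pair: MaskedImagePair) -> ImageQuantResult:
    """All three measures for one image pair."""
    return ImageQuantResult(
        intensity_per_area=intensity_per_area(pair.channel_col, pair.mask_col),
        coverage_pct=coverage_within_mask(pair.mask_col, pair.mask_mbp),
        overlap_intensity_norm=overlap_intensity_normalized(
            pair.channel_col, pair.mask_col, pair.mask_mbp
        ),
    )


def compare_groups(values_young, values_old) -> tuple[float, float, float]:
    """Unpaired two-tailed pooled-variance t-test plus Cohen's d
    (young - old convention). Degenerate (zero pooled variance with a
    nonzero difference) comparisons return NaN statistics."""
    x = np.asarray(values_young, dtype=float)
    y = np.asarray(values_old, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateInputError("each group needs >= 2 values")
    d = cohens_d(x, y)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        # degenerate: no within-group variance; comparable only when equal
        if x.mean() == y.mean():
            return 0.0, 1.0, d
        return float("nan"), float("nan"), d
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p), d
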