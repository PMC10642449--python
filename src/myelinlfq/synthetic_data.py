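"""Synthetic label-free proteomics experiments with known ground truth.

The generator emulates the structure of peripheral-nerve myelin LFQ data:

* heavy right-skewed (log-normal) protein abundance, with a handful of
  dominant proteins (the MPZ/MBP/PRX analogues) pinned to prescribed
  shares of total signal;
* per-group multiplicative log2 fold changes on a subset of proteins;
* intensity-dependent left-censored dropout (MNAR, logistic in log2
  intensity) plus a uniform random dropout (MAR), each missing cell
  carrying its true mechanism label;
* an unpaired groups-of-n design (aging: young vs. old pools) and a
  paired intact/crush design (injury: one pair of nerves per mouse).

Everything is drawn from a single :func:`numpy.random.default_rng` stream
so a given config + seed reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, DegenerateInputError, InvalidDesignError
from .types import RAW, IntensityMatrix, SampleDesign

MNAR_TRUE = "MNAR_TRUE"
MAR_TRUE = "MAR_TRUE"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic LFQ generator.

    ``top_fractions`` are the expected relative-abundance shares of the
    first ``len(top_fractions)`` proteins, defaulting to the young-myelin
    shares of the three dominant proteins (40/17/6%). ``cv_within_group``
    is the multiplicative within-group coefficient of variation.
    MNAR dropout probability for a cell of log2 intensity ``x`` is
    ``expit(mnar_steepness * (mnar_midpoint - x))``; MAR dropout is a
    uniform Bernoulli at ``mar_rate`` on the surviving cells.
    """

    n_proteins: int = 1000
    n_per_group: int = 3
    top_fractions: tuple[float, ...] = (0.40, 0.17, 0.06)
    de_fraction: float = 0.05
    de_log2fc_distribution: tuple[float, float] = (2.0, 1.0)  # (mean, sd) of |log2FC|
    cv_within_group: float = 0.25
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    mnar_midpoint: float = 17.0
    mnar_steepness: float = 1.0
    mar_rate: float = 0.02
    n_myelin: int | None = None  # injury designs: size of designated myelin set
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        if self.n_per_group < 2:
            raise InvalidDesignError("n_per_group must be >= 2")
        if any(not 0 < f < 1 for f in self.top_fractions):
            raise ConfigError("top_fractions must lie in (0, 1)")
        if sum(self.top_fractions) >= 1:
            raise ConfigError("sum(top_fractions) must be < 1")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if not 0 <= self.mar_rate <= 1:
            raise ConfigError("mar_rate must lie in [0, 1]")
        if self.cv_within_group <= 0:
            raise ConfigError("cv_within_group must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated matrix.

    ``proteins``: per-protein table (protein_id, true_base_abundance,
    true_log2fc, is_de, and is_myelin for injury designs).
    ``mechanisms``: one row per missing cell (protein_id, sample,
    mechanism in {MNAR_TRUE, MAR_TRUE}).
    """

    proteins: pd.DataFrame
    mechanisms: pd.DataFrame

    def mechanism_frame(self, like: IntensityMatrix) -> pd.DataFrame:
        """Mechanism labels re-shaped onto the matrix grid ('' = observed)."""
        frame = pd.DataFrame("", index=like.proteins, columns=like.samples)
        for _, row in self.mechanisms.iterrows():
            frame.loc[row["protein_id"], row["sample"]] = row["mechanism"]
        return frame


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def _base_abundances(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-normal base abundances; the top proteins are set deterministically
    so that their expected relative shares equal ``top_fractions``."""
    k = len(cfg.top_fractions)
    if cfg.n_proteins <= k:
        raise ConfigError(f"n_proteins must exceed the {k} pinned top proteins")
    rest = 2.0 ** rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, cfg.n_proteins - k)
    total = rest.sum() / (1.0 - sum(cfg.top_fractions))
    tops = np.array(cfg.top_fractions) * total
    return np.concatenate([tops, rest])


def _noise(cfg: SimulationConfig, rng: np.random.Generator, shape) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the configured CV."""
    sigma = np.sqrt(np.log1p(cfg.cv_within_group**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, shape))


def _apply_dropout(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    values: np.ndarray,
    protein_ids: list[str],
    samples: list[str],
) -> tuple[np.ndarray, pd.DataFrame]:
    """MNAR first (logistic in log2 intensity), then MAR on survivors.

    Order makes the two mechanism labels exhaustive and exclusive over
    missing cells.
    """
    log2v = np.log2(values)
    if np.isneginf(cfg.mnar_midpoint):
        # midpoint at -inf disables the MNAR mechanism entirely
        p_mnar = np.zeros_like(values)
    else:
        p_mnar = expit(cfg.mnar_steepness * (cfg.mnar_midpoint - log2v))
    mnar = rng.random(values.shape) < p_mnar
    mar = (rng.random(values.shape) < cfg.mar_rate) & ~mnar
    out = values.copy()
    out[mnar | mar] = np.nan
    rows = []
    for i, j in zip(*np.nonzero(mnar)):
        rows.append((protein_ids[i], samples[j], MNAR_TRUE))
    for i, j in zip(*np.nonzero(mar)):
        rows.append((protein_ids[i], samples[j], MAR_TRUE))
    mech = pd.DataFrame(rows, columns=["protein_id", "sample", "mechanism"])
    return out, mech


def default_aging_design(cfg: SimulationConfig) -> SampleDesign:
    return SampleDesign.from_groups(
        {
            "young": [f"young_{i}" for i in range(1, cfg.n_per_group + 1)],
            "old": [f"old_{i}" for i in range(1, cfg.n_per_group + 1)],
        }
    )


def simulate_lfq_experiment(
    config: SimulationConfig, design: SampleDesign | None = None
) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Simulate an unpaired LFQ experiment (young vs. old pools by default).

    The fold-change effect is applied to every non-reference group relative
    to the first group in the design. The dominant (pinned-share) proteins
    never carry an effect, mirroring the stability of the major myelin
    proteins.

    Returns a raw-scale matrix (NaN = missing) and the ground truth.
    """
    config.validate()
    if design is None:
        design = default_aging_design(config)
    groups = design.groups
    if len(groups) < 2:
        raise InvalidDesignError("need at least 2 groups")
    for g, n in design.group_sizes().items():
        if n < 2:
            raise InvalidDesignError(f"group {g!r} has fewer than 2 samples")

    rng = np.random.default_rng(config.seed)
    ids = _protein_ids(config.n_proteins)
    base = _base_abundances(config, rng)

    k_top = len(config.top_fractions)
    lfc = np.zeros(config.n_proteins)
    n_de = int(round(config.de_fraction * (config.n_proteins - k_top)))
    de_idx = rng.choice(np.arange(k_top, config.n_proteins), size=n_de, replace=False)
    mu, sd = config.de_log2fc_distribution
    magnitudes = np.abs(rng.normal(mu, sd, n_de))
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc[de_idx] = signs * magnitudes

    samples = design.samples
    is_ref = np.array([design.table.loc[design.table["sample"] == s, "group"].iloc[0] == groups[0] for s in samples])
    expected = base[:, None] * np.where(is_ref[None, :], 1.0, 2.0 ** lfc[:, None])
    values = expected * _noise(config, rng, (config.n_proteins, len(samples)))

    dropped, mech = _apply_dropout(config, rng, values, ids, samples)
    matrix = IntensityMatrix(pd.DataFrame(dropped, index=ids, columns=samples), RAW)
    proteins = pd.DataFrame(
        {
            "protein_id": ids,
            "true_base_abundance": base,
            "true_log2fc": lfc,
            "is_de": lfc != 0,
        }
    )
    return matrix, SyntheticTruth(proteins, mech)


def simulate_injury_experiment(
    config: SimulationConfig,
    n_mice: int,
    down_fraction: float,
    seed: int | None = None,
    background_down_fraction: float | None = None,
) -> tuple[IntensityMatrix, SampleDesign, SyntheticTruth]:
    """Simulate a paired intact/crush nerve experiment.

    One intact and one crushed sample per mouse. The first
    ``config.n_myelin`` proteins (default: a fifth of the proteome,
    including the dominant ones) form the designated "myelin" set; a
    ``down_fraction`` subset of it carries a negative true log2 fold
    change (crush vs. intact), as does a ``background_down_fraction``
    subset of the remaining proteins (default: ``config.de_fraction``).
    """
    config.validate()
    if n_mice < 2:
        raise InvalidDesignError("n_mice must be >= 2")
    if not 0 <= down_fraction <= 1:
        raise ConfigError("down_fraction must lie in [0, 1]")
    if background_down_fraction is None:
        background_down_fraction = config.de_fraction
    if seed is None:
        seed = config.seed

    n_myelin = config.n_myelin or max(1, config.n_proteins // 5)
    if n_myelin > config.n_proteins:
        raise ConfigError("n_myelin exceeds n_proteins")

    rng = np.random.default_rng(seed)
    ids = _protein_ids(config.n_proteins)
    base = _base_abundances(config, rng)

    lfc = np.zeros(config.n_proteins)
    mu, sd = config.de_log2fc_distribution
    n_down_my = int(round(down_fraction * n_myelin))
    my_idx = rng.choice(np.arange(n_myelin), size=n_down_my, replace=False)
    lfc[my_idx] = -np.abs(rng.normal(mu, sd, n_down_my))
    n_rest = config.n_proteins - n_myelin
    n_down_bg = int(round(background_down_fraction * n_rest))
    bg_idx = rng.choice(np.arange(n_myelin, config.n_proteins), size=n_down_bg, replace=False)
    lfc[bg_idx] = -np.abs(rng.normal(mu, sd, n_down_bg))

    design = SampleDesign.paired([f"m{i}" for i in range(1, n_mice + 1)])
    samples = design.samples
    is_crush = np.array(
        [design.table.loc[design.table["sample"] == s, "group"].iloc[0] == "crush" for s in samples]
    )
    expected = base[:, None] * np.where(is_crush[None, :], 2.0 ** lfc[:, None], 1.0)
    values = expected * _noise(config, rng, (config.n_proteins, len(samples)))

    dropped, mech = _apply_dropout(config, rng, values, ids, samples)
    matrix = IntensityMatrix(pd.DataFrame(dropped, index=ids, columns=samples), RAW)
    proteins = pd.DataFrame(
        {
            "protein_id": ids,
            "true_base_abundance": base,
            "true_log2fc": lfc,
            "is_de": lfc != 0,
            "is_myelin": np.arange(config.n_proteins) < n_myelin,
        }
    )
    return matrix, design, SyntheticTruth(proteins, mech)


@dataclass
class ImageFixture:
    """Two-channel synthetic nerve cross-section with pixel-exact truth masks."""

    channel_mbp: np.ndarray
    channel_col: np.ndarray
    mask_mbp: np.ndarray
    mask_col: np.ndarray


def generate_image_fixture(
    n_rings: int,
    ring_intensity: float,
    collagen_pattern: str,
    seed: int = 0,
    shape: tuple[int, int] = (192, 192),
    col_intensity: float = 120.0,
) -> ImageFixture:
    """Draw myelin rings (annuli) and a collagen channel with known masks.

    ``collagen_pattern="separate"`` places collagen strands strictly
    outside the ring mask (zero coverage by construction);
    ``"overlapping"`` places the collagen signal exactly on the ring
    annuli, so the collagen mask is a subset of the myelin mask.
    """
    if collagen_pattern not in ("separate", "overlapping"):
        raise ConfigError(f"unknown collagen_pattern {collagen_pattern!r}")
    if ring_intensity < 0 or col_intensity < 0:
        raise ConfigError("intensities must be >= 0")
    if n_rings == 0 and collagen_pattern == "overlapping":
        raise DegenerateInputError("overlapping pattern needs at least one ring")

    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask_mbp = np.zeros(shape, dtype=bool)
    r_outer, r_inner = 10.0, 6.0
    for _ in range(n_rings):
        cy = rng.uniform(r_outer + 2, h - r_outer - 2)
        cx = rng.uniform(r_outer + 2, w - r_outer - 2)
        dist = np.hypot(yy - cy, xx - cx)
        mask_mbp |= (dist <= r_outer) & (dist >= r_inner)

    channel_mbp = np.where(mask_mbp, float(ring_intensity), 0.0)

    if collagen_pattern == "overlapping":
        mask_col = mask_mbp.copy()
    else:
        mask_col = np.zeros(shape, dtype=bool)
        n_strands = max(3, n_rings)
        for _ in range(n_strands):
            x0 = int(rng.integers(1, w - 2))
            mask_col[:, x0 : x0 + 2] = True
        mask_col &= ~mask_mbp  # disjoint by construction
    channel_col = np.where(mask_col, float(col_intensity), 0.0)

    return ImageFixture(channel_mbp, channel_col, mask_mbp, mask_col)
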