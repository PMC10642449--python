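"""Core in-memory containers shared across the pipeline.

The protein quantification table travels through the pipeline as an
:class:`IntensityMatrix` — a proteins x samples :class:`pandas.DataFrame`
with ``NaN`` marking missing values and an explicit ``scale`` tag so that
stages can assert they are operating on the scale they expect (raw
intensities, log2, or quantile-normalized log2).

:class:`SampleDesign` maps samples to biological groups, with optional
pairing ids for paired (within-animal) designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, SchemaError

RAW = "raw"
LOG2 = "log2"
NORMALIZED = "normalized"
_SCALES = (RAW, LOG2, NORMALIZED)


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity table with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample;
        ``NaN`` encodes a missing (not-detected) cell.
    scale
        One of ``"raw"``, ``"log2"`` or ``"normalized"``.
    """

    values: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise SchemaError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate protein ids in intensity matrix")
        if self.values.columns.has_duplicates:
            raise SchemaError("duplicate sample ids in intensity matrix")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.scale)

    # -- I/O: empty cell = missing ------------------------------------
    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="protein_id", na_rep="")

    @classmethod
    def read_tsv(cls, path, scale: str = RAW) -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        return cls(df.astype(float), scale)


@dataclass
class SampleDesign:
    """Sample -> group mapping with optional pairing (animal) ids.

    ``table`` has columns ``sample``, ``group`` and optionally ``pair_id``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "group"}
        if not required.issubset(self.table.columns):
            raise SchemaError(f"design table must have columns {sorted(required)}")
        if self.table["sample"].duplicated().any():
            raise SchemaError("duplicate sample ids in design")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_groups(cls, groups: dict[str, list[str]]) -> "SampleDesign":
        rows = [(s, g) for g, samples in groups.items() for s in samples]
        return cls(pd.DataFrame(rows, columns=["sample", "group"]))

    @classmethod
    def paired(cls, pair_ids: list[str], conditions: tuple[str, str] = ("intact", "crush")) -> "SampleDesign":
        rows = [
            (f"{pid}_{cond}", cond, pid)
            for pid in pair_ids
            for cond in conditions
        ]
        return cls(pd.DataFrame(rows, columns=["sample", "group", "pair_id"]))

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def groups(self) -> list[str]:
        # preserve first-appearance order (reference group = first)
        return list(dict.fromkeys(self.table["group"]))

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample"])

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in self.groups}

    @property
    def has_pairs(self) -> bool:
        return "pair_id" in self.table.columns and self.table["pair_id"].notna().all()

    def pair_table(self) -> pd.DataFrame:
        """Pivot to pair_id x group sample names; validates 1 sample/condition."""
        if not self.has_pairs:
            raise InvalidDesignError("design has no complete pair_id column")
        pivot = self.table.pivot(index="pair_id", columns="group", values="sample")
        if pivot.isna().any().any():
            raise InvalidDesignError("every pair id needs exactly one sample per condition")
        return pivot

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t"))


def check_matrix_design(matrix: IntensityMatrix, design: SampleDesign) -> None:
    """Raise :class:`SchemaError` unless every design sample is a matrix column."""
    missing = set(design.samples) - set(matrix.samples)
    if missing:
        raise SchemaError(f"design samples absent from matrix: {sorted(missing)}")


def two_group_arrays(
    matrix: IntensityMatrix, design: SampleDesign
) -> tuple[str, str, np.ndarray, np.ndarray]:
    """Split a two-group design's columns into (name1, name2, values1, values2)."""
    check_matrix_design(matrix, design)
    groups = design.groups
    if len(groups) != 2:
        raise InvalidDesignError(f"expected exactly 2 groups, got {groups}")
    g1, g2 = groups
    x1 = matrix.values[design.samples_in(g1)].to_numpy(float)
    x2 = matrix.values[design.samples_in(g2)].to_numpy(float)
    return g1, g2, x1, x2
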