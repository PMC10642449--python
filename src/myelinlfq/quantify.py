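"""iBAQ quantification, relative-abundance summaries and the detection filter.

iBAQ (intensity-based absolute quantification) divides a protein's summed
peptide intensity by its count of theoretically observable fully-tryptic
peptides, making intensities comparable across proteins of different
length. The in-silico digest cleaves after K or R unless the next residue
is proline; "observable" peptides fall in a configurable length window
(default 7-30 residues, the usual iBAQ convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlphabetError,
    ConfigError,
    DegenerateInputError,
    EmptyInputError,
    SchemaError,
)
from .types import IntensityMatrix, SampleDesign, check_matrix_design

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_MIN_PEPTIDE_LEN = 7
DEFAULT_MAX_PEPTIDE_LEN = 30


@dataclass
class ProteinRecord:
    accession: str
    gene_name: str
    sequence: str

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)


@dataclass
class DigestResult:
    """Fully-cleaved tryptic peptides with 0-based half-open coordinates."""

    peptides: list[tuple[str, int, int]]
    observable_count: int | None = None


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise EmptyInputError("empty protein sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise AlphabetError(f"illegal residues in sequence: {sorted(bad)}")


def tryptic_digest(sequence: str) -> DigestResult:
    """Fully cleave a protein after K/R residues, unless followed by P.

    Zero missed cleavages; peptides tile the sequence contiguously.
    """
    _check_sequence(sequence)
    peptides: list[tuple[str, int, int]] = []
    start = 0
    for i, residue in enumerate(sequence):
        at_end = i == len(sequence) - 1
        cleave = residue in "KR" and not at_end and sequence[i + 1] != "P"
        if cleave or at_end:
            peptides.append((sequence[start : i + 1], start, i + 1))
            start = i + 1
    return DigestResult(peptides)


def count_observable(
    digest: DigestResult,
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> int:
    """Number of digest peptides with length in [min_len, max_len]."""
    if min_len > max_len:
        raise ConfigError("min_len must be <= max_len")
    return sum(1 for seq, _, _ in digest.peptides if min_len <= len(seq) <= max_len)


def compute_ibaq(peptide_intensity_sum: float, observable_count: int) -> float:
    """Summed peptide intensity divided by observable peptide count."""
    if observable_count < 1:
        raise DegenerateInputError(
            "iBAQ undefined: protein has zero observable peptides"
        )
    if peptide_intensity_sum < 0:
        raise ConfigError("peptide intensity sum must be >= 0")
    return peptide_intensity_sum / observable_count


def ibaq_from_peptides(
    peptide_table: pd.DataFrame,
    records: list[ProteinRecord],
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> pd.DataFrame:
    """Compute per-sample iBAQ from a peptide intensity table + sequences.

    ``peptide_table`` columns: ``protein_id``, ``peptide``, then one
    intensity column per sample. Proteins with zero observable peptides
    are flagged (returned with NaN iBAQ), never silently zeroed.
    """
    required = {"protein_id", "peptide"}
    if not required.issubset(peptide_table.columns):
        raise SchemaError(f"peptide table needs columns {sorted(required)}")
    sample_cols = [c for c in peptide_table.columns if c not in required]
    by_protein = peptide_table.groupby("protein_id")[sample_cols].sum()
    counts = {
        r.accession: count_observable(tryptic_digest(r.sequence), min_len, max_len)
        for r in records
    }
    out = {}
    for pid, sums in by_protein.iterrows():
        n_obs = counts.get(pid)
        if n_obs is None:
            raise SchemaError(f"no sequence record for protein {pid!r}")
        if n_obs == 0:
            logger.warning("protein %s has zero observable peptides; iBAQ flagged NaN", pid)
            out[pid] = sums * np.nan
        else:
            out[pid] = sums / n_obs
    return pd.DataFrame(out).T.rename_axis("protein_id")


def relative_abundance(ibaq_by_protein: pd.Series | dict) -> pd.Series:
    """Per-protein share of total iBAQ signal, in percent (sums to 100)."""
    s = pd.Series(ibaq_by_protein, dtype=float)
    if len(s) == 0:
        raise EmptyInputError("no proteins supplied")
    if (s < 0).any():
        raise ConfigError("iBAQ values must be >= 0")
    total = s.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero iBAQ input; shares undefined")
    return 100.0 * s / total


def detection_filter(
    matrix: IntensityMatrix,
    design: SampleDesign,
    min_detected: int = 2,
) -> tuple[IntensityMatrix, pd.Series]:
    """Keep proteins detected (>= ``min_detected`` non-missing values) in at
    least one group; label each protein's group presence.

    Labels: ``both`` (detected in every group), ``<group>_only``, or
    ``excluded`` (dropped from the returned matrix).
    """
    check_matrix_design(matrix, design)
    for g, n in design.group_sizes().items():
        if min_detected > n:
            raise ConfigError(f"min_detected={min_detected} exceeds size of group {g!r}")
    detected = {}
    for g in design.groups:
        cols = design.samples_in(g)
        detected[g] = matrix.values[cols].notna().sum(axis=1) >= min_detected
    det = pd.DataFrame(detected)
    n_groups_detected = det.sum(axis=1)
    labels = pd.Series("excluded", index=matrix.proteins, name="presence")
    labels[n_groups_detected == len(design.groups)] = "both"
    for g in design.groups:
        only = det[g] & (n_groups_detected == 1)
        labels[only] = f"{g}_only"
    kept = labels != "excluded"
    filtered = IntensityMatrix(matrix.values.loc[kept].copy(), matrix.scale)
    return filtered, labels


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records; gene name parsed from a UniProt-style ``GN=``
    tag when present, else the record id."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        for token in rec.description.split():
            if token.startswith("GN="):
                gene = token[3:]
        records.append(ProteinRecord(rec.id, gene, str(rec.seq).upper()))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records
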