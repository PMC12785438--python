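"""Domain types and file I/O for milk digesta peptidomics.

Peptide identity throughout the package is the bare uppercase sequence over
the 20-letter amino-acid alphabet; modification notation is rejected rather
than stripped, and duplicate rows in an input table are merged by summing
abundances per sample. Readers cover the three flat-file inputs of the
pipeline: a peptide abundance TSV (``sequence`` column plus one intensity
column per sample, empty cell = not detected), parent-protein FASTA, and a
bioactive-peptide reference TSV in the style of the Milk Bioactive Peptide
Database (MBPDB).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("lactopept")

#: The 20 proteinogenic residues; B, J, O, U, X, Z are not accepted.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """Malformed input file (bad header, missing column, empty file)."""


class ValidationError(ValueError):
    """Structurally valid file with invalid content (e.g. illegal residue)."""


def validate_sequence(sequence: str, context: str = "sequence") -> str:
    """Return ``sequence`` uppercased, or raise :class:`ValidationError`.

    Rejects empty strings and any character outside the 20-letter alphabet,
    including the ambiguity codes B/J/O/U/X/Z and modification notation.
    """
    if not sequence:
        raise ValidationError(f"{context}: empty sequence")
    seq = sequence.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValidationError(
            f"{context}: illegal residue(s) {sorted(bad)} in {sequence!r}"
        )
    return seq


@dataclass
class PeptideRecord:
    """One detected peptide: sequence plus per-sample abundances.

    ``abundances`` maps sample id to a non-negative intensity in arbitrary
    units; a sample absent from the map means the peptide was not detected
    in that sample. ``annotations`` optionally carries parent attribution
    (``parent``, ``start``, ``end``) and bookkeeping flags.
    """

    sequence: str
    abundances: dict[str, float] = field(default_factory=dict)
    annotations: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence, "PeptideRecord")
        for sample, value in self.abundances.items():
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValidationError(
                    f"{self.sequence}: use absence, not NaN, for missing sample {sample!r}"
                )
            if value < 0:
                raise ValidationError(
                    f"{self.sequence}: negative abundance {value} in sample {sample!r}"
                )


@dataclass
class PeptideTable:
    """A peptidome: unique peptide records over an ordered set of samples.

    ``groups`` maps every sample id to its group label; differential analysis
    requires exactly two groups.
    """

    records: list[PeptideRecord]
    samples: list[str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        if set(self.groups) != set(self.samples):
            raise ValidationError("groups must cover exactly the declared samples")
        seen: set[str] = set()
        declared = set(self.samples)
        for rec in self.records:
            if rec.sequence in seen:
                raise ValidationError(f"duplicate peptide sequence {rec.sequence}")
            seen.add(rec.sequence)
            undeclared = set(rec.abundances) - declared
            if undeclared:
                raise ValidationError(
                    f"{rec.sequence}: abundances for undeclared samples {sorted(undeclared)}"
                )

    @property
    def group_labels(self) -> list[str]:
        """Group labels in first-appearance (sample) order."""
        out: list[str] = []
        for s in self.samples:
            g = self.groups[s]
            if g not in out:
                out.append(g)
        return out

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def sequences(self) -> set[str]:
        return {rec.sequence for rec in self.records}

    def group_sequences(self, group: str) -> set[str]:
        """Sequences detected (positive abundance) in >= 1 sample of a group."""
        cols = self.samples_of(group)
        return {
            rec.sequence
            for rec in self.records
            if any(rec.abundances.get(s, 0.0) > 0.0 for s in cols)
        }


@dataclass
class BioactiveEntry:
    """One reference bioactive peptide with its reported functions."""

    sequence: str
    functions: list[str]
    parent: str
    reference: str

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence, "BioactiveEntry")
        if not self.functions:
            raise ValidationError(f"{self.sequence}: empty function list")


@dataclass
class ParentProtein:
    """A parent protein, mature-chain convention, 1-based residue numbering."""

    id: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence, f"ParentProtein {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_peptide_table(path: str | Path, group_map: Mapping[str, str]) -> PeptideTable:
    """Read a peptide abundance TSV into a validated :class:`PeptideTable`.

    The header row must be ``sequence`` followed by one column per sample;
    empty cells encode missing (not-detected) values. ``group_map`` must
    assign a group label to every sample column. Duplicate sequence rows are
    merged by summing abundances per sample, with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.columns.empty or df.columns[0] != "sequence":
        raise FormatError(
            f"{path}: first column must be 'sequence', got {list(df.columns[:1])}"
        )
    samples = [str(c) for c in df.columns[1:]]
    if not samples:
        raise FormatError(f"{path}: no sample columns")
    missing = [s for s in samples if s not in group_map]
    if missing:
        raise FormatError(f"{path}: samples without group label: {missing}")

    merged: dict[str, dict[str, float]] = {}
    order: list[str] = []
    for row_idx, row in enumerate(df.itertuples(index=False), start=2):
        raw_seq = row[0]
        if not isinstance(raw_seq, str):
            raise ValidationError(f"{path} row {row_idx}: missing sequence")
        seq = validate_sequence(raw_seq, f"{path} row {row_idx}")
        if seq in merged:
            logger.warning("merging duplicate peptide row for %s (summing abundances)", seq)
        else:
            merged[seq] = {}
            order.append(seq)
        for sample, value in zip(samples, row[1:]):
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            value = float(value)
            if value < 0:
                raise ValidationError(
                    f"{path} row {row_idx}: negative abundance {value} in {sample}"
                )
            merged[seq][sample] = merged[seq].get(sample, 0.0) + value

    records = [PeptideRecord(seq, merged[seq]) for seq in order]
    return PeptideTable(records, samples, {s: group_map[s] for s in samples})


def write_peptide_table(table: PeptideTable, path: str | Path) -> None:
    """Write a peptide table as TSV; missing abundances become empty cells.

    Uses ``repr`` float formatting so a write/read round trip reproduces
    abundances exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sequence\t" + "\t".join(table.samples) + "\n")
        for rec in table.records:
            cells = [
                repr(rec.abundances[s]) if s in rec.abundances else ""
                for s in table.samples
            ]
            fh.write(rec.sequence + "\t" + "\t".join(cells) + "\n")


def read_fasta(path: str | Path) -> list[ParentProtein]:
    """Read parent proteins from FASTA, in file order.

    The header token up to the first whitespace is the id, the remainder the
    name. Sequences are uppercased and a terminal ``*`` stop is stripped.
    """
    proteins: list[ParentProtein] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if any(ch.isdigit() for ch in seq):
            raise ValidationError(f"{path}: digits in sequence of {record.id}")
        proteins.append(ParentProtein(record.id, record.description, seq))
    if not proteins:
        raise FormatError(f"{path}: no FASTA records")
    return proteins


def read_bioactive_db(path: str | Path) -> list[BioactiveEntry]:
    """Read a bioactive-peptide reference TSV (MBPDB-style flat file).

    Expected columns: ``sequence``, ``functions`` (semicolon-separated),
    ``parent``, ``reference``. One entry per row; function labels are split
    on ``;`` and whitespace-trimmed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sequence", "functions", "parent", "reference"]
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise FormatError(f"{path}: missing column(s) {absent}")
    entries: list[BioactiveEntry] = []
    for row_idx, row in enumerate(df.itertuples(index=False), start=2):
        functions_cell = getattr(row, "functions")
        if not isinstance(functions_cell, str) or not functions_cell.strip():
            raise ValidationError(f"{path} row {row_idx}: empty functions cell")
        functions = [f.strip() for f in functions_cell.split(";") if f.strip()]
        entries.append(
            BioactiveEntry(
                sequence=validate_sequence(getattr(row, "sequence"), f"{path} row {row_idx}"),
                functions=functions,
                parent=str(getattr(row, "parent")),
                reference=str(getattr(row, "reference")),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("lactopept").joinpath("data", name)))


def load_parent_proteins() -> list[ParentProtein]:
    """The six bundled bovine milk proteins (mature chains)."""
    return read_fasta(_data_path("parent_proteins.fasta"))


def load_bioactive_reference() -> list[BioactiveEntry]:
    """The bundled excerpt-style milk bioactive peptide reference database."""
    return read_bioactive_db(_data_path("bioactive_reference.tsv"))


def load_example_differential_peptides() -> pd.DataFrame:
    """Bundled example set of differentially abundant digesta peptides.

    Columns: ``sequence``, ``status`` (up/down), ``parent``. Useful for
    exercising the bioactive matcher without an abundance table.
    """
    df = pd.read_csv(_data_path("example_differential_peptides.tsv"), sep="\t", dtype=str)
    for seq in df["sequence"]:
        validate_sequence(seq, "example_differential_peptides")
    return df


def iter_sequences(records: Iterable[PeptideRecord]) -> Iterable[str]:
    for rec in records:
        yield rec.sequence
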