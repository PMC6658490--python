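"""FASTA and tab-separated table I/O with alphabet and schema validation.

All coordinates exposed by this package are 0-based, half-open.

Parsing rides on Biopython (:mod:`Bio.SeqIO`) and pandas; this module adds
the validation layer: alphabet checking with line-number diagnostics,
duplicate-id detection, and typed table schemas (counts >= 0, lengths > 0,
percents in [0, 100]).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_AMBIGUOUS = frozenset("X")
NUCLEOTIDE_ALPHABET = frozenset("ACGT")
NUCLEOTIDE_AMBIGUOUS = frozenset("N")

#: Default line width used by :func:`write_fasta`.
FASTA_WIDTH = 60


class FastaParseError(ValueError):
    """Malformed FASTA content; the message names the offending line."""


class DuplicateIdError(ValueError):
    """Two records in one file share an identifier."""


class TableSchemaError(ValueError):
    """A table is missing a required column or violates a column type."""


@dataclass(frozen=True)
class SequenceRecord:
    """A validated protein or nucleotide sequence.

    ``residues`` is upper-case over the declared alphabet; ``X`` (protein)
    and ``N`` (nucleotide) are permitted and flagged via :attr:`ambiguous`.
    """

    id: str
    residues: str
    alphabet: str = "protein"  # "protein" | "nucleotide"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.alphabet not in ("protein", "nucleotide"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        strict, ambig = _alphabet_sets(self.alphabet)
        bad = set(self.residues) - strict - ambig
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: illegal {self.alphabet} character(s) "
                f"{''.join(sorted(bad))!r}"
            )

    @property
    def ambiguous(self) -> bool:
        _, ambig = _alphabet_sets(self.alphabet)
        return any(c in ambig for c in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def _alphabet_sets(alphabet: str) -> tuple[frozenset, frozenset]:
    if alphabet == "protein":
        return PROTEIN_ALPHABET, PROTEIN_AMBIGUOUS
    return NUCLEOTIDE_ALPHABET, NUCLEOTIDE_AMBIGUOUS


def _line_of_offence(path: Path, bad_chars: set[str], record_id: str) -> int | None:
    """Locate the first line of ``record_id``'s sequence holding a bad char."""
    in_record = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(">"):
            in_record = line[1:].split()[0] == record_id if line[1:].split() else False
            continue
        if in_record and set(line.strip().upper()) & bad_chars:
            return lineno
    return None


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    The first whitespace in a header splits id from description; wrapped and
    unwrapped sequence lines are both accepted. Raises
    :class:`FastaParseError` (naming the line) on illegal characters and
    :class:`DuplicateIdError` on repeated ids. An empty file yields ``[]``.
    """
    path = Path(path)
    strict, ambig = _alphabet_sets(alphabet)
    allowed = strict | ambig
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty id")
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        bad = set(residues) - allowed
        if bad:
            lineno = _line_of_offence(path, bad, rec.id)
            where = f" at line {lineno}" if lineno is not None else ""
            raise FastaParseError(
                f"{path}{where}: record {rec.id!r} contains illegal "
                f"{alphabet} character(s) {''.join(sorted(bad))!r}"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, residues, alphabet, desc))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = FASTA_WIDTH
) -> Path:
    """Write records as FASTA wrapped at ``width`` columns; round-trips with
    :func:`read_fasta`."""
    path = Path(path)
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)
    return path


# ---------------------------------------------------------------------------
# Typed tables
# ---------------------------------------------------------------------------

#: Semantic column types understood by :func:`read_table`.
COLUMN_KINDS = ("text", "count", "length_bases", "length_mm", "percent", "number")


@dataclass
class TableSchema:
    """Declares column names and semantic kinds for a tab-separated table."""

    columns: Mapping[str, str]
    optional: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name, kind in self.columns.items():
            if kind not in COLUMN_KINDS:
                raise TableSchemaError(f"column {name!r}: unknown kind {kind!r}")


def _validate_column(name: str, kind: str, series: pd.Series) -> pd.Series:
    if kind == "text":
        return series.astype(str)
    try:
        values = pd.to_numeric(series)
    except (ValueError, TypeError) as exc:
        raise TableSchemaError(f"column {name!r}: non-numeric value ({exc})") from exc
    if kind == "count":
        if (values < 0).any():
            raise TableSchemaError(f"column {name!r}: negative count")
    elif kind in ("length_bases", "length_mm"):
        if (values <= 0).any():
            raise TableSchemaError(f"column {name!r}: non-positive length")
    elif kind == "percent":
        if ((values < 0) | (values > 100)).any():
            raise TableSchemaError(f"column {name!r}: percent outside [0, 100]")
    return values


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a tab-separated table with a header row and validate it against
    ``schema``. Missing optional columns are absent from the result; a
    missing required column raises :class:`TableSchemaError`."""
    df = pd.read_csv(path, sep="\t")
    required = [c for c in schema.columns if c not in schema.optional]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableSchemaError(f"{path}: missing required column(s) {missing}")
    out = {}
    for name, kind in schema.columns.items():
        if name not in df.columns:
            continue
        out[name] = _validate_column(name, kind, df[name])
    return pd.DataFrame(out)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table_string(text: str, schema: TableSchema) -> pd.DataFrame:
    """As :func:`read_table` but from an in-memory string (used in tests)."""
    df = pd.read_csv(io.StringIO(text), sep="\t")
    required = [c for c in schema.columns if c not in schema.optional]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableSchemaError(f"missing required column(s) {missing}")
    out = {}
    for name, kind in schema.columns.items():
        if name in df.columns:
            out[name] = _validate_column(name, kind, df[name])
    return pd.DataFrame(out)
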