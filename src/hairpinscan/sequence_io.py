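"""I/O for the hairpin screen: FASTA records, TANGO-style batch files,
per-residue propensity tables, and skip-lists of excluded accessions.

Coordinates are 1-based inclusive throughout the package (UniProt
convention); conversion to Python slices happens only at call sites.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "BatchParams",
    "PropensityProfile",
    "TableDialect",
    "FormatError",
    "AlignmentError",
    "read_fasta",
    "write_tango_batch",
    "read_propensity_table",
    "find_profile_path",
    "write_propensity_table",
    "read_skip_list",
]

#: The 20 standard one-letter codes plus tolerated extras that occur in
#: reviewed UniProt entries (X unknown, U selenocysteine, B Asx, Z Glx,
#: O pyrrolysine).
STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
TOLERATED_EXTRAS = set("XUBZO")
VALID_RESIDUES = STANDARD_RESIDUES | TOLERATED_EXTRAS


class FormatError(ValueError):
    """Malformed input file (FASTA, propensity table, batch line)."""


class AlignmentError(ValueError):
    """A propensity profile does not align 1:1 with its sequence."""


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry.

    ``id`` is the first whitespace-delimited header token, with UniProt
    ``sp|ACC|NAME`` / ``tr|ACC|NAME`` headers unwrapped to the accession.
    ``sequence`` is upper-case, with any terminal ``*`` stripped.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("empty record id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_RESIDUES:
                raise FormatError(
                    f"record {self.id!r}: illegal residue character {ch!r} "
                    f"at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BatchParams:
    """Physicochemical parameters written to each batch line.

    Defaults correspond to unmodified termini, pH 7, T = 298 K and an
    ionic strength of 0.1 M.
    """

    nterm_mod: str = "N"
    cterm_mod: str = "N"
    ph: float = 7.0
    temperature: float = 298.0
    ionic_strength: float = 0.1

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0 M")


@dataclass(frozen=True)
class PropensityProfile:
    """Per-residue nonnegative β-aggregation scores for one protein.

    Scores live on the predictor's percentage-like scale (typically
    0–100); position i (1-based) aligns to residue i of the matching
    :class:`ProteinRecord`.
    """

    protein_id: str
    scores: tuple = ()

    def __post_init__(self) -> None:
        scores = tuple(float(s) for s in self.scores)
        object.__setattr__(self, "scores", scores)
        for pos, s in enumerate(scores, start=1):
            if not math.isfinite(s):
                raise FormatError(
                    f"profile {self.protein_id!r}: non-finite score at position {pos}"
                )
            if s < 0:
                raise FormatError(
                    f"profile {self.protein_id!r}: negative score {s} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.scores)

    def check_alignment(self, record: ProteinRecord) -> None:
        if len(self.scores) != len(record.sequence):
            raise AlignmentError(
                f"profile for {record.id!r} has {len(self.scores)} scores but "
                f"the sequence has {len(record.sequence)} residues"
            )


@dataclass(frozen=True)
class TableDialect:
    """Layout of a delimited per-residue score table.

    ``delimiter`` is ``None`` for any-whitespace splitting or an explicit
    character (e.g. ``"\\t"``). Columns may be addressed by header name
    (when ``has_header``) or 0-based integer index.
    """

    delimiter: Union[str, None] = None
    has_header: bool = True
    residue_column: Union[str, int, None] = "aa"
    score_column: Union[str, int] = "Aggregation"
    comment_prefix: str = "#"

    def __post_init__(self) -> None:
        if self.residue_column is not None and self.residue_column == self.score_column:
            raise ValueError("residue_column and score_column must differ")


DEFAULT_DIALECT = TableDialect()


def _unwrap_uniprot(token: str) -> str:
    parts = token.split("|")
    if len(parts) == 3 and parts[0] in {"sp", "tr"} and parts[1]:
        return parts[1]
    return token


def read_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Parse a FASTA file into :class:`ProteinRecord` objects in file order.

    Sequences are upper-cased and a terminal ``*`` (stop marker emitted by
    some translators) is stripped. Duplicate ids raise :class:`FormatError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        raw_id = _unwrap_uniprot(entry.id)
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if raw_id in seen:
            raise FormatError(f"duplicate record id {raw_id!r} in {path}")
        seen.add(raw_id)
        records.append(ProteinRecord(id=raw_id, sequence=seq, description=entry.description))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def _fmt_number(x: float) -> str:
    """Render a numeric batch field without trailing zeros (7, 298, 0.1)."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def write_tango_batch(
    records: Sequence[ProteinRecord],
    out_dir: Union[str, Path],
    params: BatchParams = BatchParams(),
    max_lines: int = 1000,
    stem: str = "batch",
) -> list[Path]:
    """Write batch-input files, one record per line, chunked at ``max_lines``.

    Each line has the exact shape ``<id> <nterm> <cterm> <ph> <temp> <ionic>
    <sequence>`` with single-space separation, e.g.
    ``P12345 N N 7 298 0.1 MKVL`` under default parameters. The external
    predictor accepts at most one thousand lines per file, hence the
    chunking default.
    """
    if not records:
        raise ValueError("no records to write")
    if max_lines < 1:
        raise ValueError("max_lines must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = (
        f"{params.nterm_mod} {params.cterm_mod} {_fmt_number(params.ph)} "
        f"{_fmt_number(params.temperature)} {_fmt_number(params.ionic_strength)}"
    )
    n_files = math.ceil(len(records) / max_lines)
    width = max(3, len(str(n_files)))
    paths: list[Path] = []
    for i in range(n_files):
        chunk = records[i * max_lines : (i + 1) * max_lines]
        path = out_dir / f"{stem}_{i + 1:0{width}d}.txt"
        with open(path, "w") as fh:
            for rec in chunk:
                fh.write(f"{rec.id} {prefix} {rec.sequence}\n")
        paths.append(path)
    return paths


def _resolve_column(df: pd.DataFrame, col: Union[str, int]) -> pd.Series:
    if isinstance(col, int):
        if col >= df.shape[1]:
            raise FormatError(f"table has no column index {col}")
        return df.iloc[:, col]
    if col not in df.columns:
        raise FormatError(f"table has no column named {col!r}")
    return df[col]


def read_propensity_table(
    path: Union[str, Path],
    record: ProteinRecord,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> PropensityProfile:
    """Read one per-residue score table and align it against ``record``.

    Rows (after header/comment removal) must be in residue order. When the
    dialect declares a residue column, its letters are cross-checked
    against the sequence and the first mismatch is reported by position.
    """
    kwargs: dict = {
        "comment": dialect.comment_prefix or None,
        "header": 0 if dialect.has_header else None,
    }
    if dialect.delimiter is None:
        kwargs["sep"] = r"\s+"
    else:
        kwargs["sep"] = dialect.delimiter
    try:
        df = pd.read_csv(path, **kwargs)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty propensity table {path}") from None

    if len(df) != len(record.sequence):
        raise AlignmentError(
            f"{path}: {len(df)} score rows for {record.id!r} but the sequence "
            f"has {len(record.sequence)} residues"
        )
    if dialect.residue_column is not None:
        residues = _resolve_column(df, dialect.residue_column).astype(str).str.upper()
        for pos, (tab_res, seq_res) in enumerate(zip(residues, record.sequence), start=1):
            if tab_res != seq_res:
                raise AlignmentError(
                    f"{path}: residue mismatch for {record.id!r} at position {pos}: "
                    f"table has {tab_res!r}, sequence has {seq_res!r}"
                )
    raw = _resolve_column(df, dialect.score_column)
    scores = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
    if np.isnan(scores).any():
        pos = int(np.flatnonzero(np.isnan(scores))[0]) + 1
        raise FormatError(f"{path}: non-numeric score at position {pos}")
    return PropensityProfile(protein_id=record.id, scores=tuple(scores))


#: Filename extensions tried, in order, when locating ``<id>`` under a
#: profiles directory.
PROFILE_EXTENSIONS = (".txt", ".tsv", ".tab", ".dat", "")


def find_profile_path(profiles_dir: Union[str, Path], protein_id: str) -> Union[Path, None]:
    """Locate the per-sequence score table for ``protein_id`` by filename stem."""
    profiles_dir = Path(profiles_dir)
    for ext in PROFILE_EXTENSIONS:
        candidate = profiles_dir / f"{protein_id}{ext}"
        if candidate.is_file():
            return candidate
    return None


def write_propensity_table(
    profile: PropensityProfile,
    record: ProteinRecord,
    path: Union[str, Path],
    backend: str = "surrogate",
) -> None:
    """Write a per-residue score table in the default dialect.

    The ``backend`` provenance tag is embedded as a comment line so tables
    produced by the built-in surrogate can never be mistaken for output of
    the external predictor.
    """
    profile.check_alignment(record)
    with open(path, "w") as fh:
        fh.write(f"# backend={backend}\n")
        fh.write("aa Aggregation\n")
        for res, score in zip(record.sequence, profile.scores):
            fh.write(f"{res} {score:.6g}\n")


def read_skip_list(path: Union[str, Path]) -> set[str]:
    """Read accessions to exclude, one per line; blanks and ``#`` comments ignored."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.add(line.split()[0])
    return ids
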