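"""FASTA and PSI-BLAST PSSM input/output.

A position-specific scoring matrix (PSSM) is the L x 20 profile that
PSI-BLAST derives from the multiple alignment of a query against a sequence
database: entry (i, j) is the log-odds score for observing amino acid j at
position i, an integer where higher means the substitution is seen more often
in the alignment.  This module reads protein sequences (FASTA), parses the
ASCII PSSM files written by ``psiblast -out_ascii_pssm``, offers a plain TSV
serialization for fixtures, and optionally drives the external ``psiblast``
binary itself.
"""

from __future__ import annotations

import io
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "PSSM",
    "PSSMFormatError",
    "PSIBlastError",
    "PSIBlastNoProfileError",
    "read_fasta",
    "write_fasta",
    "parse_ascii_pssm",
    "write_ascii_pssm",
    "read_pssm_tsv",
    "write_pssm_tsv",
    "generate_pssm",
]

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Column order used by NCBI PSI-BLAST ASCII PSSM files.
PSIBLAST_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Sanity window for parsed PSI-BLAST log-odds scores.
SCORE_MIN, SCORE_MAX = -32, 32

PathLike = Union[str, os.PathLike]


class PSSMFormatError(ValueError):
    """Raised when an ASCII or TSV PSSM file violates the expected layout."""


class PSIBlastError(RuntimeError):
    """Raised when the external psiblast invocation fails."""


class PSIBlastNoProfileError(PSIBlastError):
    """psiblast ran but produced no PSSM (typically: no database hits)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20-letter amino-acid alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        seq = self.sequence.upper()
        allowed = set(AMINO_ACIDS)
        for pos, ch in enumerate(seq, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PSSM:
    """Per-protein L x 20 evolutionary score matrix.

    ``scores[i, j]`` is the substitution score of amino acid
    ``alphabet_order[j]`` at sequence position ``i`` (0-based row for
    1-based sequence position i+1).
    """

    protein_id: str
    scores: np.ndarray
    alphabet_order: str = PSIBLAST_ALPHABET

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(
                f"PSSM {self.protein_id!r}: scores must be L x 20, got {scores.shape}"
            )
        if scores.shape[0] < 1:
            raise ValueError(f"PSSM {self.protein_id!r}: empty score matrix")
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"PSSM {self.protein_id!r}: non-finite scores")
        if len(self.alphabet_order) != 20 or len(set(self.alphabet_order)) != 20:
            raise ValueError("alphabet_order must contain 20 distinct letters")
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])


def _as_text_handle(source: Union[PathLike, IO[str]]) -> tuple[IO[str], bool]:
    """Return (handle, should_close) for a path or open text stream."""
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    return open(source, "r"), True


def read_fasta(source: Union[PathLike, IO[str]]) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Multi-line (wrapped) sequences are concatenated; record order is
    preserved.  Empty input, duplicate ids and residues outside the standard
    20-letter alphabet are errors.
    """
    handle, close = _as_text_handle(source)
    try:
        records: list[ProteinRecord] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
        if not records:
            raise ValueError("FASTA input contains no records")
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[ProteinRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM dialect
# ---------------------------------------------------------------------------
# Layout accepted (modern psiblast -out_ascii_pssm):
#   - preamble line(s)
#   - a column-header line with 40 single-letter labels (20 log-odds +
#     20 weighted-percentage columns)
#   - one row per residue: position index, residue letter, 20 log-odds
#     integers, 20 percentage integers, then optional per-position
#     statistics (information content, relative weight)
#   - optional K/Lambda footer and blank lines, ignored
# Only the first 20 (log-odds) columns are kept.

def parse_ascii_pssm(source: Union[PathLike, IO[str]], protein_id: str) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM file into a :class:`PSSM`.

    Returns the 20 log-odds columns as an L x 20 matrix in file row order.
    The column alphabet is taken from the file's header line.
    """
    handle, close = _as_text_handle(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()

    header_idx = None
    alphabet: list[str] = []
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 40 and all(len(t) == 1 and t.isalpha() for t in tokens):
            header_idx = i
            alphabet = tokens[:20]
            break
    if header_idx is None:
        raise PSSMFormatError(
            f"{protein_id}: no PSSM column header line (40 one-letter labels) found"
        )
    if len(set(alphabet)) != 20:
        raise PSSMFormatError(f"{protein_id}: header alphabet is not 20 distinct letters")

    rows: list[list[int]] = []
    for line in lines[header_idx + 1 :]:
        tokens = line.split()
        if not tokens:
            continue
        # Data rows start with the 1-based position index.
        try:
            pos = int(tokens[0])
        except ValueError:
            break  # footer (K/Lambda statistics) reached
        row_no = len(rows) + 1
        if pos != row_no:
            raise PSSMFormatError(
                f"{protein_id}: row {row_no} has position index {pos}, expected {row_no}"
            )
        if len(tokens) < 2 or not tokens[1].isalpha():
            raise PSSMFormatError(f"{protein_id}: row {row_no} missing residue letter")
        numeric = tokens[2:]
        # Trailing per-position statistics are floats; the score block is
        # exactly 40 integers.
        ints: list[int] = []
        for tok in numeric:
            try:
                ints.append(int(tok))
            except ValueError:
                break
        if len(ints) != 40:
            raise PSSMFormatError(
                f"{protein_id}: row {row_no} has {len(ints)} numeric score fields, expected 40"
            )
        scores = ints[:20]
        bad = [v for v in scores if not (SCORE_MIN <= v <= SCORE_MAX)]
        if bad:
            raise PSSMFormatError(
                f"{protein_id}: row {row_no} has scores outside [{SCORE_MIN}, {SCORE_MAX}]: {bad}"
            )
        rows.append(scores)

    if not rows:
        raise PSSMFormatError(f"{protein_id}: PSSM data block is empty")
    return PSSM(protein_id=protein_id, scores=np.array(rows, dtype=float),
                alphabet_order="".join(alphabet))


def write_ascii_pssm(pssm: PSSM, path: PathLike, sequence: str | None = None) -> None:
    """Write a PSSM in the psiblast ASCII dialect accepted by the parser.

    The weighted-percentage block is filled with zeros; it is not used
    downstream.  ``sequence`` supplies the residue-letter column; when absent
    the most-scoring amino acid per row is written instead.
    """
    scores = np.rint(pssm.scores).astype(int)
    letters = list(pssm.alphabet_order)
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed, weighted "
                 "observed percentages rounded down, information per position, "
                 "and relative weight of gapless real matches to pseudocounts\n")
        cols = letters + letters
        fh.write("          " + "".join(f"{c:>4}" for c in cols) + "\n")
        for i, row in enumerate(scores):
            if sequence is not None:
                res = sequence[i]
            else:
                res = letters[int(np.argmax(row))]
            body = "".join(f"{v:>4d}" for v in row) + "".join(f"{0:>4d}" for _ in row)
            fh.write(f"{i + 1:>5d} {res} " + body + "  0.00 0.00\n")
        fh.write("\n                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1337     0.3177\n")


# ---------------------------------------------------------------------------
# TSV fixture serialization
# ---------------------------------------------------------------------------

def write_pssm_tsv(pssm: PSSM, path: PathLike) -> None:
    """Serialize a PSSM as plain TSV: an id/alphabet header then L rows."""
    with open(path, "w") as fh:
        fh.write(f"#pssm\t{pssm.protein_id}\t{pssm.alphabet_order}\n")
        for row in pssm.scores:
            fh.write("\t".join(format(v, "g") for v in row) + "\n")


def read_pssm_tsv(path: PathLike) -> PSSM:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 3 or header[0] != "#pssm":
            raise PSSMFormatError(f"{path}: not a PSSM TSV (bad header)")
        _, protein_id, alphabet = header
        rows = []
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 20:
                raise PSSMFormatError(
                    f"{path}: line {line_no} has {len(fields)} fields, expected 20"
                )
            rows.append([float(v) for v in fields])
    if not rows:
        raise PSSMFormatError(f"{path}: no score rows")
    return PSSM(protein_id=protein_id, scores=np.array(rows), alphabet_order=alphabet)


# ---------------------------------------------------------------------------
# External psiblast wrapper
# ---------------------------------------------------------------------------

def generate_pssm(
    record: ProteinRecord,
    database_path: PathLike,
    iterations: int = 3,
    evalue: float = 0.001,
    executable: str = "psiblast",
) -> PSSM:
    """Run PSI-BLAST on one query and parse the resulting ASCII PSSM.

    Profiles are built with three search iterations and an inclusion
    e-value of 0.001 by default.  The wrapper is optional at runtime: all
    downstream stages accept PSSMs from :func:`parse_ascii_pssm` or
    :func:`read_pssm_tsv` instead.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    if evalue <= 0:
        raise ValueError(f"evalue must be positive, got {evalue}")
    exe = shutil.which(executable)
    if exe is None:
        raise PSIBlastError(
            f"{executable!r} not found on PATH; install NCBI BLAST+ or pass "
            "pre-computed PSSM files instead"
        )
    with tempfile.TemporaryDirectory(prefix="ppirvm_psiblast_") as tmp:
        query = Path(tmp) / "query.fasta"
        out_pssm = Path(tmp) / "query.pssm"
        write_fasta([record], query)
        cmd = [
            exe,
            "-query", str(query),
            "-db", str(database_path),
            "-num_iterations", str(iterations),
            "-evalue", str(evalue),
            "-out_ascii_pssm", str(out_pssm),
            "-out", os.devnull,
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise PSIBlastError(
                f"psiblast exited with status {proc.returncode} for "
                f"{record.id!r}: {proc.stderr.strip()}"
            )
        if not out_pssm.exists() or out_pssm.stat().st_size == 0:
            raise PSIBlastNoProfileError(
                f"psiblast produced no PSSM for {record.id!r} "
                "(query may have no database hits)"
            )
        return parse_ascii_pssm(out_pssm, record.id)
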