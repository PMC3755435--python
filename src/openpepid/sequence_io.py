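"""FASTA protein database input/output and synthetic database generation.

Protein records carry a positional integer ID (0-based ordinal within the
database file).  That ordinal — not anything parsed from the header — is
what peptide index entries refer back to, so it must be stable across
re-reads of the same file.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import CANONICAL_RESIDUES


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry.

    Attributes
    ----------
    protein_id : 0-based ordinal of the record within its database file.
    accession : first whitespace-delimited token of the header line.
    description : remainder of the header line (may be empty).
    sequence : upper-case residue string, stop codons ('*') stripped.
    """

    protein_id: int
    accession: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize_sequence(raw: str) -> str:
    return "".join(raw.split()).upper().replace("*", "")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA protein database into ordered :class:`ProteinRecord` s.

    Sequence lines are concatenated with internal whitespace removed,
    upper-cased, and '*' characters stripped.  ``protein_id`` is assigned
    positionally.  An empty file yields an empty list.

    Raises
    ------
    FastaParseError
        If sequence data precedes any header, or a record has an empty
        header or empty sequence.  The message includes the line number.
    """
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = _normalize_sequence("".join(chunks))
        if not seq:
            raise FastaParseError(
                f"record with empty sequence at line {header_line}"
            )
        fields = header.split(None, 1)
        if not fields:
            raise FastaParseError(f"empty FASTA header at line {header_line}")
        accession = fields[0]
        description = fields[1].strip() if len(fields) > 1 else ""
        records.append(
            ProteinRecord(len(records), accession, description, seq)
        )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"sequence data before any header at line {lineno}"
                    )
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, sequences wrapped at `width` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.accession
            if rec.description:
                header = f"{header} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def database_fingerprint(records: Sequence[ProteinRecord]) -> str:
    """Content hash of a database: order-sensitive SHA-256 over sequences.

    Used to detect a stale index whose source database has changed.
    """
    h = hashlib.sha256()
    for rec in records:
        h.update(rec.accession.encode())
        h.update(b"\x00")
        h.update(rec.sequence.encode())
        h.update(b"\x01")
    return h.hexdigest()


def generate_synthetic_fasta(
    n_proteins: int,
    min_length: int = 50,
    max_length: int = 400,
    seed: int = 0,
    alphabet: str = CANONICAL_RESIDUES,
    path: str | Path | None = None,
) -> list[ProteinRecord]:
    """Generate a random protein database for testing and benchmarking.

    Residues are drawn i.i.d. uniformly from `alphabet`; lengths uniformly
    from [min_length, max_length].  Deterministic for a fixed seed.  If
    `path` is given the database is also written as FASTA; the written file
    round-trips through :func:`read_fasta` to identical records.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not (3 <= min_length <= max_length):
        raise ValueError("need 3 <= min_length <= max_length")
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(min_length, max_length + 1))
        seq = "".join(rng.choice(letters, size=length))
        records.append(ProteinRecord(i, f"syn|{seed}|{i}", "synthetic protein", seq))
    if path is not None:
        write_fasta(records, path)
    return records
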