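"""The mass-sorted, fixed-width peptide index.

Every peptide produced by in-silico digestion is stored as an equal-width
term of three integers — protein ID, start position, residue length —
keyed by its monoisotopic neutral mass.  Terms are sorted ascending by
mass (ties by protein ID, start, length), so a precursor-mass tolerance
window maps to one contiguous slice of the table.  A bucket table at
1-Dalton resolution gives the first array position with mass >= b for
every integer Dalton b in the index's mass window, so locating the start
of a query window costs a table lookup plus a bounded bisection inside a
single bucket rather than a full binary search.

On-disk layout (little-endian, versioned)
-----------------------------------------
=========  ======================================================
offset     content
=========  ======================================================
0          magic ``b"OPEPIDX\\0"`` (8 bytes)
8          format version, u32
12         header_len, u32 — file offset where the arrays begin
16         record count N, u64
24         bucket count B, u64
32         bucket base (integer Dalton of bucket 0), i64
40         JSON blob (digestion params + database fingerprint)
header_len mass array, N x f64
+8N        entry array, N x (u32 protein_id, u32 start, u32 length)
+20N       bucket offsets, B x u64
=========  ======================================================

Each entry record is a constant 12 bytes (20 bytes with its mass key), so
the k-th entry lives at ``header_len + 8N + 12k`` — pure offset
arithmetic, no parsing of variable-width data.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .digestion import (
    DigestionParams, EnzymeRule, PeptideEntry, enumerate_peptides,
)
from .sequence_io import ProteinRecord, database_fingerprint

MAGIC = b"OPEPIDX\x00"
FORMAT_VERSION = 1

__all__ = [
    "PeptideIndex", "IndexFormatError", "IndexCorruptionError",
    "build_index", "save_index", "load_index",
]


class IndexFormatError(ValueError):
    """Magic or version mismatch when loading an index file."""


class IndexCorruptionError(ValueError):
    """Index file is truncated or internally inconsistent."""


@dataclass(frozen=True)
class PeptideIndex:
    """Parallel mass/entry arrays plus the integer-Dalton bucket table.

    Attributes
    ----------
    masses : (N,) float64, non-decreasing.
    entries : (N, 3) uint32 — columns protein_id, start, length.
    bucket_offsets : (B,) uint64; ``bucket_offsets[b - bucket_base]`` is
        the first position with mass >= b.
    bucket_base : integer Dalton of the first bucket (floor of min_mass).
    params : digestion parameters the index was built with.
    db_fingerprint : content hash of the source database.
    """

    masses: np.ndarray
    entries: np.ndarray
    bucket_offsets: np.ndarray
    bucket_base: int
    params: DigestionParams
    db_fingerprint: str

    def __len__(self) -> int:
        return len(self.masses)

    # -- queries ---------------------------------------------------------

    def _first_geq(self, value: float) -> int:
        """First position with mass >= value, via the bucket table."""
        n = len(self.masses)
        if n == 0:
            return 0
        if not np.isfinite(value):
            return 0 if value < 0 else n
        b = int(np.floor(value)) - self.bucket_base
        if b < 0:
            # below the index's mass window: refine inside bucket 0
            lo_bound, hi_bound = 0, int(self.bucket_offsets[0])
        elif b >= len(self.bucket_offsets):
            return n
        else:
            lo_bound = int(self.bucket_offsets[b])
            hi_bound = (int(self.bucket_offsets[b + 1])
                        if b + 1 < len(self.bucket_offsets) else n)
        return int(np.searchsorted(self.masses[lo_bound:hi_bound], value,
                                   side="left")) + lo_bound

    def query_mass_range(self, lo: float, hi: float) -> tuple[int, int]:
        """Contiguous slice (first position, count) with lo <= mass <= hi.

        Both window ends are inclusive.  Raises ValueError if lo > hi.
        """
        if lo > hi:
            raise ValueError(f"empty mass window: lo={lo} > hi={hi}")
        first = self._first_geq(lo)
        # end = first position with mass > hi
        end = self._first_geq(np.nextafter(hi, np.inf))
        if end < first:
            end = first
        return first, end - first

    def mass_histogram(self, bin_width: float) -> dict[float, int]:
        """Histogram of index masses into bins [k*w, (k+1)*w).

        Returns a mapping from bin lower edge to count; counts sum to the
        record count.
        """
        if bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if len(self.masses) == 0:
            return {}
        bins = np.floor(self.masses / bin_width).astype(np.int64)
        uniq, counts = np.unique(bins, return_counts=True)
        return {float(k) * bin_width: int(c) for k, c in zip(uniq, counts)}

    def fraction_below(self, threshold: float) -> float:
        """Fraction of indexed peptides with mass <= threshold.

        Raises ValueError on an empty index (the statistic is undefined).
        """
        if len(self.masses) == 0:
            raise ValueError("fraction_below is undefined for an empty index")
        _, count = self.query_mass_range(-np.inf, threshold)
        return count / len(self.masses)

    # -- block splitting (used by the distributed driver) ---------------

    def slice_block(self, start: int, stop: int) -> "PeptideIndex":
        """A sub-index over entry positions [start, stop); order preserved."""
        masses = self.masses[start:stop]
        entries = self.entries[start:stop]
        offsets, base = _build_buckets(masses, self.params)
        return replace(self, masses=masses, entries=entries,
                       bucket_offsets=offsets, bucket_base=base)

    def entry_at(self, pos: int) -> PeptideEntry:
        pid, start, length = (int(v) for v in self.entries[pos])
        return PeptideEntry(pid, start, length)


def _build_buckets(masses: np.ndarray,
                   params: DigestionParams) -> tuple[np.ndarray, int]:
    base = int(np.floor(params.min_mass))
    top = int(np.ceil(params.max_mass))
    grid = np.arange(base, top + 1, dtype=np.float64)
    offsets = np.searchsorted(masses, grid, side="left").astype(np.uint64)
    return offsets, base


def build_index(proteins: Sequence[ProteinRecord],
                params: DigestionParams | None = None) -> PeptideIndex:
    """Digest every protein and assemble the globally mass-sorted index.

    The result is exactly the union of the per-protein digestion streams,
    sorted by (mass, protein_id, start, length); deterministic for fixed
    inputs.  An empty protein collection yields an empty index.
    """
    if params is None:
        params = DigestionParams()
    mass_parts: list[np.ndarray] = []
    entry_parts: list[np.ndarray] = []
    for protein in proteins:
        buf = [(m, e.protein_id, e.start, e.length)
               for e, m in enumerate_peptides(protein, params)]
        if not buf:
            continue
        arr = np.array(buf, dtype=np.float64)
        mass_parts.append(arr[:, 0])
        entry_parts.append(arr[:, 1:].astype(np.uint32))
    if mass_parts:
        masses = np.concatenate(mass_parts)
        entries = np.vstack(entry_parts)
    else:
        masses = np.empty(0, dtype=np.float64)
        entries = np.empty((0, 3), dtype=np.uint32)
    order = np.lexsort(
        (entries[:, 2], entries[:, 1], entries[:, 0], masses)
    )
    masses = np.ascontiguousarray(masses[order])
    entries = np.ascontiguousarray(entries[order])
    offsets, base = _build_buckets(masses, params)
    return PeptideIndex(masses, entries, offsets, base, params,
                        database_fingerprint(proteins))


# -- serialization -------------------------------------------------------

_FIXED_HEADER = struct.Struct("<8sIIQQq")


def _params_to_json(params: DigestionParams, fingerprint: str) -> bytes:
    rule = params.enzyme_rule
    doc = {
        "mode": params.mode,
        "enzyme_rule": {
            "cleave_after": sorted(rule.cleave_after),
            "suppress_next": sorted(rule.suppress_next),
            "terminus": rule.terminus,
        },
        "min_len": params.min_len,
        "max_len": params.max_len,
        "min_mass": params.min_mass,
        "max_mass": params.max_mass,
        "max_missed_cleavages": params.max_missed_cleavages,
        "db_fingerprint": fingerprint,
    }
    return json.dumps(doc, sort_keys=True).encode()


def _params_from_json(blob: bytes) -> tuple[DigestionParams, str]:
    doc = json.loads(blob.decode())
    rule = EnzymeRule(
        frozenset(doc["enzyme_rule"]["cleave_after"]),
        frozenset(doc["enzyme_rule"]["suppress_next"]),
        doc["enzyme_rule"]["terminus"],
    )
    params = DigestionParams(
        mode=doc["mode"], enzyme_rule=rule,
        min_len=doc["min_len"], max_len=doc["max_len"],
        min_mass=doc["min_mass"], max_mass=doc["max_mass"],
        max_missed_cleavages=doc["max_missed_cleavages"],
    )
    return params, doc["db_fingerprint"]


def save_index(index: PeptideIndex, path: str | Path) -> None:
    """Write the index in the fixed-width binary layout described above."""
    blob = _params_to_json(index.params, index.db_fingerprint)
    header_len = _FIXED_HEADER.size + len(blob)
    with open(path, "wb") as fh:
        fh.write(_FIXED_HEADER.pack(
            MAGIC, FORMAT_VERSION, header_len, len(index.masses),
            len(index.bucket_offsets), index.bucket_base,
        ))
        fh.write(blob)
        fh.write(index.masses.astype("<f8", copy=False).tobytes())
        fh.write(index.entries.astype("<u4", copy=False).tobytes())
        fh.write(index.bucket_offsets.astype("<u8", copy=False).tobytes())


def load_index(path: str | Path) -> PeptideIndex:
    """Read an index written by :func:`save_index`; bit-exact round trip.

    Raises
    ------
    IndexFormatError
        Wrong magic bytes or unsupported format version.
    IndexCorruptionError
        Truncated file or size inconsistent with the declared counts.
    """
    data = Path(path).read_bytes()
    if len(data) < _FIXED_HEADER.size:
        raise IndexCorruptionError("file shorter than the fixed header")
    magic, version, header_len, n, n_buckets, base = _FIXED_HEADER.unpack_from(data)
    if magic != MAGIC:
        raise IndexFormatError("not a peptide index file (bad magic)")
    if version != FORMAT_VERSION:
        raise IndexFormatError(f"unsupported index format version {version}")
    expected = header_len + 8 * n + 12 * n + 8 * n_buckets
    if len(data) != expected:
        raise IndexCorruptionError(
            f"file size {len(data)} != expected {expected} for {n} records"
        )
    params, fingerprint = _params_from_json(data[_FIXED_HEADER.size:header_len])
    off = header_len
    masses = np.frombuffer(data, dtype="<f8", count=n, offset=off).copy()
    off += 8 * n
    entries = np.frombuffer(data, dtype="<u4", count=3 * n,
                            offset=off).reshape(n, 3).copy()
    off += 12 * n
    offsets = np.frombuffer(data, dtype="<u8", count=n_buckets,
                            offset=off).copy()
    return PeptideIndex(masses, entries, offsets, base, params, fingerprint)
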