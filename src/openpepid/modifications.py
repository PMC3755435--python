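"""Modification table and the delta-mass inverted index.

Open search explains an unassigned precursor mass difference by looking it
up in a table of known modifications sorted by monoisotopic delta mass —
the same sorted-array-plus-bucket-table idea as the peptide index, applied
to a few dozen records instead of millions.  A TSV dialect (columns: id,
name, delta_mass, sites) stands in for the full community catalogue; a
curated default table of common modifications ships with the package.

Site specifiers are single residue letters or one of ``peptide-N``,
``peptide-C``, ``protein-N``, ``protein-C``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .tolerance import Tolerance

TERMINUS_SPECIFIERS = frozenset(
    {"peptide-N", "peptide-C", "protein-N", "protein-C"}
)

__all__ = [
    "ModificationRecord", "ModificationIndex", "ModTableError",
    "load_modifications", "default_modifications", "build_mod_index",
    "default_mod_index", "query_mod_by_delta",
]


class ModTableError(ValueError):
    """Malformed modification TSV; message names the offending line."""


@dataclass(frozen=True)
class ModificationRecord:
    """One modification: identifier, human name, signed delta mass, sites."""

    mod_id: str
    name: str
    delta_mass: float
    sites: frozenset[str]

    def residue_sites(self) -> frozenset[str]:
        return frozenset(s for s in self.sites if s not in TERMINUS_SPECIFIERS)

    def terminal_sites(self) -> frozenset[str]:
        return frozenset(s for s in self.sites if s in TERMINUS_SPECIFIERS)


def load_modifications(path: str | Path) -> list[ModificationRecord]:
    """Parse a modification TSV (header: id, name, delta_mass, sites).

    Raises :class:`ModTableError` on a missing column, an unparseable
    delta mass, an empty site list, or a duplicate id.
    """
    records: list[ModificationRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "name", "delta_mass", "sites"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ModTableError(
                f"modification table must have columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            mod_id = (row["id"] or "").strip()
            if not mod_id:
                raise ModTableError(f"missing id at line {lineno}")
            if mod_id in seen:
                raise ModTableError(f"duplicate mod id {mod_id!r} at line {lineno}")
            seen.add(mod_id)
            try:
                delta = float(row["delta_mass"])
            except (TypeError, ValueError):
                raise ModTableError(
                    f"unparseable delta_mass at line {lineno}: "
                    f"{row['delta_mass']!r}"
                ) from None
            if not np.isfinite(delta):
                raise ModTableError(f"non-finite delta_mass at line {lineno}")
            sites = frozenset(
                s.strip() for s in (row["sites"] or "").split(",") if s.strip()
            )
            if not sites:
                raise ModTableError(f"empty site list at line {lineno}")
            for s in sites:
                if len(s) != 1 and s not in TERMINUS_SPECIFIERS:
                    raise ModTableError(
                        f"unknown site specifier {s!r} at line {lineno}"
                    )
            records.append(ModificationRecord(mod_id, row["name"], delta, sites))
    return records


def default_modifications() -> list[ModificationRecord]:
    """The curated table of common modifications shipped with the package."""
    ref = resources.files("openpepid").joinpath("data/modifications.tsv")
    with resources.as_file(ref) as path:
        return load_modifications(path)


class ModificationIndex:
    """Modification records sorted ascending by delta mass.

    A 1-Dalton bucket table over the signed delta range locates the first
    candidate for a query in constant time; ties in delta are ordered by
    mod id so results are fully deterministic.
    """

    def __init__(self, records: Iterable[ModificationRecord]):
        self.records: list[ModificationRecord] = sorted(
            records, key=lambda r: (r.delta_mass, r.mod_id)
        )
        self.deltas = np.array([r.delta_mass for r in self.records])
        if len(self.deltas):
            self._base = int(np.floor(self.deltas.min()))
            grid = np.arange(self._base,
                             int(np.ceil(self.deltas.max())) + 2)
            self._offsets = np.searchsorted(self.deltas, grid, side="left")
        else:
            self._base = 0
            self._offsets = np.zeros(1, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.records)

    def _first_geq(self, value: float) -> int:
        n = len(self.deltas)
        if n == 0:
            return 0
        b = int(np.floor(value)) - self._base
        if b < 0:
            return 0
        if b >= len(self._offsets) - 1:
            return n if value > self.deltas[-1] else \
                int(np.searchsorted(self.deltas, value, side="left"))
        lo, hi = int(self._offsets[b]), int(self._offsets[b + 1])
        return lo + int(np.searchsorted(self.deltas[lo:hi], value, side="left"))

    def query(self, delta: float,
              tol: Tolerance | float) -> list[ModificationRecord]:
        """All records with |delta_mass - delta| within tolerance.

        Ranked by distance to the query delta ascending, ties by mod id.
        A ppm tolerance is evaluated at |delta|.
        """
        if not isinstance(tol, Tolerance):
            tol = Tolerance(float(tol), "da")
        hw = tol.half_width(abs(delta))
        first = self._first_geq(delta - hw)
        out = []
        for i in range(first, len(self.records)):
            if self.deltas[i] > delta + hw:
                break
            out.append(self.records[i])
        out.sort(key=lambda r: (abs(r.delta_mass - delta), r.mod_id))
        return out


def build_mod_index(records: Iterable[ModificationRecord]) -> ModificationIndex:
    return ModificationIndex(records)


def default_mod_index() -> ModificationIndex:
    return ModificationIndex(default_modifications())


def query_mod_by_delta(mindex: ModificationIndex, delta: float,
                       tol: Tolerance | float) -> list[ModificationRecord]:
    """Functional alias for :meth:`ModificationIndex.query`."""
    return mindex.query(delta, tol)


def compatible_sites(mod: ModificationRecord, peptide: str,
                     protein_nterm: bool = False,
                     protein_cterm: bool = False) -> list[int]:
    """0-based positions in `peptide` where `mod` may sit.

    Terminal specifiers map to position 0 (N) or len-1 (C); the
    protein-terminal ones apply only when the peptide actually sits at
    the corresponding protein terminus.
    """
    n = len(peptide)
    sites: set[int] = set()
    residues = mod.residue_sites()
    for i, aa in enumerate(peptide):
        if aa in residues:
            sites.add(i)
    terms = mod.terminal_sites()
    if "peptide-N" in terms:
        sites.add(0)
    if "peptide-C" in terms:
        sites.add(n - 1)
    if "protein-N" in terms and protein_nterm:
        sites.add(0)
    if "protein-C" in terms and protein_cterm:
        sites.add(n - 1)
    return sorted(sites)
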