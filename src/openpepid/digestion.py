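"""In-silico digestion: peptide masses and the three digestion semantics.

Digestion modes
---------------
specific
    Both peptide termini lie at enzymatic cleavage boundaries (or protein
    termini); up to ``max_missed_cleavages`` internal sites may be left
    uncut.
semispecific
    Exactly one terminus is required to lie at an enzymatic boundary; the
    other may fall at any residue.
nonspecific
    Neither terminus is constrained: every substring within the length and
    mass windows is a peptide.  This is the mode the mass-sorted index is
    built for; it subsumes the other two.

Coordinates are 0-based with half-open substrings throughout:
``sequence[start : start + length]`` is the peptide.

Masses are monoisotopic neutral peptide masses (sum of residue masses plus
one water).  Peptides containing residues with no defined monoisotopic
mass (B, J, O, X, Z) are skipped, never assigned a guessed mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .constants import RESIDUE_MASSES, WATER_MASS
from .sequence_io import ProteinRecord

__all__ = [
    "EnzymeRule", "TRYPSIN", "DigestionParams", "PeptideEntry", "DigestStats",
    "peptide_mass", "residue_prefix_masses", "count_nonspecific",
    "enumerate_nonspecific", "enumerate_specific", "enumerate_semispecific",
    "enumerate_peptides",
]


class UndefinedResidueError(ValueError):
    """A residue without a defined monoisotopic mass was encountered."""


@dataclass(frozen=True)
class EnzymeRule:
    """Cleavage specificity of a protease.

    For ``terminus == "C"`` the bond after a residue in `cleave_after` is
    cut unless the next residue is in `suppress_next` (trypsin: after K/R
    unless P follows).  For ``terminus == "N"`` the bond before a residue
    in `cleave_after` is cut unless the preceding residue is in
    `suppress_next`.
    """

    cleave_after: frozenset[str]
    suppress_next: frozenset[str] = frozenset()
    terminus: str = "C"

    def boundaries(self, sequence: str) -> list[int]:
        """All boundary indices: 0, len, and internal cleavage positions.

        A boundary index b means the bond between residues b-1 and b; a
        peptide [i, j) is fully enzymatic iff both i and j are boundaries.
        """
        n = len(sequence)
        sites = {0, n}
        if self.terminus == "C":
            for p in range(n - 1):
                if sequence[p] in self.cleave_after and \
                        sequence[p + 1] not in self.suppress_next:
                    sites.add(p + 1)
        else:
            for p in range(1, n):
                if sequence[p] in self.cleave_after and \
                        sequence[p - 1] not in self.suppress_next:
                    sites.add(p)
        return sorted(sites)


TRYPSIN = EnzymeRule(frozenset("KR"), frozenset("P"), "C")


@dataclass(frozen=True)
class DigestionParams:
    """Digestion mode plus the peptide mass/length windows.

    Defaults: length 3-60 residues, neutral mass 300-8000 Da (both windows
    inclusive), trypsin rule, 2 missed cleavages for the enzymatic modes.
    """

    mode: str = "nonspecific"
    enzyme_rule: EnzymeRule = TRYPSIN
    min_len: int = 3
    max_len: int = 60
    min_mass: float = 300.0
    max_mass: float = 8000.0
    max_missed_cleavages: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("specific", "semispecific", "nonspecific"):
            raise ValueError(f"unknown digestion mode: {self.mode!r}")
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if not (0 < self.min_mass <= self.max_mass):
            raise ValueError("need 0 < min_mass <= max_mass")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")


@dataclass(frozen=True)
class PeptideEntry:
    """The fixed-width index term: (protein ID, start, length).

    ``start`` is the 0-based offset of the first residue;
    ``sequence[start : start + length]`` is the peptide.
    """

    protein_id: int
    start: int
    length: int

    def extract(self, protein: ProteinRecord) -> str:
        return protein.sequence[self.start:self.start + self.length]


@dataclass
class DigestStats:
    """Optional counters surfaced for logging during enumeration."""

    yielded: int = 0
    skipped_undefined: int = 0
    skipped_window: int = 0


def peptide_mass(sequence: str) -> float:
    """Monoisotopic neutral mass of a peptide: residue masses + one water.

    Raises
    ------
    UndefinedResidueError
        For an empty sequence or a residue outside the mass table.
    """
    if not sequence:
        raise UndefinedResidueError("empty peptide sequence")
    total = WATER_MASS
    for aa in sequence:
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise UndefinedResidueError(
                f"residue {aa!r} has no defined monoisotopic mass"
            ) from None
    return total


def residue_prefix_masses(sequence: str) -> np.ndarray:
    """Prefix sums of residue masses; undefined residues poison as NaN.

    ``prefix[j] - prefix[i] + WATER_MASS`` is the mass of sequence[i:j];
    NaN whenever the substring spans an undefined residue.
    """
    masses = np.array(
        [RESIDUE_MASSES.get(aa, np.nan) for aa in sequence], dtype=np.float64
    )
    prefix = np.empty(len(sequence) + 1, dtype=np.float64)
    prefix[0] = 0.0
    np.cumsum(masses, out=prefix[1:])
    return prefix


def count_nonspecific(length: int, min_len: int = 3, max_len: int = 60) -> int:
    """Substring count for a protein of `length` residues, mass filter off.

    Closed form: sum over k in [min_len, min(max_len, length)] of
    (length - k + 1).
    """
    hi = min(max_len, length)
    if hi < min_len:
        return 0
    n_terms = hi - min_len + 1
    # arithmetic series of (length - k + 1) for k = min_len .. hi
    first = length - min_len + 1
    last = length - hi + 1
    return n_terms * (first + last) // 2


def enumerate_nonspecific(
    protein: ProteinRecord,
    params: DigestionParams,
    stats: DigestStats | None = None,
) -> Iterator[tuple[PeptideEntry, float]]:
    """Yield every substring within the length and mass windows, once each.

    Order is deterministic: ascending start, then ascending length.
    Substrings spanning undefined-mass residues are skipped.
    """
    seq = protein.sequence
    n = len(seq)
    prefix = residue_prefix_masses(seq)
    min_len, max_len = params.min_len, params.max_len
    lo, hi = params.min_mass, params.max_mass
    pid = protein.protein_id
    for start in range(n - min_len + 1):
        stop = min(n, start + max_len)
        masses = prefix[start + min_len:stop + 1] - prefix[start] + WATER_MASS
        for k, m in enumerate(masses):
            if np.isnan(m):
                if stats:
                    stats.skipped_undefined += 1
                continue
            if lo <= m <= hi:
                if stats:
                    stats.yielded += 1
                yield PeptideEntry(pid, start, min_len + k), float(m)
            elif stats:
                stats.skipped_window += 1


def _emit_filtered(
    protein: ProteinRecord,
    spans: list[tuple[int, int]],
    params: DigestionParams,
    stats: DigestStats | None,
) -> Iterator[tuple[PeptideEntry, float]]:
    """Filter (start, length) spans by the windows and yield with masses."""
    prefix = residue_prefix_masses(protein.sequence)
    for start, length in spans:
        if not (params.min_len <= length <= params.max_len):
            if stats:
                stats.skipped_window += 1
            continue
        m = prefix[start + length] - prefix[start] + WATER_MASS
        if np.isnan(m):
            if stats:
                stats.skipped_undefined += 1
            continue
        if params.min_mass <= m <= params.max_mass:
            if stats:
                stats.yielded += 1
            yield PeptideEntry(protein.protein_id, start, length), float(m)
        elif stats:
            stats.skipped_window += 1


def enumerate_specific(
    protein: ProteinRecord,
    params: DigestionParams,
    stats: DigestStats | None = None,
) -> Iterator[tuple[PeptideEntry, float]]:
    """Fully enzymatic peptides with up to `max_missed_cleavages` missed sites."""
    bounds = params.enzyme_rule.boundaries(protein.sequence)
    spans = []
    for i, b_start in enumerate(bounds[:-1]):
        upper = min(len(bounds), i + params.max_missed_cleavages + 2)
        for b_end in bounds[i + 1:upper]:
            spans.append((b_start, b_end - b_start))
    spans.sort()
    yield from _emit_filtered(protein, spans, params, stats)


def enumerate_semispecific(
    protein: ProteinRecord,
    params: DigestionParams,
    stats: DigestStats | None = None,
) -> Iterator[tuple[PeptideEntry, float]]:
    """Peptides with at least one enzymatic terminus, each yielded once.

    The missed-cleavage limit bounds the number of enzymatic sites left
    uncut strictly inside the peptide.
    """
    seq = protein.sequence
    n = len(seq)
    bounds = params.enzyme_rule.boundaries(seq)
    bset = np.zeros(n + 1, dtype=bool)
    bset[bounds] = True
    cuts = np.cumsum(bset)  # cuts[b] = number of boundaries <= b
    max_missed = params.max_missed_cleavages
    spans: set[tuple[int, int]] = set()
    for start in range(n):
        for end in range(start + params.min_len,
                         min(n, start + params.max_len) + 1):
            if not (bset[start] or bset[end]):
                continue
            # boundaries strictly inside (start, end) are left uncut
            internal = int(cuts[end - 1] - cuts[start])
            if internal > max_missed:
                continue
            spans.add((start, end - start))
    yield from _emit_filtered(protein, sorted(spans), params, stats)


_MODES = {
    "nonspecific": enumerate_nonspecific,
    "specific": enumerate_specific,
    "semispecific": enumerate_semispecific,
}


def enumerate_peptides(
    protein: ProteinRecord,
    params: DigestionParams,
    stats: DigestStats | None = None,
) -> Iterator[tuple[PeptideEntry, float]]:
    """Dispatch to the enumerator selected by ``params.mode``."""
    yield from _MODES[params.mode](protein, params, stats)
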