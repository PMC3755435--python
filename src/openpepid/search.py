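"""Closed and open (mass-delta) identification against the peptide index.

Closed search retrieves every indexed peptide whose mass falls in the
precursor tolerance window and scores it against the spectrum.

Open search runs in two stages.  Stage one widens the retrieval window to
an open delta range (peptides whose mass differs from the precursor by an
amount attributable to a modification) and pre-scores each candidate with
its *unmodified* fragment ladder: fragments on the far side of a
modification site are mass-shifted and will not match, so the unshifted
series anchors one terminus of the peptide and candidates with no
anchoring evidence are discarded, leaving a small survivor set.  Stage
two takes each survivor's residual precursor mass difference, looks it up
in the modification index, tries every sequence-compatible site, rescores
with the shifted ladder, and keeps the best interpretation.  Unmodified
interpretations compete with modified ones on score.

Scoring is a transparent shared-peak count: greedy one-to-one matching of
theoretical fragments to observed peaks within the fragment tolerance
(closest pairs first, each peak used at most once); the score is the
match count plus the matched-intensity fraction as a fractional
tie-breaker.  It is deliberately simple plumbing, not a calibrated
discriminant — no false-discovery-rate machinery sits on top of it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import PROTON_MASS, RESIDUE_MASSES, WATER_MASS
from .digestion import PeptideEntry, peptide_mass, residue_prefix_masses
from .modifications import (
    ModificationIndex, ModificationRecord, compatible_sites,
)
from .peptide_index import PeptideIndex
from .sequence_io import ProteinRecord
from .spectra import Spectrum, neutral_mass, theoretical_fragments
from .tolerance import Tolerance

__all__ = [
    "SearchParams", "PeptideSpectrumMatch", "score_psm",
    "search_spectrum_closed", "search_spectrum_open", "search_batch",
    "write_psm_table", "PSM_COLUMNS",
]


@dataclass(frozen=True)
class SearchParams:
    """Tolerances and limits governing a search.

    open_delta_range is the signed interval of precursor mass differences
    considered in open mode (default -200 to +500 Da, covering common
    losses through large additions); mod_match_tol is the absolute window
    for explaining a residual delta as a known modification.
    """

    precursor_tol: Tolerance = Tolerance(10.0, "ppm")
    fragment_tol: float = 0.02
    open_delta_range: tuple[float, float] = (-200.0, 500.0)
    mod_match_tol: float = 0.01
    top_k: int = 5
    min_matched_peaks: int = 1

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0 or self.mod_match_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        lo, hi = self.open_delta_range
        if lo > hi:
            raise ValueError("open_delta_range must be a non-empty interval")


@dataclass(frozen=True)
class PeptideSpectrumMatch:
    """A scored pairing of one spectrum with one candidate peptide."""

    spectrum_id: str
    entry: PeptideEntry | None
    peptide: str
    score: float
    matched_peaks: int
    precursor_delta: float
    mod_id: str | None = None
    mod_site: int | None = None  # 0-based residue position
    flag: str = ""

    def rank_key(self) -> tuple:
        """Global ordering: score desc, |delta| asc, entry coordinates asc."""
        e = self.entry or PeptideEntry(0, 0, 0)
        return (-self.score, abs(self.precursor_delta),
                e.protein_id, e.start, e.length)


def score_psm(
    spectrum: Spectrum,
    peptide: str,
    mod: tuple[float, int] | None,
    fragment_tol: float,
) -> tuple[float, int]:
    """Greedy one-to-one fragment matching; returns (score, matched_peaks).

    Theoretical fragments pair with observed peaks within `fragment_tol`,
    closest pairs claimed first, each observed peak and each fragment
    used at most once.  The score is the pair count plus the matched
    intensity fraction (strictly below 1), so more matches always beat a
    better intensity fraction.  Deterministic.
    """
    if len(spectrum) == 0:
        return 0.0, 0
    frags = theoretical_fragments(peptide, mod)
    mz, inten = spectrum.mz, spectrum.intensity
    # candidate pairs within tolerance, nearest first
    pairs: list[tuple[float, int, int]] = []
    lo_idx = np.searchsorted(mz, frags - fragment_tol, side="left")
    hi_idx = np.searchsorted(mz, frags + fragment_tol, side="right")
    for fi, (a, b) in enumerate(zip(lo_idx, hi_idx)):
        for pi in range(a, b):
            pairs.append((abs(frags[fi] - mz[pi]), fi, pi))
    pairs.sort()
    used_frag: set[int] = set()
    used_peak: set[int] = set()
    matched_intensity = 0.0
    for _, fi, pi in pairs:
        if fi in used_frag or pi in used_peak:
            continue
        used_frag.add(fi)
        used_peak.add(pi)
        matched_intensity += inten[pi]
    matched = len(used_frag)
    total = float(inten.sum())
    frac = matched_intensity / (total + 1e-9) if total > 0 else 0.0
    return matched + frac, matched


def _concat_prefix(
    proteins: Sequence[ProteinRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """One flat residue-mass prefix array covering every protein.

    ``cp[offsets[pid] + i]`` is the mass of protein pid's first i
    residues.  Residues without a defined mass contribute 0 here; that is
    safe because index entries never span them (they are filtered out at
    digestion time), and this array is only ever evaluated on index
    entries.
    """
    counts = np.array([len(p) + 1 for p in proteins], dtype=np.int64)
    offsets = np.zeros(len(proteins) + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    cp = np.empty(int(offsets[-1]), dtype=np.float64)
    for pid, protein in enumerate(proteins):
        lo = offsets[pid]
        cp[lo] = 0.0
        res = [RESIDUE_MASSES.get(aa, 0.0) for aa in protein.sequence]
        np.cumsum(res, out=cp[lo + 1:offsets[pid + 1]])
    return cp, offsets[:-1]


def _stage1_hit_counts(
    index: PeptideIndex, first: int, count: int,
    cp: np.ndarray, offsets: np.ndarray,
    mz: np.ndarray, fragment_tol: float,
) -> np.ndarray:
    """Per-candidate count of unmodified b/y fragments near any peak.

    Vectorized over the whole candidate window.  The count bounds the
    greedy matched-peak count from above, so it can discard candidates
    that cannot reach the stage-1 anchoring threshold without changing
    which PSMs are reported.
    """
    ent = index.entries[first:first + count].astype(np.int64)
    pid, start, length = ent[:, 0], ent[:, 1], ent[:, 2]
    base = offsets[pid] + start
    n_frag = length - 1  # split points; two ions per split
    total = int(n_frag.sum())
    cum = np.concatenate([[0], np.cumsum(n_frag)])
    cand = np.repeat(np.arange(count), n_frag)
    inner = np.arange(total) - cum[cand] + 1  # split index 1..length-1
    b = cp[base[cand] + inner] - cp[base[cand]] + PROTON_MASS
    end = (base + length)[cand]
    y = cp[end] - cp[end - inner] + WATER_MASS + PROTON_MASS

    def _hit(frag_mz: np.ndarray) -> np.ndarray:
        return (np.searchsorted(mz, frag_mz + fragment_tol, side="right")
                > np.searchsorted(mz, frag_mz - fragment_tol, side="left"))

    hits = _hit(b).astype(np.float64) + _hit(y)
    return np.bincount(cand, weights=hits, minlength=count).astype(np.int64)


def _candidates(index: PeptideIndex, proteins: Sequence[ProteinRecord],
                lo: float, hi: float):
    first, count = index.query_mass_range(lo, hi)
    for pos in range(first, first + count):
        entry = index.entry_at(pos)
        protein = proteins[entry.protein_id]
        yield entry, entry.extract(protein), float(index.masses[pos])


def _finalize(psms: list[PeptideSpectrumMatch],
              top_k: int) -> list[PeptideSpectrumMatch]:
    psms.sort(key=PeptideSpectrumMatch.rank_key)
    return psms[:top_k]


def search_spectrum_closed(
    spectrum: Spectrum,
    index: PeptideIndex,
    proteins: Sequence[ProteinRecord],
    params: SearchParams,
) -> list[PeptideSpectrumMatch]:
    """Score every indexed peptide inside the precursor window; top_k PSMs."""
    observed = neutral_mass(spectrum)
    lo, hi = params.precursor_tol.window(observed)
    psms = []
    for entry, peptide, pmass in _candidates(index, proteins, lo, hi):
        score, matched = score_psm(spectrum, peptide, None,
                                   params.fragment_tol)
        if matched < params.min_matched_peaks:
            continue
        psms.append(PeptideSpectrumMatch(
            spectrum.spectrum_id, entry, peptide, score, matched,
            observed - pmass,
        ))
    return _finalize(psms, params.top_k)


def _compatible_sites(mod: ModificationRecord, peptide: str,
                      entry: PeptideEntry,
                      protein: ProteinRecord) -> list[int]:
    """0-based positions in `peptide` where `mod` may sit."""
    return compatible_sites(
        mod, peptide,
        protein_nterm=entry.start == 0,
        protein_cterm=entry.start + entry.length == len(protein),
    )


def search_spectrum_open(
    spectrum: Spectrum,
    index: PeptideIndex,
    proteins: Sequence[ProteinRecord],
    mindex: ModificationIndex,
    params: SearchParams,
) -> list[PeptideSpectrumMatch]:
    """Two-stage open search: anchor candidates, then explain the delta."""
    observed = neutral_mass(spectrum)
    d_lo, d_hi = params.open_delta_range
    first, count = index.query_mass_range(observed - d_hi, observed - d_lo)
    if params.min_matched_peaks >= 1:
        if len(spectrum) == 0 or count == 0:
            return []
        cp, offsets = _concat_prefix(proteins)
        upper = _stage1_hit_counts(index, first, count, cp, offsets,
                                   spectrum.mz, params.fragment_tol)
        positions = (first + np.nonzero(
            upper >= params.min_matched_peaks)[0]).tolist()
    else:
        positions = range(first, first + count)
    psms = []
    for pos in positions:
        entry = index.entry_at(pos)
        peptide = entry.extract(proteins[entry.protein_id])
        pmass = float(index.masses[pos])
        base_score, base_matched = score_psm(
            spectrum, peptide, None, params.fragment_tol)
        if base_matched < params.min_matched_peaks:
            continue  # stage-1 anchoring filter
        delta = observed - pmass
        if abs(delta) <= params.mod_match_tol:
            psms.append(PeptideSpectrumMatch(
                spectrum.spectrum_id, entry, peptide, base_score,
                base_matched, delta,
            ))
            continue
        protein = proteins[entry.protein_id]
        best: PeptideSpectrumMatch | None = None
        best_key: tuple | None = None
        for mod in mindex.query(delta, params.mod_match_tol):
            for site in _compatible_sites(mod, peptide, entry, protein):
                score, matched = score_psm(
                    spectrum, peptide, (mod.delta_mass, site),
                    params.fragment_tol)
                key = (-score, abs(delta - mod.delta_mass), mod.mod_id, site)
                if best_key is None or key < best_key:
                    best_key = key
                    best = PeptideSpectrumMatch(
                        spectrum.spectrum_id, entry, peptide, score, matched,
                        delta - mod.delta_mass, mod.mod_id, site,
                    )
        if best is not None and best.matched_peaks >= params.min_matched_peaks:
            psms.append(best)
        else:
            psms.append(PeptideSpectrumMatch(
                spectrum.spectrum_id, entry, peptide, base_score,
                base_matched, delta, flag="unexplained-delta",
            ))
    return _finalize(psms, params.top_k)


def search_batch(
    spectra: Sequence[Spectrum],
    index: PeptideIndex,
    proteins: Sequence[ProteinRecord],
    params: SearchParams,
    mode: str = "closed",
    mindex: ModificationIndex | None = None,
) -> list[PeptideSpectrumMatch]:
    """Search every spectrum; output ordered by (spectrum_id, rank).

    Per-spectrum failures become flagged rows rather than aborting the
    batch.  The result is independent of the input spectrum order.
    """
    if mode not in ("closed", "open"):
        raise ValueError(f"unknown search mode: {mode!r}")
    if mode == "open" and mindex is None:
        raise ValueError("open search requires a modification index")
    results: list[tuple[str, list[PeptideSpectrumMatch]]] = []
    for spectrum in spectra:
        try:
            if mode == "closed":
                psms = search_spectrum_closed(spectrum, index, proteins, params)
            else:
                psms = search_spectrum_open(spectrum, index, proteins,
                                            mindex, params)
        except Exception as exc:  # keep the batch going
            psms = [PeptideSpectrumMatch(
                spectrum.spectrum_id, None, "", 0.0, 0, 0.0,
                flag=f"error:{exc}",
            )]
        results.append((spectrum.spectrum_id, psms))
    results.sort(key=lambda item: item[0])
    return [psm for _, psms in results for psm in psms]


PSM_COLUMNS = [
    "spectrum_id", "peptide", "protein", "start", "length", "score",
    "matched_peaks", "precursor_delta", "mod_id", "mod_site", "flag",
]


def write_psm_table(
    psms: Iterable[PeptideSpectrumMatch],
    proteins: Sequence[ProteinRecord],
    path: str | Path,
) -> None:
    """Write PSMs as TSV; start and mod_site are reported 1-based."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PSM_COLUMNS)
        for p in psms:
            if p.entry is not None:
                accession = proteins[p.entry.protein_id].accession
                start = p.entry.start + 1
                length = p.entry.length
            else:
                accession, start, length = "", "", ""
            writer.writerow([
                p.spectrum_id, p.peptide, accession, start, length,
                f"{p.score:.6f}", p.matched_peaks,
                f"{p.precursor_delta:.6f}",
                p.mod_id or "", "" if p.mod_site is None else p.mod_site + 1,
                p.flag,
            ])
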