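"""End-to-end synthetic benchmarks with known ground truth.

A benchmark consists of a random protein database, a set of MS/MS spectra
each synthesized from a peptide actually present in that database
(optionally carrying one planted modification at a known site), and a
truth table tying every spectrum to its source peptide.  Search recovery
against the truth table is the package's primary correctness benchmark,
since no public spectral ground truth exists at this scale.

Defaults emulate a clean high-resolution experiment: charge states 2+
and 3+, planted peptides of 7-25 residues (the typical identified-peptide
length range), no fragment dropout and no noise peaks unless requested.
What clean synthetic spectra cannot emulate — chimeric spectra,
isotope-envelope errors, real intensity models — is documented in the
methods note.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .digestion import DigestionParams, PeptideEntry, enumerate_peptides
from .modifications import (
    ModificationRecord, compatible_sites, default_modifications,
)
from .sequence_io import ProteinRecord, generate_synthetic_fasta
from .spectra import Spectrum, synthesize_spectrum

__all__ = ["PlantedTruth", "simulate_benchmark", "write_truth_table",
           "read_truth_table"]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one synthesized spectrum."""

    spectrum_id: str
    peptide: str
    protein_id: int
    start: int
    length: int
    charge: int
    mod_id: str | None = None
    mod_site: int | None = None  # 0-based position within the peptide


def simulate_benchmark(
    n_proteins: int = 50,
    n_spectra: int = 200,
    modified_fraction: float = 0.0,
    dropout: float = 0.0,
    n_noise_peaks: int = 0,
    seed: int = 0,
    digestion_params: DigestionParams | None = None,
    mods: Sequence[ModificationRecord] | None = None,
    min_plant_len: int = 7,
    max_plant_len: int = 25,
    protein_length_range: tuple[int, int] = (80, 400),
) -> tuple[list[ProteinRecord], list[Spectrum], list[PlantedTruth]]:
    """Generate a database, planted spectra, and the truth table.

    Each spectrum's peptide is drawn uniformly from the database's
    digestible peptides with length in [min_plant_len, max_plant_len];
    a `modified_fraction` of spectra carry one modification drawn
    uniformly from the site-compatible entries of `mods` (default: the
    shipped table), planted at a random compatible site.  Deterministic
    for a fixed seed.
    """
    if not (0.0 <= modified_fraction <= 1.0):
        raise ValueError("modified_fraction must be in [0, 1]")
    if digestion_params is None:
        digestion_params = DigestionParams()
    if mods is None:
        mods = default_modifications()
    rng = np.random.default_rng(seed)
    proteins = generate_synthetic_fasta(
        n_proteins, *protein_length_range,
        seed=int(rng.integers(0, 2**31)),
    )
    candidates: list[tuple[PeptideEntry, str]] = []
    for protein in proteins:
        for entry, _mass in enumerate_peptides(protein, digestion_params):
            if min_plant_len <= entry.length <= max_plant_len:
                candidates.append((entry, entry.extract(protein)))
    if not candidates:
        raise ValueError("database yields no plantable peptides")
    spectra: list[Spectrum] = []
    truths: list[PlantedTruth] = []
    picks = rng.integers(0, len(candidates), size=n_spectra)
    n_modified = int(round(modified_fraction * n_spectra))
    for i, pick in enumerate(picks):
        entry, peptide = candidates[int(pick)]
        protein = proteins[entry.protein_id]
        charge = 2 if rng.random() < 0.6 else 3
        mod_id = None
        site = None
        mod_arg = None
        if i < n_modified:
            usable = []
            for mod in mods:
                sites = compatible_sites(
                    mod, peptide,
                    protein_nterm=entry.start == 0,
                    protein_cterm=entry.start + entry.length == len(protein),
                )
                if sites:
                    usable.append((mod, sites))
            if usable:
                mod, sites = usable[int(rng.integers(0, len(usable)))]
                site = int(sites[int(rng.integers(0, len(sites)))])
                mod_id = mod.mod_id
                mod_arg = (mod.delta_mass, site)
        sid = f"bench_{seed}_{i:05d}"
        spectra.append(synthesize_spectrum(
            peptide, charge=charge, mod=mod_arg,
            n_noise_peaks=n_noise_peaks, dropout=dropout,
            seed=int(rng.integers(0, 2**31)), spectrum_id=sid,
        ))
        truths.append(PlantedTruth(
            sid, peptide, entry.protein_id, entry.start, entry.length,
            charge, mod_id, site,
        ))
    return proteins, spectra, truths


_TRUTH_COLUMNS = ["spectrum_id", "peptide", "protein_id", "start", "length",
                  "charge", "mod_id", "mod_site"]


def write_truth_table(truths: Sequence[PlantedTruth],
                      path: str | Path) -> None:
    """Write the ground-truth table as TSV (start and mod_site 0-based)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TRUTH_COLUMNS)
        for t in truths:
            writer.writerow([
                t.spectrum_id, t.peptide, t.protein_id, t.start, t.length,
                t.charge, t.mod_id or "",
                "" if t.mod_site is None else t.mod_site,
            ])


def read_truth_table(path: str | Path) -> list[PlantedTruth]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        out = []
        for row in reader:
            out.append(PlantedTruth(
                row["spectrum_id"], row["peptide"], int(row["protein_id"]),
                int(row["start"]), int(row["length"]), int(row["charge"]),
                row["mod_id"] or None,
                int(row["mod_site"]) if row["mod_site"] else None,
            ))
        return out
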