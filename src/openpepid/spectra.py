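"""MS/MS spectra: MGF input/output, mass conversions, synthesis.

A spectrum holds the precursor m/z and charge plus a peak list of
(fragment m/z, intensity) pairs sorted by m/z.  The neutral precursor
mass M relates to the measured m/z by ``M = z * mz - z * proton``.

The fragment model is singly charged b- and y-ions (the dominant backbone
series under beam-type collisional dissociation):

    b_i = sum of the first i residue masses + proton
    y_i = sum of the last i residue masses + water + proton

so ``b_i + y_(n-i) = M + 2 * proton`` for every split point — an identity
the test suite exercises.  A single modification of delta mass D at
residue position s shifts every fragment whose span contains s by D.

The synthesizer plants a known peptide (optionally modified) into a
spectrum with controllable fragment dropout and uniform noise peaks,
providing ground truth for search benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .constants import PROTON_MASS, WATER_MASS
from .digestion import peptide_mass, residue_prefix_masses

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum", "MgfParseError", "read_mgf", "write_mgf", "neutral_mass",
    "theoretical_fragments", "synthesize_spectrum",
    "query_mass_distribution",
]


class MgfParseError(ValueError):
    """Malformed MGF input (unterminated block, missing PEPMASS, ...)."""


@dataclass(frozen=True)
class Spectrum:
    """One MS/MS spectrum: identifier, precursor, sorted peak list."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be > 0")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        mz = np.asarray(self.mz, dtype=np.float64)
        inten = np.asarray(self.intensity, dtype=np.float64)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity must have equal lengths")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", np.ascontiguousarray(mz[order]))
        object.__setattr__(self, "intensity", np.ascontiguousarray(inten[order]))

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


def neutral_mass(spectrum: Spectrum) -> float:
    """Uncharged precursor mass: charge x (m/z - proton mass)."""
    return spectrum.charge * (spectrum.precursor_mz - PROTON_MASS)


def mz_from_mass(mass: float, charge: int) -> float:
    """Precursor m/z of a neutral mass at the given charge state."""
    return (mass + charge * PROTON_MASS) / charge


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF peak-list file into :class:`Spectrum` objects.

    Blocks must carry PEPMASS; a block without CHARGE defaults to 2+ with
    a logged warning.  Raises :class:`MgfParseError` on malformed input,
    including unterminated BEGIN IONS blocks.
    """
    text = Path(path).read_text()
    if text.count("BEGIN IONS") != text.count("END IONS"):
        raise MgfParseError(f"{path}: unterminated BEGIN IONS block")
    spectra: list[Spectrum] = []
    try:
        with _mgf.read(str(path), use_index=False) as reader:
            for i, entry in enumerate(reader):
                params = entry["params"]
                title = str(params.get("title", f"spectrum_{i}"))
                pepmass = params.get("pepmass")
                if pepmass is None or pepmass[0] is None:
                    raise MgfParseError(
                        f"{path}: spectrum {title!r} has no PEPMASS"
                    )
                charges = params.get("charge")
                if charges:
                    charge = int(charges[0])
                else:
                    logger.warning(
                        "spectrum %r has no CHARGE; assuming 2+", title
                    )
                    charge = 2
                spectra.append(Spectrum(
                    title, float(pepmass[0]), charge,
                    entry["m/z array"], entry["intensity array"],
                ))
    except MgfParseError:
        raise
    except Exception as exc:
        raise MgfParseError(f"{path}: malformed MGF ({exc})") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (PEPMASS = m/z, CHARGE like ``2+``)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n")


def theoretical_fragments(
    peptide: str,
    mod: tuple[float, int] | None = None,
) -> np.ndarray:
    """Singly charged b/y fragment m/z values, ascending, deduplicated.

    `mod` is an optional (delta mass, 0-based site position); the delta is
    added to every fragment whose residue span contains the site.
    Duplicate m/z values closer than 1e-6 are collapsed.
    """
    n = len(peptide)
    if n < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    prefix = residue_prefix_masses(peptide)
    if np.isnan(prefix[-1]):
        raise ValueError(f"peptide {peptide!r} contains undefined residues")
    total = float(prefix[-1])
    delta, site = (0.0, -1) if mod is None else (float(mod[0]), int(mod[1]))
    if mod is not None and not (0 <= site < n):
        raise ValueError(f"modification site {site} outside peptide of length {n}")
    i = np.arange(1, n)
    b = prefix[1:n] + PROTON_MASS
    y = (total - prefix[n - i]) + WATER_MASS + PROTON_MASS
    if mod is not None:
        b = b + delta * (i > site)
        y = y + delta * (site >= n - i)
    frags = np.concatenate([b, y])
    frags.sort()
    keep = np.ones(len(frags), dtype=bool)
    keep[1:] = np.diff(frags) > 1e-6
    return frags[keep]


def synthesize_spectrum(
    peptide: str,
    charge: int = 2,
    mod: tuple[float, int] | None = None,
    n_noise_peaks: int = 0,
    noise_mz_range: tuple[float, float] = (100.0, 1500.0),
    dropout: float = 0.0,
    seed: int = 0,
    spectrum_id: str | None = None,
) -> Spectrum:
    """Generate a spectrum with a planted peptide and known ground truth.

    The precursor m/z encodes the peptide mass plus any modification
    delta at the requested charge.  Peaks are the theoretical b/y
    fragments minus a seeded random `dropout` fraction (each fragment
    dropped independently), plus `n_noise_peaks` uniform random noise
    peaks.  Fragment intensities are 100 with a small seeded jitter;
    noise intensities are below 30.  Deterministic for a fixed seed.
    """
    if not (0.0 <= dropout < 1.0):
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mass = peptide_mass(peptide) + (mod[0] if mod else 0.0)
    frags = theoretical_fragments(peptide, mod)
    if dropout > 0:
        keep = rng.random(len(frags)) >= dropout
        frags = frags[keep]
    frag_intensity = 100.0 + rng.uniform(-10.0, 10.0, size=len(frags))
    noise_mz = rng.uniform(*noise_mz_range, size=n_noise_peaks)
    noise_intensity = rng.uniform(1.0, 30.0, size=n_noise_peaks)
    if spectrum_id is None:
        spectrum_id = f"synth|{peptide}|z{charge}|seed{seed}"
    return Spectrum(
        spectrum_id,
        mz_from_mass(mass, charge),
        charge,
        np.concatenate([frags, noise_mz]),
        np.concatenate([frag_intensity, noise_intensity]),
    )


def query_mass_distribution(
    spectra: Sequence[Spectrum],
    bin_edges: Sequence[float],
) -> np.ndarray:
    """Histogram of precursor neutral masses over the given bin edges.

    Masses outside the edges are counted in the nearest end bin so the
    counts always partition the input (they sum to the spectrum count).
    """
    if len(spectra) == 0:
        raise ValueError("query_mass_distribution needs at least one spectrum")
    edges = np.asarray(bin_edges, dtype=np.float64)
    masses = np.array([neutral_mass(s) for s in spectra])
    clipped = np.clip(masses, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return counts
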