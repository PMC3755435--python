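"""Scoring, closed search, and two-stage open search."""

import numpy as np
import pytest

from openpepid.digestion import DigestionParams, peptide_mass
from openpepid.modifications import default_mod_index
from openpepid.peptide_index import build_index
from openpepid.search import (
    PeptideSpectrumMatch, SearchParams, score_psm, search_batch,
    search_spectrum_closed, search_spectrum_open, write_psm_table,
)
from openpepid.simulate import simulate_benchmark
from openpepid.spectra import (
    Spectrum, mz_from_mass, synthesize_spectrum, theoretical_fragments,
)


@pytest.fixture(scope="module")
def bench():
    proteins, spectra, truths = simulate_benchmark(
        n_proteins=15, n_spectra=30, modified_fraction=0.0, seed=21)
    index = build_index(proteins, DigestionParams())
    return proteins, spectra, truths, index


@pytest.fixture(scope="module")
def mindex():
    return default_mod_index()


def brute_force_closed(spectrum, index, proteins, params):
    """Independent oracle: score every in-window peptide by linear scan."""
    from openpepid.spectra import neutral_mass
    observed = neutral_mass(spectrum)
    lo, hi = params.precursor_tol.window(observed)
    psms = []
    for pos in range(len(index)):
        m = float(index.masses[pos])
        if not (lo <= m <= hi):
            continue
        entry = index.entry_at(pos)
        peptide = entry.extract(proteins[entry.protein_id])
        score, matched = score_psm(spectrum, peptide, None,
                                   params.fragment_tol)
        if matched < params.min_matched_peaks:
            continue
        psms.append(PeptideSpectrumMatch(
            spectrum.spectrum_id, entry, peptide, score, matched,
            observed - m))
    psms.sort(key=PeptideSpectrumMatch.rank_key)
    return psms[:params.top_k]


class TestScore:
    def test_self_match_hits_every_fragment(self):
        s = synthesize_spectrum("ELVISWAK", 2, seed=5)
        score, matched = score_psm(s, "ELVISWAK", None, 0.02)
        assert matched == len(theoretical_fragments("ELVISWAK"))
        assert score == pytest.approx(matched + 1.0, abs=1e-6)

    def test_empty_peak_list_scores_zero(self):
        s = Spectrum("x", 500.0, 2, np.array([]), np.array([]))
        assert score_psm(s, "ELVISWAK", None, 0.02) == (0.0, 0)

    def test_unrelated_peptide_scores_below_self_match(self):
        rng = np.random.default_rng(17)
        from openpepid.constants import CANONICAL_RESIDUES
        letters = list(CANONICAL_RESIDUES)
        for _ in range(20):
            a = "".join(rng.choice(letters, size=12))
            b = "".join(rng.choice(letters, size=12))
            if a == b:
                continue
            s = synthesize_spectrum(a, 2, seed=int(rng.integers(1 << 30)))
            assert score_psm(s, a, None, 0.02) > score_psm(s, b, None, 0.02)

    def test_deterministic(self):
        s = synthesize_spectrum("SAMPLEK", 2, n_noise_peaks=10, seed=2)
        assert score_psm(s, "SAMPLEK", None, 0.02) \
            == score_psm(s, "SAMPLEK", None, 0.02)


class TestClosedSearch:
    def test_planted_peptides_rank_first(self, bench):
        proteins, spectra, truths, index = bench
        params = SearchParams()
        for s, t in zip(spectra, truths):
            psms = search_spectrum_closed(s, index, proteins, params)
            assert psms and psms[0].peptide == t.peptide

    def test_mass_outside_index_range_is_empty(self, bench):
        proteins, _, _, index = bench
        s = Spectrum("hi", mz_from_mass(20000.0, 2), 2,
                     np.array([500.0]), np.array([1.0]))
        assert search_spectrum_closed(s, index, proteins,
                                      SearchParams()) == []

    def test_equals_brute_force_oracle(self, bench):
        proteins, spectra, _, index = bench
        params = SearchParams(top_k=10)
        for s in spectra[:10]:
            got = search_spectrum_closed(s, index, proteins, params)
            want = brute_force_closed(s, index, proteins, params)
            assert got == want


class TestOpenSearch:
    def test_planted_phospho_recovered_with_site(self, bench, mindex):
        proteins, _, _, index = bench
        # pick an indexed peptide containing S away from the termini
        target = None
        for pos in range(len(index)):
            entry = index.entry_at(pos)
            pep = entry.extract(proteins[entry.protein_id])
            if 8 <= len(pep) <= 15 and "S" in pep[2:-2]:
                target, site = pep, 2 + pep[2:-2].index("S")
                break
        assert target is not None
        s = synthesize_spectrum(target, 2, mod=(79.966331, site), seed=3)
        psms = search_spectrum_open(s, index, proteins, mindex,
                                    SearchParams())
        top = psms[0]
        assert top.peptide == target
        assert top.mod_id == "phospho"
        assert top.mod_site == site

    def test_zero_delta_consistent_with_closed(self, bench, mindex):
        proteins, spectra, _, index = bench
        params = SearchParams()
        for s in spectra[:8]:
            closed = search_spectrum_closed(s, index, proteins, params)
            opened = search_spectrum_open(s, index, proteins, mindex,
                                          params)
            assert opened[0].peptide == closed[0].peptide
            assert opened[0].mod_id is None
            assert opened[0].score == closed[0].score

    def test_narrow_delta_range_reduces_to_closed(self, bench, mindex):
        proteins, spectra, _, index = bench
        s = spectra[0]
        closed = search_spectrum_closed(s, index, proteins, SearchParams())
        tol = SearchParams().precursor_tol.half_width(
            s.charge * s.precursor_mz)
        narrow = SearchParams(open_delta_range=(-tol, tol))
        opened = search_spectrum_open(s, index, proteins, mindex, narrow)
        assert opened[0].peptide == closed[0].peptide
        assert opened[0].entry == closed[0].entry

    def test_unmatched_delta_flagged_unexplained(self, bench, mindex):
        proteins, _, _, index = bench
        entry = index.entry_at(len(index) // 2)
        pep = entry.extract(proteins[entry.protein_id])
        # a delta present in no table record
        weird = 123.4567
        s = Spectrum("weird", mz_from_mass(peptide_mass(pep) + weird, 2),
                     2, theoretical_fragments(pep),
                     np.full(2 * (len(pep) - 1), 100.0))
        psms = search_spectrum_open(s, index, proteins, mindex,
                                    SearchParams())
        top = next(p for p in psms if p.peptide == pep)
        assert top.mod_id is None
        assert top.flag == "unexplained-delta"
        assert top.precursor_delta == pytest.approx(weird, abs=1e-6)


class TestBatch:
    def test_equals_per_spectrum_calls_and_order_invariant(self, bench):
        proteins, spectra, _, index = bench
        params = SearchParams()
        batch = search_batch(spectra, index, proteins, params)
        shuffled = search_batch(list(reversed(spectra)), index, proteins,
                                params)
        assert batch == shuffled
        by_hand = []
        for s in sorted(spectra, key=lambda x: x.spectrum_id):
            by_hand.extend(search_spectrum_closed(s, index, proteins,
                                                  params))
        assert batch == by_hand

    def test_psm_table_columns_and_coordinates(self, bench, tmp_path):
        proteins, spectra, truths, index = bench
        psms = search_batch(spectra[:3], index, proteins, SearchParams())
        path = tmp_path / "psms.tsv"
        write_psm_table(psms, proteins, path)
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        assert header[:5] == ["spectrum_id", "peptide", "protein",
                              "start", "length"]
        first = dict(zip(header, lines[1].split("\t")))
        entry = psms[0].entry
        assert int(first["start"]) == entry.start + 1  # 1-based report
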