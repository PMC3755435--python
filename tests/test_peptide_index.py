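"""Mass-sorted index: build, queries, statistics, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from openpepid.digestion import DigestionParams, count_nonspecific
from openpepid.peptide_index import (
    IndexCorruptionError, IndexFormatError, build_index, load_index,
    save_index, _FIXED_HEADER,
)
from openpepid.sequence_io import generate_synthetic_fasta


def _linear_scan(index, lo, hi):
    mask = (index.masses >= lo) & (index.masses <= hi)
    positions = np.nonzero(mask)[0]
    if len(positions) == 0:
        return None
    return int(positions[0]), len(positions)


class TestBuild:
    def test_entry_count_equals_per_protein_brute_force(self,
                                                        default_params):
        proteins = generate_synthetic_fasta(2, 40, 40, seed=5)
        index = build_index(proteins, default_params)
        brute = 0
        for p in proteins:
            for start in range(len(p)):
                for length in range(default_params.min_len,
                                    default_params.max_len + 1):
                    if start + length > len(p):
                        break
                    from openpepid.digestion import peptide_mass
                    m = peptide_mass(p.sequence[start:start + length])
                    if default_params.min_mass <= m <= default_params.max_mass:
                        brute += 1
        assert len(index) == brute

    def test_empty_collection_gives_empty_index(self, default_params):
        index = build_index([], default_params)
        assert len(index) == 0
        assert (index.bucket_offsets == 0).all()

    def test_sorted_with_deterministic_tie_order(self, small_index):
        masses = small_index.masses
        assert (np.diff(masses) >= 0).all()
        # ties ordered by (protein_id, start, length)
        for i in np.nonzero(np.diff(masses) == 0)[0]:
            a = tuple(small_index.entries[i])
            b = tuple(small_index.entries[i + 1])
            assert a < b

    def test_build_is_deterministic(self, small_proteins, default_params):
        a = build_index(small_proteins, default_params)
        b = build_index(small_proteins, default_params)
        assert np.array_equal(a.masses, b.masses)
        assert np.array_equal(a.entries, b.entries)


class TestQuery:
    def test_empty_window_returns_zero_count(self, small_index):
        _, count = small_index.query_mass_range(100.0, 100.1)
        assert count == 0

    def test_rejects_inverted_window(self, small_index):
        with pytest.raises(ValueError):
            small_index.query_mass_range(700.0, 600.0)

    def test_exact_mass_of_indexed_peptide_is_found(self, small_index):
        target = float(small_index.masses[len(small_index) // 2])
        first, count = small_index.query_mass_range(target, target)
        assert count >= 1
        assert small_index.masses[first] == target

    @settings(max_examples=200, deadline=None)
    @given(st.floats(250, 8100), st.floats(0, 50))
    def test_matches_linear_scan(self, small_index, lo, width):
        hi = lo + width
        first, count = small_index.query_mass_range(lo, hi)
        expected = _linear_scan(small_index, lo, hi)
        if expected is None:
            assert count == 0
        else:
            assert (first, count) == expected

    def test_bucket_lookup_equals_global_bisection(self, small_index):
        for b in range(small_index.bucket_base,
                       small_index.bucket_base
                       + len(small_index.bucket_offsets)):
            got = small_index._first_geq(float(b))
            want = int(np.searchsorted(small_index.masses, float(b),
                                       side="left"))
            assert got == want


class TestStatistics:
    def test_histogram_conserves_and_matches_brute_force(self, small_index):
        hist = small_index.mass_histogram(100.0)
        assert sum(hist.values()) == len(small_index)
        bins = np.floor(small_index.masses / 100.0) * 100.0
        for edge, count in hist.items():
            assert count == int((bins == edge).sum())

    def test_single_entry_histogram(self, default_params):
        proteins = generate_synthetic_fasta(1, 3, 3, seed=2)
        params = DigestionParams(min_mass=1.0, max_mass=8000.0)
        index = build_index(proteins, params)
        assert len(index) == 1
        hist = index.mass_histogram(50.0)
        assert list(hist.values()) == [1]

    def test_fraction_below_extremes_and_oracle(self, small_index):
        assert small_index.fraction_below(1.0) == 0.0
        assert small_index.fraction_below(1e9) == 1.0
        got = small_index.fraction_below(2000.0)
        want = (small_index.masses <= 2000.0).mean()
        assert got == pytest.approx(want, abs=1e-12)

    def test_fraction_below_empty_index_undefined(self, default_params):
        index = build_index([], default_params)
        with pytest.raises(ValueError):
            index.fraction_below(2000.0)


class TestSerialization:
    def test_round_trip_bit_exact(self, small_index, tmp_path):
        path = tmp_path / "db.idx"
        save_index(small_index, path)
        loaded = load_index(path)
        assert np.array_equal(loaded.masses, small_index.masses)
        assert np.array_equal(loaded.entries, small_index.entries)
        assert np.array_equal(loaded.bucket_offsets,
                              small_index.bucket_offsets)
        assert loaded.params == small_index.params
        assert loaded.db_fingerprint == small_index.db_fingerprint

    def test_constant_20_byte_records_by_file_size(self, small_index,
                                                   tmp_path):
        path = tmp_path / "db.idx"
        save_index(small_index, path)
        n = len(small_index)
        blob_len = path.stat().st_size - _FIXED_HEADER.size - 20 * n \
            - 8 * len(small_index.bucket_offsets)
        # remaining bytes are exactly the JSON parameter blob
        header_len = _FIXED_HEADER.size + blob_len
        assert path.stat().st_size == header_len + 20 * n \
            + 8 * len(small_index.bucket_offsets)
        assert blob_len > 0

    def test_truncated_file_detected(self, small_index, tmp_path):
        path = tmp_path / "db.idx"
        save_index(small_index, path)
        data = path.read_bytes()
        path.write_bytes(data[:-1])
        with pytest.raises(IndexCorruptionError):
            load_index(path)

    def test_bad_magic_detected(self, small_index, tmp_path):
        path = tmp_path / "db.idx"
        save_index(small_index, path)
        data = bytearray(path.read_bytes())
        data[0] ^= 0xFF
        path.write_bytes(bytes(data))
        with pytest.raises(IndexFormatError):
            load_index(path)


class TestBlocks:
    def test_slice_preserves_entries_and_answers_queries(self, small_index):
        n = len(small_index)
        block = small_index.slice_block(n // 3, 2 * n // 3)
        assert len(block) == 2 * n // 3 - n // 3
        lo = float(block.masses[0])
        hi = float(block.masses[-1])
        first, count = block.query_mass_range(lo, hi)
        assert first == 0 and count == len(block)
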