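"""Partitioned, multi-worker search on one machine.

The database is split into contiguous parts balanced by residue (amino
acid) count — digestion and search cost scale with residues, not with
protein count — and each part's index is further split into blocks no
larger than a configurable entry budget, so the working set per search
round is bounded regardless of database size.  Spectra are sorted by
precursor neutral mass and divided into contiguous chunks, so each
subtask touches a narrow, cache-friendly slice of the mass-sorted index.
Chunks are assigned to workers statically (chunk i to worker i); while a
worker searches one block the next block may be prepared concurrently
(prefetch), and the merged result is guaranteed identical — PSM set and
ranking — to a single-worker, single-block search of the whole database.
That transparency is the central correctness property of the design and
is enforced by the per-spectrum merge rule: block partitioning assigns
every indexed peptide to exactly one block, so re-ranking the union of
per-block top-k lists with the global tie-break chain reproduces the
monolithic top-k.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor, ThreadPoolExecutor
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Sequence

import multiprocessing as mp

from .digestion import DigestionParams
from .modifications import ModificationIndex
from .peptide_index import PeptideIndex, build_index
from .search import (
    PeptideSpectrumMatch, SearchParams, search_spectrum_closed,
    search_spectrum_open,
)
from .sequence_io import ProteinRecord
from .spectra import Spectrum, neutral_mass

logger = logging.getLogger(__name__)

__all__ = [
    "PartitionPlan", "SpectrumChunkPlan", "DistributedSearchError",
    "partition_by_amino_acids", "sort_and_chunk_spectra", "parallel_search",
]


class DistributedSearchError(RuntimeError):
    """A worker failed; the message names the failed spectrum chunk."""


@dataclass(frozen=True)
class PartitionPlan:
    """Contiguous protein ranges with their residue totals.

    ``parts[i]`` is a (first_protein_id, last_protein_id + 1) half-open
    range; parts are disjoint and cover the database in order.
    """

    parts: tuple[tuple[int, int], ...]
    residue_totals: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.parts)


@dataclass(frozen=True)
class SpectrumChunkPlan:
    """Spectrum ids grouped into mass-contiguous chunks.

    Concatenating the chunks in order lists every spectrum exactly once,
    sorted by neutral mass (ties by spectrum id).
    """

    chunks: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.chunks)


def _greedy_parts(lengths: Sequence[int],
                  n_parts: int) -> tuple[list[tuple[int, int]], list[int]]:
    """One-pass greedy: close each part at the prefix nearest its share
    of the residues still unassigned (recomputed per part)."""
    n = len(lengths)
    remaining = sum(lengths)
    parts: list[tuple[int, int]] = []
    totals: list[int] = []
    start = 0
    for part_no in range(n_parts):
        parts_left = n_parts - part_no
        if parts_left == 1:
            end = n
        else:
            target = remaining / parts_left
            running = 0
            end = start
            while end < n - (parts_left - 1):
                running += lengths[end]
                end += 1
                if running >= target:
                    overshoot = running - target
                    undershoot = target - (running - lengths[end - 1])
                    if end - start > 1 and overshoot > undershoot:
                        end -= 1
                    break
        total = sum(lengths[start:end])
        parts.append((start, end))
        totals.append(total)
        remaining -= total
        start = end
    return parts, totals


def _refine_sweep(lengths: Sequence[int], parts: list[tuple[int, int]],
                  totals: list[int]) -> None:
    """Move a boundary protein from the heavier of two adjacent parts to
    the lighter while that strictly reduces their imbalance.  Each move
    strictly decreases the sum of squared part totals, so the sweep
    terminates."""
    changed = True
    while changed:
        changed = False
        for j in range(len(parts) - 1):
            (a_lo, a_hi), (b_lo, b_hi) = parts[j], parts[j + 1]
            if a_hi - a_lo > 1:
                moved = lengths[a_hi - 1]
                if totals[j] - totals[j + 1] > moved:
                    parts[j] = (a_lo, a_hi - 1)
                    parts[j + 1] = (a_hi - 1, b_hi)
                    totals[j] -= moved
                    totals[j + 1] += moved
                    changed = True
                    continue
            if b_hi - b_lo > 1:
                moved = lengths[b_lo]
                if totals[j + 1] - totals[j] > moved:
                    parts[j] = (a_lo, a_hi + 1)
                    parts[j + 1] = (a_hi + 1, b_hi)
                    totals[j] += moved
                    totals[j + 1] -= moved
                    changed = True


def _window_partition(lengths: Sequence[int], n_parts: int,
                      lo_total: int, hi_total: int
                      ) -> list[tuple[int, int]] | None:
    """Exact contiguous partition with every part total in
    [lo_total, hi_total], or None.

    Layered reachability over prefix sums: position i is reachable with
    j parts if some reachable r with j-1 parts has prefix[i] - prefix[r]
    inside the window.  Prefix sums are nondecreasing, so the feasible
    r form a contiguous index range per i (bisection); O(n_parts · k log k).
    """
    import bisect

    k = len(lengths)
    prefix = [0] * (k + 1)
    for i, length in enumerate(lengths):
        prefix[i + 1] = prefix[i] + length
    reach = [i == 0 for i in range(k + 1)]
    parents: list[list[int]] = []
    for _ in range(n_parts):
        last_reach = [-1] * (k + 1)
        last = -1
        for i in range(k + 1):
            if reach[i]:
                last = i
            last_reach[i] = last
        new = [False] * (k + 1)
        par = [-1] * (k + 1)
        for i in range(1, k + 1):
            r_lo = bisect.bisect_left(prefix, prefix[i] - hi_total)
            r_hi = min(bisect.bisect_right(prefix, prefix[i] - lo_total),
                       i) - 1
            if r_hi >= r_lo:
                witness = last_reach[r_hi]
                if witness >= r_lo:
                    new[i] = True
                    par[i] = witness
        parents.append(par)
        reach = new
    if not reach[k]:
        return None
    bounds = [k]
    for layer in range(n_parts - 1, -1, -1):
        bounds.append(parents[layer][bounds[-1]])
    bounds.reverse()
    return [(bounds[i], bounds[i + 1]) for i in range(n_parts)]


def partition_by_amino_acids(proteins: Sequence[ProteinRecord],
                             n_parts: int) -> PartitionPlan:
    """Contiguous partition balanced by residue count.

    Proteins are assigned in database order by a greedy pass (each part
    closes at the prefix nearest its share of the remaining residues)
    followed by a boundary-refinement sweep.  If the result still
    spreads part totals by more than the longest single protein — rare,
    and only possible on small adversarial length profiles — an exact
    reachability search finds a partition whose totals all fit in a
    window of that width, restoring the balance bound.  Deterministic.
    If ``n_parts`` exceeds the protein count the result degrades to
    all-singleton parts with a warning.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    n = len(proteins)
    if n == 0:
        return PartitionPlan((), ())
    if n_parts > n:
        logger.warning(
            "n_parts=%d exceeds protein count %d; using singleton parts",
            n_parts, n)
        n_parts = n
    lengths = [len(p) for p in proteins]
    parts, totals = _greedy_parts(lengths, n_parts)
    _refine_sweep(lengths, parts, totals)
    longest = max(lengths)
    if n_parts > 1 and max(totals) - min(totals) > longest:
        total = sum(lengths)
        mean = total / n_parts
        # any valid window must straddle the mean total
        for lo_total in range(int(mean), max(int(mean) - longest, 0) - 1,
                              -1):
            exact = _window_partition(lengths, n_parts, lo_total,
                                      lo_total + longest)
            if exact is not None:
                parts = exact
                totals = [sum(lengths[a:b]) for a, b in exact]
                break
    return PartitionPlan(tuple(parts), tuple(totals))


def sort_and_chunk_spectra(spectra: Sequence[Spectrum],
                           n_chunks: int) -> SpectrumChunkPlan:
    """Sort spectra by neutral mass and split into near-equal-count chunks."""
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    ordered = sorted(spectra, key=lambda s: (neutral_mass(s), s.spectrum_id))
    n = len(ordered)
    base, extra = divmod(n, n_chunks)
    chunks: list[tuple[str, ...]] = []
    pos = 0
    for i in range(n_chunks):
        size = base + (1 if i < extra else 0)
        chunks.append(tuple(s.spectrum_id for s in ordered[pos:pos + size]))
        pos += size
    return SpectrumChunkPlan(tuple(chunks))


def _split_blocks(index: PeptideIndex, memory_cap: int) -> list[PeptideIndex]:
    """Slice an index into blocks of at most `memory_cap` entries."""
    if memory_cap < 1:
        raise ValueError("memory_cap must be >= 1")
    n = len(index)
    if n == 0:
        return []
    return [index.slice_block(i, min(i + memory_cap, n))
            for i in range(0, n, memory_cap)]


def _iter_prefetched(makers: Sequence[Callable[[], PeptideIndex]],
                     prefetch: bool) -> Iterator[PeptideIndex]:
    """Yield blocks, optionally preparing the next one in the background.

    The block sequence and hence the search result are identical whether
    or not prefetch is enabled; prefetch only overlaps preparation with
    the search of the current block.
    """
    if not prefetch:
        for make in makers:
            yield make()
        return
    with ThreadPoolExecutor(max_workers=1) as pool:
        future = pool.submit(makers[0]) if makers else None
        for i in range(len(makers)):
            block = future.result()
            future = (pool.submit(makers[i + 1])
                      if i + 1 < len(makers) else None)
            yield block


def _search_chunk(
    spectra: Sequence[Spectrum],
    blocks_or_makers: Sequence,
    proteins: Sequence[ProteinRecord],
    params: SearchParams,
    mode: str,
    mindex: ModificationIndex | None,
    prefetch: bool,
) -> list[PeptideSpectrumMatch]:
    """Search one spectrum chunk against every block; merge per spectrum."""
    makers = [b if callable(b) else (lambda blk=b: blk)
              for b in blocks_or_makers]
    per_spectrum: dict[str, list[PeptideSpectrumMatch]] = {
        s.spectrum_id: [] for s in spectra
    }
    for block in _iter_prefetched(makers, prefetch):
        for spectrum in spectra:
            try:
                if mode == "closed":
                    psms = search_spectrum_closed(
                        spectrum, block, proteins, params)
                else:
                    psms = search_spectrum_open(
                        spectrum, block, proteins, mindex, params)
            except Exception as exc:
                psms = [PeptideSpectrumMatch(
                    spectrum.spectrum_id, None, "", 0.0, 0, 0.0,
                    flag=f"error:{exc}")]
            per_spectrum[spectrum.spectrum_id].extend(psms)
    out: list[PeptideSpectrumMatch] = []
    for sid in sorted(per_spectrum):
        merged = per_spectrum[sid]
        # a spectrum failing against several blocks reports one error row,
        # keeping the table independent of the block count
        errors = {p.flag: p for p in merged if p.flag.startswith("error:")}
        merged = [p for p in merged if not p.flag.startswith("error:")]
        merged.sort(key=PeptideSpectrumMatch.rank_key)
        out.extend(merged[:params.top_k])
        out.extend(errors[f] for f in sorted(errors))
    return out


def parallel_search(
    proteins: Sequence[ProteinRecord],
    spectra: Sequence[Spectrum],
    params: SearchParams,
    digestion_params: DigestionParams | None = None,
    n_workers: int = 1,
    memory_cap: int | None = None,
    n_parts: int | None = None,
    mode: str = "closed",
    mindex: ModificationIndex | None = None,
    prefetch: bool = True,
) -> list[PeptideSpectrumMatch]:
    """Partitioned multi-process search; result equals the monolithic run.

    Parameters
    ----------
    n_workers : processes searching spectrum chunks (static assignment).
    memory_cap : maximum index entries per block (None = unlimited).
    n_parts : database partitions (default: ``n_workers``).
    prefetch : prepare the next index block while one is being searched.

    The merged PSM table — ordering included — is identical for every
    combination of ``n_workers``, ``n_parts``, ``memory_cap`` and
    ``prefetch``.
    """
    if mode not in ("closed", "open"):
        raise ValueError(f"unknown search mode: {mode!r}")
    if mode == "open" and mindex is None:
        raise ValueError("open search requires a modification index")
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if digestion_params is None:
        digestion_params = DigestionParams()
    if not spectra:
        return []
    plan = partition_by_amino_acids(proteins, n_parts or n_workers)
    blocks: list[PeptideIndex] = []
    for lo, hi in plan.parts:
        part_index = build_index(proteins[lo:hi], digestion_params)
        if memory_cap is None:
            if len(part_index):
                blocks.append(part_index)
        else:
            blocks.extend(_split_blocks(part_index, memory_cap))
    chunk_plan = sort_and_chunk_spectra(spectra, n_workers)
    by_id = {s.spectrum_id: s for s in spectra}
    chunk_spectra = [[by_id[sid] for sid in chunk]
                     for chunk in chunk_plan.chunks]
    results: list[list[PeptideSpectrumMatch]] = []
    if n_workers == 1:
        results.append(_search_chunk(
            chunk_spectra[0], blocks, proteins, params, mode, mindex,
            prefetch))
    else:
        ctx = mp.get_context("fork" if "fork" in mp.get_all_start_methods()
                             else None)
        with ProcessPoolExecutor(max_workers=n_workers,
                                 mp_context=ctx) as pool:
            futures = [
                pool.submit(_search_chunk, chunk, blocks, proteins, params,
                            mode, mindex, prefetch)
                for chunk in chunk_spectra
            ]
            for i, fut in enumerate(futures):
                try:
                    results.append(fut.result())
                except Exception as exc:
                    raise DistributedSearchError(
                        f"worker for spectrum chunk {i} failed: {exc}"
                    ) from exc
    merged = [psm for chunk_result in results for psm in chunk_result]
    merged.sort(key=lambda p: p.spectrum_id)
    return merged
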