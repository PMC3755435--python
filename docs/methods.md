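# Methods

This document describes the computational model implemented by
`openpepid`: what is computed, under which parameter conventions, which
numerical choices were made, and where the implementation deliberately
simplifies.

## Problem setting

Shotgun proteomics identifies peptides by comparing measured tandem
(MS/MS) spectra against candidate peptides derived from a protein
sequence database. For each spectrum, the precursor neutral mass is
inferred from the precursor m/z and charge; candidate peptides whose
mass lies inside a tolerance window around that mass are scored against
the observed fragment peaks, and the best-scoring peptide-spectrum
match (PSM) is reported.

`openpepid` implements this pipeline with three distinguishing design
points:

1. **Exhaustive nonspecific digestion** into a precomputed, mass-sorted
   peptide index, so candidate retrieval is a range query rather than
   an on-the-fly digestion.
2. **Two-stage open modification search**, which explains a precursor
   mass discrepancy as a post-translational modification by looking the
   mass difference up in a delta-sorted modification table.
3. **Residue-balanced partitioning** of the database plus mass-sorted
   spectrum chunking, so the same search distributes over multiple
   processes with a result guaranteed identical to the monolithic run.

## Masses and fragment model

- Residue monoisotopic masses are a frozen literal table (sourced
  numerically from `pyteomics.mass.std_aa_mass`) for the 20 canonical
  amino acids plus selenocysteine (U). Ambiguity codes (B, J, O, X, Z)
  are *undefined*: any peptide spanning one is skipped during digestion
  and counted in the digestion statistics.
- Peptide neutral mass = sum of residue masses + one water
  (18.0105646837 Da). Precursor neutral mass = charge × (m/z − proton),
  proton = 1.00727646677 Da.
- Theoretical fragments are singly charged b- and y-ions:
  `b_i = prefix_mass(i) + proton`, `y_i = suffix_mass(i) + water +
  proton`. The identity `b_i + y_(n−i) = M + 2·proton` holds to
  1e-6 Da and is tested exhaustively.
- A modification is modelled as a single mass delta attached to one
  0-based residue position; it shifts every b-ion whose prefix contains
  the site and every y-ion whose suffix contains it.

Mass arithmetic is float64 throughout. Prefix-mass arrays use NaN
poisoning for undefined residues: a NaN propagates through the
cumulative sum, so every window spanning the residue is detected in
O(1) without per-window checks.

## Digestion and the peptide index

Three digestion semantics share one parameter set (length window
3–60 residues, mass window 300–8000 Da, both inclusive, by default):

- **nonspecific**: every substring inside the windows;
- **specific**: both termini at enzymatic boundaries (trypsin rule:
  cleave after K/R except before P), at most `max_missed_cleavages`
  internal sites;
- **semispecific**: at least one enzymatic terminus, same missed-
  cleavage budget.

The peptide sets form a containment chain (specific ⊆ semispecific ⊆
nonspecific under identical filters), which is tested. For nonspecific
digestion the entry count has the closed form Σ_L Σ_k (L−k+1), used as
a conservation oracle.

The index stores, for every peptide occurrence, the triple
(protein_id, start, length) as three `uint32` values (12 bytes) plus a
float64 mass (8 bytes) — a constant 20 bytes per record — sorted by
mass with ties broken by the triple, so builds are deterministic and
byte-reproducible. A bucket table of 1-Da integer mass bins stores the
first index position per bin; a range query jumps to the bucket and
bisects within it, then bisects for the window end. Queries are
verified against linear scans.

Serialization is a single binary file: fixed header (magic, version,
counts, bucket base), a JSON blob of digestion parameters and the
database fingerprint (SHA-256 over accessions and sequences), then the
three arrays. Loading verifies magic, version, and exact file size;
round trips are bit-exact.

## Closed and open search

**Closed search** retrieves all indexed peptides inside the precursor
tolerance window (default 10 ppm) and scores each against the spectrum.
Scoring pairs each theoretical fragment with at most one observed peak
(greedy nearest-m/z within the fragment tolerance, default 0.02 Da);
the score is `matched_peaks + matched_intensity / (total_intensity +
1e-9)` — the integer part dominates, the fractional part (< 1 by
construction) breaks ties toward explained intensity. Remaining ties
break deterministically on (|precursor delta|, protein, start, length).

**Open search** proceeds in two stages:

1. *Anchoring*: candidates are retrieved in the widened window
   [M − 500, M + 200] Da (the delta range reversed: a modification of
   +delta makes the *observed* mass larger than the peptide mass).
   Each candidate is scored with its unmodified fragment ladder;
   candidates with fewer matched peaks than `min_matched_peaks` are
   discarded. A vectorized prefilter computes an upper bound on the
   matched-peak count for the whole candidate window at once; because
   it is an upper bound, discarding below the threshold never changes
   the result (verified by brute-force equality tests).
2. *Delta explanation*: the residual `delta = observed − peptide mass`
   is looked up in the modification index (29 shipped modifications,
   sorted by delta, 1-Da buckets, match tolerance 0.01 Da). Every
   returned modification is tried at every compatible site (residue
   letters and peptide/protein terminus specifiers), rescoring with
   the shifted ladder; the best (score, |delta − mod delta|, mod, site)
   wins. A delta matching nothing in the table keeps the unmodified
   score and is flagged `unexplained-delta`. A delta within the match
   tolerance of zero competes as an unmodified PSM.

## Distribution

- The database is split into contiguous parts balanced by residue
  count: a greedy pass closes each part at the prefix nearest its share
  of the remaining residues, a refinement sweep moves boundary proteins
  between adjacent parts while that reduces imbalance, and — only if
  the spread still exceeds the longest single protein, which can happen
  on small adversarial length profiles — an exact reachability search
  over prefix sums finds a partition whose part totals all fit in a
  window of that width. The resulting invariant, max − min residue
  total ≤ longest protein length, is property-tested.
- Each part's index is further sliced into blocks of at most
  `memory_cap` entries, bounding the per-round working set.
- Spectra are sorted by precursor neutral mass and split into
  near-equal chunks assigned statically to worker processes, so each
  worker touches a narrow slice of the mass-sorted index. While a block
  is searched the next one can be prepared concurrently (prefetch);
  prefetch changes scheduling only, never results.
- Per spectrum, the union of per-block top-k lists is re-ranked with
  the global tie-break chain. Because blocks partition the index, this
  reproduces the monolithic top-k exactly: the merged PSM table is
  byte-identical for every (workers, parts, memory cap, prefetch)
  combination. This transparency is the central correctness property
  and is tested end to end.

## Synthetic benchmarks

`simulate_benchmark` generates a seeded random protein database, plants
peptides (7–25 residues, charge 2+/3+), optionally applies one
modification from the shipped table at a compatible site, and emits
noise-free spectra by default (dropout and noise peaks are opt-in
knobs). Ground truth is written as a TSV. All randomness flows from
`numpy.random.default_rng` seeded from a single integer; derived seeds
stay below 2^31.

Recovery is measured by rank-1 peptide *sequence* equality: isobaric
residues (I/L) and repeated substrings make occurrence-level identity
undecidable from mass spectra alone.

## Numerical and design choices

- Inclusive range-query upper bounds are implemented with
  `nextafter(hi, +inf)` so floating-point equality at the window edge
  is included deterministically.
- The score's intensity fraction divides by `total + 1e-9`, keeping the
  fraction strictly below 1 even for a fully matched spectrum, so "more
  matched peaks always wins" is exact.
- `build_index` sorts in memory only. For databases beyond memory, the
  distribution path (partition → per-part index → bounded blocks)
  provides the same result with bounded working sets, so a separate
  external-merge build path was deliberately omitted.
- FASTA parsing is hand-rolled (~40 lines) to give line-numbered errors
  for malformed input; MGF reading uses `pyteomics.mgf` with a pre-scan
  for unterminated blocks, and MGF writing is a small direct emitter
  for deterministic formatting.

## Limitations

- Only singly charged b/y fragments are modelled; no neutral losses,
  isotopes, or higher fragment charges.
- At most one modification per peptide in open search.
- The scorer is a shared-peak count with an intensity tie-break, not a
  probabilistic model; no false-discovery-rate estimation is included.
- The shipped modification table is a small curated subset, not a full
  Unimod mirror.
- Parallelism is multi-process on one machine; no cluster scheduler.
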