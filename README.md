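# openpepid

Open protein identification over a mass-sorted peptide index.

`openpepid` identifies peptides from tandem mass spectra by searching a
protein sequence database. It digests the database exhaustively
(every substring inside configurable length and mass windows) into a
compact, mass-sorted index of `(protein, start, length)` records, so
candidate retrieval for a spectrum is a range query instead of an
on-the-fly digestion. On top of that index it provides:

- **Closed search** — candidates within a precursor tolerance window
  (default 10 ppm), scored by shared b/y fragment peaks.
- **Open modification search** — a two-stage search that first anchors
  candidates in a widened mass window with their unmodified fragment
  ladders, then explains the residual precursor mass difference as a
  post-translational modification by looking the delta up in a shipped,
  delta-sorted modification table, localizing it to the best-scoring
  compatible site.
- **Transparent parallelism** — the database is partitioned into
  residue-balanced contiguous parts, indexes are sliced into
  memory-bounded blocks (with optional block prefetch), and spectra are
  mass-sorted and chunked across worker processes. The merged result is
  guaranteed byte-identical to the single-process, single-block run for
  every combination of workers, partitions, and memory cap.

See [docs/methods.md](docs/methods.md) for the computational model and
design choices.

## Worked example

Generate a seeded synthetic benchmark (20 proteins, 50 spectra, 30%
carrying one planted modification), build the index, and search in open
mode:

```sh
openpepid simulate --seed 42 --n-proteins 20 --n-spectra 50 \
    --modified-fraction 0.3 \
    --out-fasta db.fasta --out-mgf run.mgf --out-truth truth.tsv

openpepid build --fasta db.fasta --out db.idx
# entries       226767
# mass_bin_0    6793
# mass_bin_500  18691
# ...

openpepid search --mgf run.mgf --index db.idx --fasta db.fasta \
    --search-mode open --out psms.tsv
```

`psms.tsv` holds the top 5 PSMs per spectrum. The rank-1 line for the
first spectrum:

```text
spectrum_id     peptide                    protein            start length score     matched_peaks precursor_delta mod_id  mod_site
bench_42_00000  VDIYYCHTLWRCMICIAMWLHICDH  syn|191664964|15   21    25     49.000000 48            0.000001        phospho 5
```

All 48 b/y fragments matched, the +79.966 Da precursor delta was
explained as a phosphorylation at residue 5, and comparing rank-1
peptides against `truth.tsv` recovers 50/50 planted peptides. Runner-up
PSMs that cannot explain their delta from the modification table are
flagged `unexplained-delta`.

The same search distributes without changing a byte of the output:

```sh
openpepid search --mgf run.mgf --index db.idx --fasta db.fasta \
    --search-mode open --out psms_par.tsv \
    --workers 4 --parts 3 --memory-cap 50000
cmp psms.tsv psms_par.tsv   # identical
```

`openpepid partition-info --fasta db.fasta --parts 4` shows the
residue-balanced partition plan; `openpepid index-stats --index db.idx`
summarizes a stored index (entry count, mass histogram, fraction of
peptides at or below a mass threshold).

## Python API

```python
from openpepid import (
    DigestionParams, SearchParams, build_index, default_mod_index,
    read_fasta, read_mgf, search_batch,
)

proteins = read_fasta("db.fasta")
index = build_index(proteins, DigestionParams())
spectra = read_mgf("run.mgf")
psms = search_batch(spectra, index, proteins, SearchParams(),
                    mode="open", mindex=default_mod_index())
```

## Testing and reproduction

```sh
python -m pytest -q tests/                 # unit + property + acceptance
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script runs the full pipeline on seeded synthetic
benchmarks and reports the headline quantities (digestion count
conservation, range-query equivalence against linear scans, closed and
open rank-1 recovery, modification identity and site accuracy,
parallel-vs-monolithic table identity, fragment-series complementarity
error). All randomness derives from the single `--seed`; repeated runs
are bit-reproducible.
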