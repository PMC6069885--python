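# Methods

## Problem and approach

Protein homology search asks: given a query sequence and a database of
proteins, which database proteins share ancestry with the query?  Exhaustive
Smith–Waterman comparison is exact but scales linearly with the database.
This package retrieves candidates with a *suffix array neighbourhood search*
(SANS) and verifies only the candidates, in four stages:

1. **Index.** All database proteins are concatenated into one text `T`,
   each followed by a `*` delimiter, and a suffix array `SA` is built over
   `T` under a configurable collation order of the 25-symbol amino-acid
   alphabet (20 standard residues, B, Z, X, J, `*`).
2. **Retrieval (asymmetric SANS).** Every query suffix `Q[i..]` of length
   ≥ `min_suffix` is located in `SA` by binary search.  Two *frontiers* per
   suffix (one on each side of the insertion point) compete in a global
   priority queue keyed by a *scored seed*: the maximum gapless prefix
   alignment score between the query suffix and the database suffix at the
   frontier,  max over n of  Σ_{i=1..n} M(Q[i], T[SA[k]+i]).  Until the
   global vote budget `V` (`--seeds`) is spent, the best frontier pops, the
   protein owning its suffix gets one vote, and the frontier advances one
   array position, is re-scored and re-queued.  High-similarity regions of
   the array therefore absorb most of the budget; suffixes surrounded by
   dissimilar text may contribute nothing.
3. **Verification.** The `N` (`--alignments`) most-voted proteins are
   aligned to the query with affine-gap Smith–Waterman; raw scores become
   bitscores and E-values via Karlin–Altschul statistics
   (`bits = (λS − ln K)/ln 2`, `E = m·n·2^−bits`).
4. **Report.** Hits with `E ≤ evalue_max` are sorted by bitscore and the
   top `H` (`--max-hits`) are emitted in 12-column BLAST tabular format.

The classic fixed-window SANS (`symmetric_sans`) is retained as a baseline:
it is the limiting case of the asymmetric search when the seed score is a
constant, a relationship the test suite checks directly.

## Collation order

Lexicographic collation puts dissimilar residues next to each other
(e.g. C and D score −3 under BLOSUM62), scattering homologous suffixes.
The shipped default ordering `ACMLJIVTSKRQZEDBNHYFWXP*G` minimises the
summed *quasi-distance* `d(a,b) = −score(a,b) + 5` (`d(a,a) = 0`) between
cyclically adjacent symbols.  Finding such an ordering is a 25-city TSP;
the package provides an exact Held–Karp solver (≤ 18 symbols, the bitmask
DP memory bound) and a 2-opt/Or-opt multi-restart heuristic for the full
alphabet.  Many tours are co-optimal, so orderings are compared by cycle
cost, never by string.  Under this package's matrix conventions the
shipped ordering's cycle costs 100 and the heuristic reaches 98 (the
lexicographic cycle costs 161); any ordering of equal or lower cost is an
equally valid collation.

## Matrix conventions

BLOSUM62 is taken from the canonical NCBI table (24 symbols).  J (I-or-L
ambiguity) is synthesised as the truncated-toward-zero mean of the I and L
rows, giving J/J = J/I = J/L = 3, the common extended-matrix convention.
`*` scores −4 against everything and +1 against itself.  U and O normalise
to X on input; lowercase is uppercased.  External matrices in NCBI text
format are accepted but must cover the same symbol set.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `--seeds` (V) | 300 000 | global vote budget per query; `--fast` preset 100 000 |
| `--alignments` (N) | 5 000 | voted candidates passed to alignment; fast preset 1 500 |
| `--max-hits` (H) | 1 000 | hits reported per query |
| `--evalue` | 1.0 | E-value cutoff |
| `--min-suffix` | 8 | shortest query suffix fed to the engine; shorter suffixes give uninformative insertion points |
| gap open / extend | 11 / 1 | BLAST protein defaults; a length-g gap costs 11 + g |
| λ, K | 0.267, 0.041 | published gapped Karlin–Altschul parameters for BLOSUM62 11/1 |
| SEG window / locut / hicut | 12 / 2.2 / 2.5 | canonical SEG defaults |

Search space for E-values is raw `m·n` (query length × database residues,
delimiters excluded) with no finite-size edge correction — a documented
divergence from BLAST that shifts E-values slightly conservative for short
sequences.

## Masking

Queries (never the database) are masked with a SEG-style trigger-and-extend
entropy filter before seed scoring: a maximal run of length-12 windows with
Shannon entropy < 2.5 bits is masked in full if it contains a trigger
window < 2.2 bits.  SEG's second refinement stage (minimal-probability
subsequence trimming) is omitted; it only adjusts segment margins.  Masked
positions contribute 0 to seed scores; they are not removed, and alignment
verification sees the unmasked sequence.

## Determinism, ties and degenerate inputs

* Frontier ties break first-in-first-out via a monotone insertion counter,
  making retrieval deterministic and giving the exact round-robin symmetric
  limit under a constant score.
* Suffix-array positions whose suffix begins with `*` carry no residue:
  frontiers step over them without voting and without spending budget;
  the fixed-window baseline skips them without replacement.
* Candidate ties: equal vote counts break by protein ordinal; equal
  bitscores break by E-value then subject ordinal.
* Co-optimal alignments: the aligner's first traceback is reported (score,
  identity count and E-value are invariant across co-optimal paths).
* Queries shorter than `min_suffix` produce no candidates and no output
  rows; `--seeds 0` is a valid degenerate budget.
* The suffix array is built by numpy prefix doubling (`O(n log² n)`), exact
  under arbitrary collation orders; positions are 64-bit throughout.

## Index file

Versioned binary: magic `TOPAZIDX`, format version, section lengths, JSON
metadata (ordering string, matrix name, protein ids, boundary offsets),
rank-encoded text (uint8), suffix array (little-endian int64), SHA-256
checksum over everything preceding it.  Loads verify magic, version and
checksum and fail with an instruction to rebuild.  An index answers
searches only under its recorded ordering; a mismatched matrix name is an
error in the CLI.

## Synthetic benchmarks

`random_proteome` draws i.i.d. sequences from the BLOSUM62 background
residue frequencies; `mutate_homolog` substitutes exactly
`⌈(1−identity)·len⌉` positions, sampling replacements from the
BLOSUM62-conditional preference `P(b|a) ∝ p_b·2^{score(a,b)/2}` with
identity excluded, so planted pairwise identity is exact.
`benchmark_set` plants homolog families at graded identities (default
0.9/0.7/0.5, three homologs per level per query) inside a decoy proteome.
Everything is deterministic per seed.

These fixtures emulate composition and graded divergence only: no domain
architecture, no realistic indel patterns (indels are optional and
default-off so identity accounting stays exact), no genuine low-complexity
regions, and desk-scale sizes (decoy databases of 500–5 000 proteins of
50–120 residues; real proteomes are larger in both dimensions).  Passing
tests therefore demonstrate correctness of the machinery and recovery of
planted homology under matrix-consistent mutation — not field sensitivity
on real databases.

## Known limitations

* Database-side low-complexity regions are not masked.
* No composition-based score adjustment, X-drop heuristics or translated
  search.
* The heuristic TSP solver guarantees only local optimality per restart;
  the exact solver is capped at 18 symbols.
* E-values use raw search-space size; very short queries are penalised
  relative to BLAST's edge-corrected statistics.
* Parallelism is across queries only (deterministic output by design); a
  single long query does not speed up with threads.
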