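# Methods

This note documents the model behind `memcorrect`, the parameters that
matter, the numerical and design choices made where the design was open, and
what the synthetic-data tests do and do not demonstrate.

## Model and assumptions

The corrector assumes two read populations over the same genome:

* **short reads** — accurate (ideally pre-corrected) reads of ~100–250 bp at
  high coverage. They are only used to build the de Bruijn graph, so their
  per-base quality directly bounds the quality of every corrected base.
* **long reads** — noisy reads whose errors are approximately uniform along
  the read (the SMRT regime), with a total rate around 15% dominated by
  insertions. Systematic or clustered error profiles (e.g. homopolymer-biased
  nanopore errors) violate the uniformity assumption that both the seed
  statistics and the gap windows rely on.

Correction never invents sequence: every output read is the spelling of a
connected path in the cleaned graph (re-threading this is part of the test
suite). Consequently the corrector can only be as complete as the graph — a
coverage gap in the short reads splits the output into pieces rather than
bridging the gap with read bases.

## Graph construction and cleaning

Canonical k-mers (lexicographic minimum of k-mer and reverse complement) are
counted with multiplicity; unitigs are compacted maximally; arcs connect
node ends overlapping by k−1 bases *and* supported by an observed
(k+1)-mer. The second condition matters: overlap alone creates spurious
"ghost" arcs between a k-mer and the neighbourhood of its own reverse
complement, which would fragment unitigs. Hairpin fold-backs (a unitig
continuing into its own reverse complement) are spelled through, and arcs at
palindromic nodes are normalised to the '+' orientation, since a
self-reverse-complementary node has indistinguishable orientations.

Cleaning removes the two artifact classes isolated substitution errors
create: **tips** (dead-end nodes of length ≤ 2k with coverage ≤ 0.5× the
adjoining path) and **bubbles** (the weaker of two parallel single-node
branches sharing both endpoints, at the same 0.5 coverage ratio; ties are
never popped). Tip clipping and bubble popping alternate with recompaction
until a fixpoint (at most 10 rounds); cleaning is idempotent and only ever
deletes k-mers. A build-time abundance floor (default 2 in the pipeline, 1
for the bare `build_graph` function) suppresses chimeric links; no further
chimera-specific rule is applied, so rare spurious connections can survive —
a known limitation.

Choice of k: the `connectedness_report` compares graphs by the fraction of
bases in their largest component; among similarly connected graphs the
largest k is preferred (fewer unresolved repeats).

## Seed statistics

With i.i.d. per-base error rate p (treating all errors as substitutions),
the run of correct bases between errors is geometric, giving

* expected coverage of a read by exact regions of size ≥ m:
  `(1−p) − Σ_{k=0}^{m−1} k(1−p)^k p²` (exact for the infinite-read model;
  Monte Carlo at n=10000 agrees to ~5·10⁻⁴, the residual being read-boundary
  truncation);
* expected longest run: the root of `np(1−p)^m = 1`, i.e. `−log_{1−p}(np)`;
* probability of a run ≥ m: `1 − exp(−np(1−p)^{m+1})` (Gumbel tail).

Two caveats, both verified by simulation in the test suite and deliberately
left as-is:

1. The Gumbel form carries an origin shift: the exponent `(1−p)^{m+1}`
   undercounts run starts by one factor of (1−p), so the formula sits below
   the empirical probability by up to ≈0.05 near its transition (e.g.
   n=10⁴, p=0.15, m=45: formula 0.572 vs simulated 0.627±0.009; the
   unshifted exponent m matches simulation). Likewise the longest-run root
   approximates the Gumbel *mode*; the empirical mean is γ/|ln(1−p)| ≈ 3–5
   bases higher. These forms are used as conservative guides (a lower bound
   on seed availability), so the bias is harmless for seed-length selection
   but should not be mistaken for a calibrated probability.
2. With insertions and deletions, true exact regions are longer than the
   substitution-only model predicts (an indel can let a match continue),
   so realized MEM coverage is at least the closed form — again the
   conservative direction.

`recommend_seed_length(n, p, target)` inverts the Gumbel form: the largest m
whose seed probability still reaches the target.

## Alignment and correction parameters

| parameter | default | meaning |
| --- | --- | --- |
| `dbg_k` | 75 | graph k-mer size (bases); decoupled from `min_mem` |
| `min_mem` (l) | 20 | minimum MEM seed length (bases) |
| `max_passes` (p) | 5 | chaining passes over unaligned regions |
| `output_mode` | short | clip to read extent vs maximal linear extension |
| `insertion/deletion/substitution_rate` | 0.09/0.045/0.015 | estimated long-read error decomposition |
| `sparseness` | 1 | suffix-array sampling interval |
| `min_abundance` | 2 | k-mer floor at graph build |
| `coverage_ratio` | 0.5 | tip/bubble coverage-ratio threshold |
| `cover_safety` | 0.5 | safety factor on the expected-coverage filter |

Numerical conventions, chosen where no canonical rule exists:

* **Gap windows.** The read-side gap n and graph-side (spelled) gap L must
  satisfy `(1+2i)⁻¹n − ε ≤ L ≤ (1−2d)⁻¹n + ε` with additive
  slack `ε = max(10, 0.05·n)`. Insertions shrink the graph-side distance,
  deletions stretch it; the factor 2 gives roughly two standard deviations
  of headroom on top of the mean shift.
* **Seed compatibility** uses the same window on inter-seed gaps, and
  requires consistent ordering on read and node.
* **Mapping plausibility.** A chained mapping is dropped when its matched
  bases fall below `cover_safety ×` the expected coverage by exact regions
  of size ≥ l. The denominator is the node extent the mapping could
  plausibly reach, `min(node length, read span/(1+2i))`: for nodes shorter
  than the read this is the whole node (absence of seeds elsewhere in the
  node is evidence against the mapping); for long unitigs it reduces to
  read-relative coverage, since a 10 kb read cannot be expected to cover a
  100 kb node.
* **Noise floor.** A chain must carry at least `max(l_used, min_mem)`
  matched bases; this keeps single short seeds found after an adaptive-l
  retry from spawning junk output on non-genomic sequence.
* **Adaptive seed length**: fewer than 2 seeds lowers l by 3 (floor 2), more
  than 20 seeds per 100 read bases raises it by 3; at most 3 retries.
* **Ambiguity and global context.** Competing overlapping mappings within
  20% of each other's weight are deferred to a later pass unless one of them
  touches (shares a node or an arc with) an already-accepted neighbouring
  alignment; on the final pass the heavier mapping wins, ties broken by
  fewer path nodes, then lexicographically smallest node-id path.
* **Shortest path / cycle search** is uniform-cost on spelled length with
  expansion capped at the window's upper bound; cycles are found by
  searching from the junction back to itself and may be inserted repeatedly
  (bounded) to fill a too-short joint.
* **Short-mode clipping** uses the midpoint of the admissible extent,
  `overhang · ((1+2i)⁻¹ + (1−2d)⁻¹)/2`, beyond the extremal seeds; long mode
  follows strictly unique arcs outward without re-entering the path.
* **Split output** pieces are named `<read id>/<piece index>` in read order;
  their claimed read intervals never overlap. No minimum output length is
  imposed.

## MEM index

The catalog concatenates every node forward and reverse-complemented with
sentinel separators that never match a base (so no seed crosses a node
boundary); '−'-strand seed coordinates refer to the reverse-complemented
node sequence. The suffix array is built by prefix doubling and sampled
every s positions; queries match every read suffix against the sampled
array with threshold l−s+1 and extend maximally, reporting each MEM exactly
once (at its first sampled position). A MEM shorter than s can contain no
sampled suffix at all — a structural blind spot of text-sparse suffix
arrays — so for l < s the index falls back to an exact packed-l-mer scan of
the text against the read's l-mer table. Results are therefore independent
of s; only memory (∝ 1/s) and query time change. Hot loops are
JIT-compiled with numba.

## Synthetic data

The simulator emulates the study conditions: i.i.d. random genomes
(GC 0.5), uniformly placed error-free (or substitution-noised) short reads
on both strands, and long reads with per-emitted-base errors at 15% total,
split 60/30/10 into insertions/deletions/substitutions, lognormal lengths
(mean 10 kb, sd 2 kb, truncated to [100, genome length]), linear genomes
without wraparound. Truth intervals (reference span, strand, true error
counts) accompany every read. Under this model the raw reads align to the
genome at ≈86.5% identity.

What the fixtures do *not* emulate: real repeat structure (random genomes
are essentially repeat-free at k=75, so the cleaned graph is a single
unitig and path search is rarely stressed beyond constructed fixtures),
position-dependent short-read error profiles, quality scores, and
paired-end structure. Passing the end-to-end tests therefore demonstrates
the machinery is correct under the stated error model, not that the
defaults are optimal for repeat-rich genomes.

## Evaluation

Corrected reads are placed on the reference by unit-cost edit distance
(edlib), read-global/reference-local, strand chosen by edit distance (ties
prefer forward), and kept at ≥70% identity. Identity is matches over
alignment columns. Accuracy and gain aggregate base-weighted totals (not
unweighted per-read means); "aligned" uses corrected-read bases as the
denominator; throughput is corrected over input bases; Nx follows the
descending-cumulative-sum definition. Problem sizes in the acceptance runs
(100 kb genome, 500 reads; 50 kb perfect-graph genome, 200 reads; 10⁵
Monte-Carlo reads) were chosen as the smallest scales at which the binomial
noise on every reported percentage is well below the margins being checked.

## Known limitations

* Chimeric links that survive the abundance floor are not otherwise
  detected; on repeat-rich genomes the ambiguity deferral is the only
  guard against mis-joins.
* `long` output mode can chain through junctions that the read itself does
  not support, with a small risk of manufactured chimeras (inherent to
  maximal linear extension).
* The theory module is substitution-only by construction; its guidance is
  conservative for indel-dominated data (see caveats above).
* Read ends without seeds are estimated, not aligned: the clipping length
  is a model-based guess with ≈±13% spread at the default rates.
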