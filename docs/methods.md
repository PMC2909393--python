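# Methods

## Distance model

All clustering operates on *quickdist*, the normalized pairwise distance

    d = (substitutions + indel differences) / alignment length

computed on an optimal global alignment under affine gap costs
(gap open 5.75, extend 2.75, match +5, mismatch −4; a gap run of length
L costs `open + (L−1)·extend`). Two conventions needed fixing where
common usage is ambiguous:

* **Indel counting.** A maximal run of gap columns counts as *one*
  difference, in both quickdist and the per-read error rate — an
  insertion or deletion of any length is one event. The flag
  `gap_per_column=True` restores per-column counting for comparison
  with tools that use it.
* **Terminal gaps.** With `end_gaps_free` (the default) terminal gap
  runs are excluded from both the numerator and the alignment length,
  and they are score-free during alignment (semi-global). Amplicons of
  unequal natural length (V6 regions range from ~57 to ~145 nt) would
  otherwise accrue distance for length alone. Consequence: an error in
  the first or last base of a read can be absorbed into a free terminal
  gap and go uncounted; at the error rates involved this is negligible.
  A fully-overhanging alignment with no aligned columns after trimming
  is reported as distance 1.0.

Traceback ties prefer diagonal, then up, then left, and each pair is
aligned in canonical (lexicographic) order, so `d(a, b) == d(b, a)`
exactly. Alignment scores are verified in the test suite against
Biopython's independent `PairwiseAligner` and against exhaustive
enumeration on short strings.

The per-read **error rate** aligns a read to every template in a pool,
takes the template minimizing the event count, and normalizes by the
*template* length (not the alignment length).

## Sparse distances and the k-mer prescreen

Only distances at or below a cutoff are stored. Before aligning, pairs
are screened with a k-mer multiset distance, `1 − shared/min` (k = 6,
prescreen cutoff 0.5): pairs above the prescreen cutoff are skipped.
These defaults are deliberately conservative for a 3% target — the test
suite checks on dense variant clouds that no sub-cutoff pair is lost —
and the prescreen can be disabled. Kernels are numba-compiled;
~6 million candidate alignments of 60-nt pairs take well under a minute
on one CPU.

## Threshold clustering

`ThresholdClustering` cuts a scipy agglomerative tree (single, average
or complete linkage) at a closed threshold: merges with linkage value
≤ threshold happen. Pairs absent from the sparse set enter the dense
matrix as distance 1.0. For single and complete linkage this is
equivalent to "farther than any threshold in use"; for average linkage
it is an approximation that is exact whenever clusters stay within the
sparse cutoff radius, and biases means upward (toward fewer merges)
otherwise.

`mothur_rounding=True` rounds merge heights to the nearest whole
percent (half up) before the cut, mimicking clustering tools that round
distances when defining clusters. On 60-nt reads this is consequential:
two differences give d = 0.0333, which rounds to 3% and therefore still
merges at a 3% threshold. When rounding is on and distances are
computed internally, the sparse cutoff is widened to `threshold + 0.005`
so every distance that rounds into range is actually present;
otherwise the flag would be inert for exactly the distances it is meant
to admit.

Merge order ties inside scipy are resolved deterministically by its
implementation; OTUs are finally ordered by total count (ties by
representative sequence), making output stable across runs and
platforms.

## Single-linkage preclustering (SLP)

SLP assumes template sequences occur more often than any of their
error-induced variants. Unique sequences are sorted by count (ties
broken lexicographically — the sort must be a total order for
reproducibility; unsorted input is rejected because the order is part
of the algorithm).

* **Pass 1.** The most abundant sequence seeds cluster 1. Each
  subsequent sequence joins the first-created cluster containing any
  member at distance strictly below the width (default 0.02, one
  difference on a 60-nt read — the narrowest width usable on such
  tags); otherwise it seeds a new cluster. Clusters are never merged:
  a sequence within the width of several clusters joins the
  first-created one, which, because clusters are created in abundance
  order, is the one anchored by the most abundant sequences.
* **Pass 2.** Clusters with fewer than 10 reads are tested, in
  descending total-count order, against the larger clusters (same
  order) and absorbed into the first with any member within the width.
  One pass only; totals, orderings and representatives are frozen at
  the start of the pass, so absorption does not cascade. The pass
  exists because a small cluster can form before the larger cluster
  acquires the member that links them.
* **Representatives.** Each precluster is represented by its
  highest-count member (ties: lexicographically smallest sequence),
  which enters the final clustering with weight one while carrying the
  precluster's total read count into OTU totals.

The final stage clusters representatives at 3% (average linkage by
default — the SLP/PW-AL method). One sparse-distance computation at the
final width serves both stages, so chains that pass 1 builds beyond the
precluster width remain visible to the final clustering.

Known, intended behavior: two genuine templates closer than the
precluster width merge in pass 1. At a 3% final threshold they would
fall into one OTU under any linkage rule, so the OTU-level result is
unchanged.

Both widths are configurable (`SLPConfig`), since the appropriate
precluster width scales with tag length.

## Filters

Read filters run in a fixed order — ambiguous bases, exact barcoded
forward primer, mean quality ≥ 30, reverse primer — so each rejected
read gets one deterministic reason code. Decisions taken where
conventions vary:

* "Recognizable reverse primer" means at most `reverse_max_mismatch`
  (default 1) substitutions against the read's 3′ end; only the forward
  primer requires an exact match.
* Mean quality is computed over the full read before trimming by
  default (`quality_after_trim` switches this).
* The coverage filter approximates a BLAST-style span on the global
  alignment: columns are rescored with blastn-like local parameters
  (+1/−2, gap 5/2) and the maximum-sum contiguous window located; the
  query bases inside that window must cover ≥ 80% of the read.
* Contamination: a sequence is removed when its best non-target
  identity (1 − quickdist) exceeds its best template identity by an
  absolute margin of 0.10. The margin is absolute, not a ratio, because
  fractional identities make a ratio ill-defined near zero.
* Chimera removal is not automated (on real data it was done by
  inspection); only exact matches to user-supplied chimera sequences
  are flagged.

## Read simulator

`simulate_templates` draws random template pools by rejection sampling
until all pairwise quickdists meet a floor (default 0.06 — twice the
OTU threshold, so templates are unambiguously distinct taxa at 60 nt).
`simulate_reads` samples a template per read and applies per-base
substitutions and indel events (indel lengths geometric(0.5), capped at
5; no published length model exists for these data, and results are
insensitive to the cap because indel events are counted once
regardless of length). Default rates — substitution 0.0025, insertion
0.00025, deletion 0.00025 — sum to the 0.003 per-base midpoint of
measured amplicon pyrosequencing error, with indels a minor component
as expected for a low-homopolymer target. A `heavy_fraction` (default
1%) of reads multiplies all rates by 10, reproducing the observed
excess of reads with ≥ 3 errors over the binomial expectation (the
instrument's out-of-phase-bead failure mode): the simulated excess is
~3.7×, close to what defined template pools show. Qualities are
emitted as a constant 35 so simulated reads pass the quality filter
unless configured otherwise. A single generator seeded from one seed
drives each run; ground truth (source template, event count, heavy
flag) is recorded per read.

**What the generator does not emulate — and what that implies.** Errors
are independent across reads and positions. Real pyrosequencing error
recurs at specific positions (homopolymer tracts), so on real data many
multi-error reads share errors with abundant 1–2-error variants and
chain into their template's precluster; with independent errors nearly
every ≥ 2-error sequence is unique and has no chaining partner. Two
measurable consequences on simulated pools, both visible in
`scripts/acceptance.py` output:

1. The SLP/PW-AL spurious-OTU rate is ~12 per 1000 reads, an order
   above the ~1–2 per 1000 seen on defined real template pools —
   passing or failing this simulation therefore bounds the method's
   behavior under *worst-case uncorrelated* noise, not its real-data
   rate.
2. Average and complete linkage give nearly identical counts at 60 nt
   with percent rounding (any two 1-error variants of one template are
   2/60 = 3.33% apart, which rounds to 3%, so complete linkage merges
   them too); the large real-data gap between PW-AL and PW-CL comes
   from variant pairs that round above 3%, e.g. 2/57 = 3.5% on shorter
   tags, and from length diversity the fixed-length simulation lacks.

Error-free simulations recover template counts exactly under all
methods, and the binomial shape of the error-count distribution (heavy
tail off) is verified bin by bin at 3σ.

## Evaluation

`count_spurious` credits an OTU to a template when the OTU's
representative lies within the clustering width of it; matching is
greedy by OTU abundance and each template is claimable once (real
studies judged this by inspection; an automatic rule is needed here).
Everything unclaimed is spurious. `depth_curve` subsamples reads
without replacement (fresh generator per depth/replicate, spawned from
the master seed), reruns the full pipeline and averages spurious counts.
`compare_methods` re-fits cloned estimators so identical configurations
provably give identical rows.

## Problem sizes and defaults in the test suite

Tests and the acceptance script run desk-scale versions of the defined
template experiments: 43 templates of 60 nt at ≥ 6% spacing, 20 000
reads for the deep noisy pool, 10 000 reads for error-rate and
binomial checks, 2000-read pools for property tests. These sizes keep
the statistical structure (thousands of unique sequences, a populated
multi-error tail) while the full run completes in about a minute.

## Known limitations

* Average linkage over sparse distances treats missing pairs as 1.0
  (exact only within the cutoff radius).
* The simulator has no error hotspots, no chimera generation, no
  flowgram-level model and fixed read length; spurious-OTU rates from
  it are conservative upper bounds (see above).
* The coverage filter is an approximation of a local-alignment search,
  not a database search; with very short homologous cores it can
  prefer `no_reference_match` (no shared k-mer) over `low_coverage`.
* SFF flowgrams and paired-end reads are out of scope.
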