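# slpotu

OTU calling for short hypervariable-region amplicon reads (pyrotags),
built around **single-linkage preclustering (SLP)**.

## The problem

Deep amplicon sequencing of rRNA hypervariable regions (e.g. the ~60-nt
16S V6 region) detects very-low-abundance community members — but it
also inflates richness estimates. Even at a per-base error rate of
~0.003, a large read set inevitably contains reads with several errors.
A read that differs from its template at two positions can sit within 3%
of the template yet more than 3% from other errant reads of the same
template, so the common recipe of multiple-sequence alignment plus
complete-linkage clustering splinters one true template into many
operational taxonomic units (OTUs), inflating the apparent "rare
biosphere".

## The method

For unique sequences $u_1, u_2, \dots$ sorted by read count
$c_1 \ge c_2 \ge \dots$ and a pairwise distance

$$d(u_i, u_j) \;=\; \frac{\#\text{substitutions} + \#\text{indel events}}{\text{alignment length}}$$

computed on an affine-gap Needleman–Wunsch global alignment (*quickdist*;
a gap run of any length counts once; terminal gaps are excluded), the
pipeline is:

1. **Filter** reads: no ambiguous bases, exact barcoded forward primer,
   mean phred quality ≥ 30, recognizable reverse primer; optional
   reference-coverage (best alignment spanning ≥ 80% of the read) and
   contamination (non-target identity ≥ 0.10 better than template
   identity) filters on unique sequences.
2. **Dereplicate** into abundance-sorted unique sequences.
3. **SLP precluster** at width 0.02: the most abundant sequence seeds
   cluster 1; each subsequent sequence joins the first cluster holding
   any member at $d < 0.02$ (clusters never merge), otherwise it seeds a
   new cluster. A single rescue pass then absorbs clusters with < 10
   reads into larger clusters within the width. Each precluster is
   represented by its most abundant member, carrying the precluster's
   total count. Because templates outnumber any individual error
   variant, abundance ordering lets error variants chain onto their
   template without low-frequency reads chaining two genuine templates
   together.
4. **Cluster representatives** at 3% with average linkage (SLP/PW-AL).
   Missing sparse distances count as 1.0; an optional
   `mothur_rounding` flag rounds merge heights to the nearest whole
   percent before the cut, as common clustering tools do.

A k-mer multiset prescreen ($1 - \text{shared}/\min$, k = 6) skips
pairwise alignments that cannot fall below the distance cutoff; the
alignment kernels are numba-compiled, so a 20 000-read pool clusters in
well under a minute on one CPU.

The package also ships a ground-truthed read simulator (`simdata`), the
spurious-OTU evaluation procedures (`evaluate`), and a CLI (`slp`).

## Worked example

Simulate a 43-template pool (all templates ≥ 6% apart, the narrowest
defensible spacing for distinct 60-nt taxa), sequence it to 20 000 reads
at a realistic error rate, and compare SLP/PW-AL with plain 3%
average-linkage clustering:

```python
from slpotu import (ErrorModel, SLPClustering, ThresholdClustering,
                    count_spurious, dereplicate, otu_stats,
                    simulate_reads, simulate_templates)

templates = simulate_templates(k=43, length=60, min_pairwise_dist=0.06, seed=11)
reads, truth = simulate_reads(templates, n=20000,
                              error_model=ErrorModel(sub_rate=0.003, seed=12))
uniques = dereplicate(reads)
print(f"{len(reads)} reads -> {len(uniques)} unique sequences")

slp = SLPClustering(mothur_rounding=True).fit(uniques)
pw_al = ThresholdClustering(linkage="average", threshold=0.03,
                            mothur_rounding=True).fit(uniques,
                                                      distances=slp.distances_)
print(f"SLP/PW-AL: {slp.n_clusters_} OTUs "
      f"({len(slp.preclusters_)} preclusters); PW-AL alone: {pw_al.n_clusters_} OTUs")

report = count_spurious(slp.otus_, [(t.id, t.bases) for t in templates])
stats = otu_stats(slp.otus_)
print(f"templates recovered: {report.matched}/43, "
      f"spurious OTUs: {report.spurious} "
      f"({report.spurious / 20:.1f} per 1000 reads)")
print(f"largest OTU: {stats.largest_otu_size} reads, "
      f"singleton OTUs: {100 * stats.singleton_fraction:.0f}%")
```

Output:

```
20000 reads -> 3488 unique sequences
SLP/PW-AL: 290 OTUs (341 preclusters); PW-AL alone: 551 OTUs
templates recovered: 43/43, spurious OTUs: 247 (12.3 per 1000 reads)
largest OTU: 510 reads, singleton OTUs: 83%
```

SLP halves the OTU count relative to plain average linkage while
recovering every template. The residual spurious OTUs are almost all
singletons seeded by reads with three or more errors; the simulator
draws errors independently, which makes such reads harder to absorb than
on real instruments — see `docs/methods.md` for why real data shows
lower spurious rates.

The estimators are scikit-learn compatible (`fit`, `labels_`,
`get_params`/`set_params`), so they compose with sklearn model-selection
utilities; `slpotu.hcluster`, `slpotu.slp_precluster` and
`slpotu.slp_pipeline` are functional wrappers over them.

The same pipeline is available from the shell:

```bash
slp simulate --templates 43 --length 60 --n 20000 --seed 11 --out sim/
slp pipeline sim/reads.fasta --skip-filter --mothur-rounding --out run/
slp evaluate run/otus.tsv run/reps.fasta sim/templates.fasta --out eval/
```

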