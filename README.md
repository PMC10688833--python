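# phagetaxkit

A toolkit for genome-based phage taxonomy, built around the sequential
workflow used to propose new mycobacteriophage genera and subclusters:
curate the dataset, compute pairwise **intergenomic nucleotide
similarity** (genus demarcation ≥ 70%, species ≥ 95%), corroborate
candidate genera with **fragmented translated-proteome similarity**
(~50% boundary), check that each proposed genus is **monophyletic** on a
distance tree, and quantify how well the proposed genera line up with
the Actinobacteriophage Database's subcluster system (the
*genus–subcluster hypothesis*).

It is aimed at phage researchers who want to re-run this style of
analysis on their own genome sets reproducibly, without the web portals
(VIRIDIC/Gegenees/VICTOR) the original workflow relied on, and at
method developers who need a planted-truth simulator to validate
threshold choices.

## The statistics at the core

**Intergenomic nucleotide similarity.** For genomes *a*, *b* with local
alignments found on both strands (seed-and-extend, BLASTN-like scoring:
match +2, mismatch −3, gap of length *L* costs 5 + 2*L*, HSPs < 50
discarded),

```
sim(a,b) = 100 · (id_a + id_b) / (len_a + len_b)
```

where `id_x` counts positions of *x* aligned to an identical base, each
position at most once. Unaligned genome fraction depresses similarity,
so the measure is threshold-comparable across genomes of unequal
length. Length ratio and per-genome aligned fractions are reported
alongside.

**Fragmented proteome similarity.** The query genome is cut into 200 bp
fragments at 100 bp steps; each fragment's six reading-frame
translations are locally aligned (BLOSUM62, gap −11/−1, stops score −4)
against the six frames of the target, keeping the single best score:

```
score(q→t) = 100 · Σ_f best(f, t) / Σ_f best(f, q)
```

— the average best score as a percentage of the query's self-score.
The matrix is asymmetric; a genome contained in a larger one scores
100 in the containment direction.

**Trees and monophyly.** Similarities convert to distances
d = (100 − sim)/100; trees are built by neighbor joining with
deterministic tie-breaking, and branch support comes from resampling
query fragments with replacement. A genus is monophyletic iff its leaf
set is one side of an edge bipartition of the unrooted tree.

**Concordance.** Each subcluster — and each cluster with no
subclusters — is a group; the statistic is the percentage of groups
whose members carry exactly one genus (a strict variant also requires
the genus to appear in no other group). A reorganization editor applies
subcluster edits (create/merge/reassign/remove) and recomputes the
statistic before and after.

## Worked example

```
phagetaxkit simulate --preset subcluster_recovery --seed 3 \
    --out-fasta sim.fa --out-truth truth.tsv
phagetaxkit nt-sim --fasta sim.fa --out nt.tsv
phagetaxkit classify --matrix nt.tsv --metadata truth.tsv --out proposals.json
phagetaxkit concordance --metadata truth.tsv --out concordance.json
```

The simulated set plants one cluster of three genera (four genomes
each, 2 kb). The top of the printed similarity matrix reads

```
nucleotide  A1_01   A1_02   A1_03   A1_04   A2_01   ...
A1_01       100.00  86.25   86.30   86.40   0.00
A1_02       86.25   100.00  86.70   87.05   0.00
```

— within-genus pairs sit near 86–88% (well above the 70% genus
threshold), while between-genus pairs at the planted divergence share
too little alignable sequence to score. `proposals.json` then reports
zero novel genera (the threshold partition reproduces the planted
taxonomy exactly) and `concordance.json` prints `"statistic": 100.0` —
every subcluster-level group carries a single genus.

The same stages run end to end, with proteome matrices, a bootstrap NJ
tree and the before/after concordance report, via

```
phagetaxkit run --fasta genomes.fa --metadata meta.tsv --out-dir run1/ \
    --genus-threshold 70 --species-threshold 95 --bootstrap 100 --seed 1
```

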