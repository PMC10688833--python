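# Methods

This note documents the models, algorithms and numerical choices behind
phagetaxkit, what the synthetic data generator does and does not
emulate, and the package's known limitations.

## Intergenomic nucleotide similarity

The pairwise measure is identity-over-total-length:
`sim = 100·(id_a + id_b)/(len_a + len_b)`, where `id_x` is the merged
per-position identity count of genome *x* across all local alignments
of the pair (both strands). This form reproduces the behaviour that
made the measure suitable for genus demarcation: genomes that align
well over only part of their length are penalized by the unaligned
remainder, so a 70% cut-off expresses "at least 70% of the summed
genome length is identically aligned". The function canonicalizes the
pair by id before aligning, so `sim(a,b) == sim(b,a)` exactly.

**Alignment engine.** Local alignments are found by seed-and-extend
with BLASTN-like defaults: exact 11-mer seeds (k-mers containing N are
ineligible; N never scores as a match), match +2, mismatch −3, a gap of
length *L* costs 5 + 2·*L*, and alignments scoring below 50 are
discarded. Seeds are grouped by diagonal into candidate regions:

- *Small regions* (window area ≤ 16 M cells) are resolved by exact
  affine-gap local dynamic programming (Bio.Align.PairwiseAligner over
  an alphabet with mask symbols), iterated with masking so every HSP
  above the score floor is recovered, not just the optimum.
- *Large regions* — in practice near-full-length homologies between
  long genomes — are resolved gaplessly: each seed-bearing diagonal is
  scored (+2/−3) and all maximal-scoring segments are enumerated with
  the Ruzzo–Tompa algorithm. Diagonals are first split at Kadane reset
  points (positions where the best segment ending there has score ≤ 0);
  maximal-scoring segments provably never span such a point, and
  segments whose best subarray cannot reach the score floor are skipped,
  which keeps the enumeration near-linear even between weakly related
  genomes.
- Isolated stray seeds are screened by a cheap gapless extension
  (radius 64) and escalated only if they approach the score floor
  (escalation threshold 40 < 50, deliberately conservative).

Overlapping HSPs are merged in descending score order (ties broken by
start coordinate, then partner id); each position contributes at most
once, to identity and to coverage alike. The test suite checks the
merged identity counts of the whole engine against an independent
exhaustive Smith–Waterman HSP enumerator (full affine DP with masking)
on pairs up to 2 kb.

The gapless long-range mode is exact for substitution-only divergence,
which is what the generator produces; real genome pairs with large
indels inside a single homologous run would be chained less precisely
there. The minimum score of 50 stabilizes the "unrelated ⇒ ~0"
behaviour on random sequence (chance 11-mer hits never extend to 50
under the scoring above).

## Fragmented translated-proteome similarity

Fragments of 200 bp are taken every 100 bp; if the genome length is not
on the step grid one final full-length fragment ending at the genome
end is appended, so every nucleotide is covered at least once (the edge
handling of the original fragmented-comparison tools is undocumented;
this rule is the package's own choice). Genomes shorter than one
fragment are a single fragment.

Each fragment is translated in all six frames and aligned locally
against all six frames of the target with BLOSUM62; gaps cost 11 + *L*
for length *L* (the NCBI convention "open 11 / extend 1"; the opening
residue pays both). The stop symbol `*` is set to −4 against
everything, including itself, so frame-breaking regions cannot
accumulate positive score. Frames shorter than one codon are skipped,
and a fragment's contribution — the single best frame-pair score — is
floored at 0 so no fragment can contribute negatively. Raw alignment
scores are used (not bit scores; the original tool's internal score
type is not documented), which is validated on synthetic data only.
The percentage is normalized by the query's self-score, obtained by
scoring each fragment against its own parent genome with the same
machinery; since a fragment is an exact substring of its parent and the
BLOSUM62 diagonal dominates its rows, the self-score is the attainable
maximum, so values stay in [0, 100] (clamped defensively).

Per-fragment best scores against every target are cached in a table,
so the bootstrap (below) resamples rows instead of re-aligning.

## Threshold clustering

Genus and species partitions cut an agglomerative clustering of
distance 100 − sim at 100 − θ. Complete linkage is the default because
the resulting clusters guarantee *every* pairwise similarity ≥ θ —
matching the demarcation's reading as "the minimum similarity required
for genus inclusion"; single linkage is available for sensitivity
analysis. Ids are sorted lexicographically before linkage so merge
ties resolve deterministically, and cluster labels `G1..Gk` follow the
lexicographically smallest member. Pairs falling within a band just
below the threshold (default 5 points) are reported as *borderline* so
judgment calls — accepting a 66% boundary where 70% would fragment an
otherwise coherent group — are an explicit, reviewable output rather
than silent behaviour.

Novel genera are named after their lexicographically first member
(lowercased + "virus", capitalized). Subcluster proposals mirror the
genus groups within each cluster, inheriting an existing subcluster
label greedily by shared-member overlap (ties: larger group, then
lexicographically first member), issuing the next free numeric suffix
otherwise; an existing label is never assigned to two groups.

## Trees, support and monophyly

Distances are d = (100 − sim)/100, clamped to [0, 1]. This is a
plumbing transform, not an evolutionary model — the tree stage is used
as a monophyly check, and only the topology is consumed downstream.
Neighbor joining is implemented directly: Q-matrix ties are broken by
the lexicographically smallest pair of clade labels (a clade is
labelled by its smallest leaf), negative branch lengths are clamped to
0, and the output is unrooted with a trifurcating seed node. On
additive matrices NJ recovers the generating topology exactly, which
the test suite verifies on random additive trees of 4–12 leaves.

Branch support resamples each genome's query fragments with
replacement (the proteome route, since the reference analyses are
amino-acid based), rebuilds the symmetrized matrix and NJ tree per
replicate, and scores each internal edge of the reference tree by the
percentage of replicates containing the same bipartition. Supports are
deterministic for a fixed seed.

Monophyly is defined on the unrooted tree: a leaf set is monophyletic
iff it or its complement is one side of an edge bipartition; singletons
and the full leaf set are monophyletic by convention. Defining it on
bipartitions avoids an arbitrary rooting decision.

## Concordance

The genus–subcluster statistic needs a denominator; the package uses
*groups*: every subcluster is a group and every cluster without
subclusters is one group (members of a partially subclustered cluster
that lack a label form a residual "unplaced" group). This is an
interpretation — it is the reading under which undivided clusters can
participate in the hypothesis at all, and under which the headline
percentages are ratios of whole groups. Both the plain statistic
(groups with exactly one genus) and the strict one-to-one variant are
reported; percentages are rounded half-up to one decimal, matching the
printed precision of published values. Reorganization edits are applied
sequentially with a full audit log, and errors identify the failing
edit by index.

The packaged RefSeq cluster census reproduces the published per-cluster
table as printed; its per-cluster counts sum to 751 against a stated
dataset size of 752 — the discrepancy is in the source and is left
unresolved. The real dataset's per-phage taxonomy (needed to reproduce
the published concordance values on real data) is not published
in-text, so the 83.3% → 97.6% arithmetic is demonstrated on an
engineered scenario with the same group structure: 60 of 72 groups
pure before, then 13 subcluster creations plus one removal yield 82 of
84 pure. The scenario is synthetic and is labelled as such in code.

## Synthetic data generator

The generator plants a cluster → genus → leaf hierarchy: per cluster an
i.i.d.-uniform root genome; per genus an ancestor obtained by
substituting each site with probability `q_genus` (uniform over the
three alternatives); per leaf further substitutions at `q_leaf`.
Uniform base composition is used deliberately — GC realism affects no
tested contract. The expected per-site identity between leaves
separated by channels q₁..qₙ is `1/4 + 3/4·Π(1 − 4qᵢ/3)`; for a
same-genus pair this reduces to `(1−q_leaf)² + q_leaf²/3`. Optional
mosaic swaps copy a same-coordinate segment from a pre-mosaic genome of
another genus in the same cluster (Poisson-distributed count per
genome), emulating — at a controllable level — the segment exchange
that decouples nucleotide and proteome similarity in real phages. All
randomness flows through one `numpy.random.default_rng(seed)`, so
output is byte-identical per seed across platforms.

Presets:

- `genus_recovery` — 3 clusters × 3 genera × 4 genomes at 30 kb;
  `q_leaf = 0.0625` puts within-genus similarity near 88 and
  `q_genus = 0.2325` puts between-genus expected identity near 0.55,
  where alignments fragment and measured similarity collapses below 10,
  so recovery at the 70 threshold must be exact.
- `borderline` — one cluster, two genera, 20 kb; `q_genus = 0.1778`
  targets between-genus expected identity 0.675, placing measured
  similarities inside the [65, 70) reporting band (derived by inverting
  the identity formula for the band midpoint; verified stable across
  seeds).
- `subcluster_recovery` — a compact single-cluster, three-genus variant
  at 2 kb, sized so the translated-proteome stage is affordable in
  routine runs.
- `mosaic_stress` — `genus_recovery` plus two expected 2 kb swaps per
  genome; with `mosaic_rate = 0` it degenerates to `genus_recovery`.

What the generator does **not** emulate: indels, gene content and
synteny, codon structure (reading frames in simulated genomes are
arbitrary), GC bias, and host-driven biases. Passing recovery tests
therefore show that the pipeline's thresholds and plumbing behave
correctly under controlled substitution divergence — not that the
thresholds are optimal for real mycobacteriophage data, where
mosaicism and shared gene pools blur the similarity structure.

## Problem sizes and numerical choices

Routine runs and the reproduction script use the full 36-genome, 30 kb
`genus_recovery` set for everything on the nucleotide route (the full
matrix takes ~30 s). The translated-proteome stage costs
O(L²) residue-cell updates per ordered genome pair, so
proteome matrices and bootstrap supports are exercised on compact sets
(1.2–2 kb genomes, 6–12 per run) — the per-fragment score table makes
the bootstrap itself cheap. End-to-end workflow checks (concordance
100, all genera monophyletic) use these compact sets; the 30 kb set
feeds the tree and monophyly checks through the nucleotide matrix.

Tolerances and tie-breaks worth knowing: nucleotide matrices are
validated symmetric to 1e−9 and resymmetrized after 2-decimal TSV
round-trips; identity counts are integers and compared exactly against
the DP oracle; NJ branch lengths are clamped at 0; all label orderings
fall back to lexicographic comparison; the concordance statistic is
rounded half-up to one decimal. Degenerate inputs: an all-N genome has
no eligible seeds (nucleotide similarity 0) and raises a zero-self-score
error in the proteome stage; empty metadata tables curate to an empty
report.

## Limitations

- The proteome stage is exact but quadratic; it is not intended for
  full-length (30–160 kb) genome sets on a single CPU.
- The gapless long-range alignment mode under-chains homologies
  containing large indels (substitution-only divergence is exact).
- Tree construction is NJ on similarity-derived distances, a
  methodological substitution for the genome-BLAST distance phylogeny
  family; only monophyly conclusions are consumed, and those agree
  with brute-force enumeration on random trees, but branch lengths are
  not comparable to published dendrograms.
- Visual-inspection overrides (e.g. accepting a 66% genus boundary) are
  not automated; the borderline report surfaces the candidates and the
  thresholds are flags.
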