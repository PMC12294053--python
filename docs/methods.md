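# Methods

This note documents the models, parameter choices, and numerical
decisions behind `hgtscreen`, and what the synthetic benchmark does and
does not establish about real data.

## Sequence model and distances

All residues live over {A, C, G, T, N}; other IUPAC codes are mapped to N
on input and N is treated as missing data throughout. Coordinates are
0-based half-open everywhere internally (BED-native); only human-readable
reports render 1-based positions.

Distances use pairwise deletion: for each sequence pair, alignment
columns where either row carries a gap or N are excluded before counting.
The p-distance is the fraction of differing retained sites; the K2P
distance is d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) with P, Q the transition
and transversion proportions. A pair with no retained sites is undefined
(NaN — never silently 0); a pair whose logarithm argument reaches zero is
saturated and reported as +inf. For tree building, undefined and
saturated entries are replaced by a configurable cap (default 5.0
substitutions/site) and flagged; the cap matters because cross-phylum 5S
gene comparisons (~65–70% similarity) approach saturation.

Region-wise similarity in the gene/NTS comparison is computed over *all*
columns of a global alignment, with gap columns counting as differences.
The pairwise-deletion convention is kept for the distance matrices, but
it is the wrong statistic for deciding whether two spacers are related:
the optimal alignment of two unrelated spacers is gap-rich, and deleting
gap columns inflates their apparent similarity to ~70%. With gaps
counted, unrelated spacers score ~50%, substitution-only diverged spacers
score ~100×(1−p), and the decision thresholds below separate cleanly.

## Alignment

Pairwise global alignment is an affine-gap Gotoh DP (match +1, mismatch
−1, gap open −2, gap extend −0.5; a gap of length L costs open +
(L−1)·extend; N never counts as a match). The traceback is deterministic
with tie order diagonal > up > left. The same DP runs on profile columns
(frequency vectors) for the progressive multiple alignment, whose guide
tree is average-linkage clustering of k-mer distances (k = 6). These
defaults are conventional DNA scores; they do not bit-reproduce any
specific aligner's output, and region similarities therefore carry a few
percentage points of alignment-induced uncertainty (the tests use ±3 pp
on spacer similarities, ±1 pp on gene similarities).

Local search is exact k-mer seeding (default k = 11, both strands, N
excluded) followed by per-diagonal extension to the maximal-scoring
ungapped segment, computed exactly via prefix sums. This is at least as
sensitive as classic x-drop extension at the same scoring; the `x_drop`
parameter is retained in the API as the admissible-drop knob. Collinear
segments on nearby diagonals (≤ 30 bp apart) are merged into gapped hits
by realigning the spanned region. Hits report identity (matches over
aligned non-gap columns), query cover, and raw score; there are no
e-values — filtering is by identity/cover/score, which is what the
downstream decisions actually consume.

## Haplotypes, trees, incongruence

Within each group, sequences are collapsed to haplotypes by exact string
identity (N compares as a symbol; different lengths are always distinct).
Collapse is per group so that identical sequences from host and parasite
remain distinct leaves — exactly the situation the screen must detect.

Trees are built by neighbor joining (Saitou–Nei Q criterion) with two
determinism guarantees: ties in Q break on the lexicographically smallest
pair of cluster representatives, and a negative pendant length is clamped
to zero with the deficit moved to its sibling so the joined pair's mutual
distance is preserved. NJ stands in for a full maximum-likelihood search
under the same substitution model; the quantity the screen consumes is
the incongruence pattern, which is robust to the exact topology of the
background groups. An optional refinement hill-climbs over
nearest-neighbor interchanges under a Felsenstein-pruning K2P likelihood
with fixed transition/transversion rate ratio κ (default 2.0,
configurable; fixing κ keeps the likelihood checkable against an
independent state-enumeration oracle). Branch lengths are re-optimized
per edge by bounded Brent; the search stops when no move gains more than
1e-6 log-likelihood. Bootstrap support resamples alignment columns with
replacement; replicate r uses seed sequence [seed, r], so support values
are independent of taxon input order.

The incongruence scan formalizes "clusters with a foreign clade": for
each leaf, take its m nearest leaves by patristic distance (default
m = 3, ties broken by label) and flag the leaf when its own group holds a
strict minority (< 50%). The scan also reports each leaf's nearest
foreign distance, and the pipeline counts a candidate as incongruently
placed only when it is flagged *and* its nearest foreign leaf lies within
a patristic radius (default 0.15 substitutions/site). The qualifier is a
deliberate design choice: the minority rule alone also fires on a lone
diverged native unit (an isolated one- or two-member group has a foreign
neighborhood by arithmetic), whereas transfer-style incongruence means
being *nested inside* the foreign clade. The radius sits an order of
magnitude above within-family divergence (~0.005–0.03) and far below
cross-phylum distance (~0.4+), so it is insensitive over a wide range.

## Gene/NTS partition and the differential comparison

A unit is partitioned by locating the 5S gene with a panel search and
projecting the full panel gene through the best hit's diagonal (exact for
substitution-only divergence; the identity floor of 0.60 sits below the
cross-phylum gene-similarity floor, so even a maximally diverged native
gene is found). Candidate units are pulled out of an assembly the same
way, extending each non-overlapping gene hit by the reference spacer
length on the appropriate side.

The differential comparison classifies a pair of units from gene
similarity and NTS similarity: `extended_similarity` iff gene ≥ 90% and
NTS ≥ 65%; `gene_only` iff gene ≥ 90% alone; else `dissimilar`. The NTS
threshold of 65% splits the two observed regimes — a transferred spacer
at ~71% and a merely gene-conserved pair at ~59.5% — and both raw values
are always reported, so the threshold never hides data.

## Coverage screen

The mapper indexes the host genome's k-mers (default k = 21; sequences
joined with an N spacer so no k-mer spans a boundary) and seeds each read
with its non-overlapping k-length chunks on both strands; with
⌈len/k⌉ ≥ max_mismatch + 1 chunks, the pigeonhole principle guarantees an
exact seed for every valid placement. Candidates are verified by Hamming
distance (default ≤ 3 mismatches over 100 bp reads); among equal-best
placements one is chosen uniformly at random under the run seed, with the
multiplicity recorded (an "all-best fractional" mode is not needed for
the decision and was left out). Reads are assumed adapter/quality
trimmed; the generator emits clean reads, and a mean-quality filter is
available for real FASTQ.

Windows tile each sequence at fixed width (1 Mb at full genome scale;
the synthetic benchmark uses 10 kb windows on ~2 Mb genomes). The
enrichment test is upper-tail Poisson, p = P(X ≥ count | λ_w), with
λ_w = N_total · width_w / genome length by default — the genome-wide rate
scaled to window length, so truncated terminal windows get
proportionally smaller expectations. A per-window-mean rate estimator
and a Bonferroni flag exist as options but are off by default; the
significance threshold is p ≤ 0.01 with no correction, and a window must
be significant in *every* library to count (the replicated-library
criterion). Because counts are discrete the test is conservative: under
uniform placement the significant fraction stays below the nominal 1%
(measured ≈ 0.8% over 200 × 50 windows).

## Evidence rules

The verdict is a pure function of a per-candidate evidence table;
every rule's outcome is reported so the inference is auditable.

* `contamination_suspected` iff any indicator fired: ≥ 1 single-copy host
  marker recovered (identity ≥ 0.9, query cover ≥ 0.5), ≥ 1 high-copy
  host TE recovered, or the abundant host repeat family present
  near-verbatim (identity ≥ 0.9).
* `HGT_candidate` iff the candidate is incongruently placed, shows
  extended gene+NTS similarity, has strictly positive NTS divergence, and
  no indicator fired.
* Everything else — including any unknown evidence field — is
  `inconclusive`.

Repeat-family presence is two-level: strict (≥ 0.9 identity,
contamination-grade) vs loose (≥ 0.65, family merely detectable), so the
copy-number-asymmetry argument can distinguish "the rare somatic-like
family is detectable while the abundant oocyte family is absent"
(transfer-compatible) from "the abundant family is present verbatim"
(contamination). How many failed indicators should suffice is not
something the underlying argument quantifies; the conjunction/disjunction
structure above is this package's explicit formalization and is labeled
as such in reports.

## Synthetic scenarios

The generator reproduces the study conditions at one tenth of real copy
numbers (a single `copy_scale` knob): host somatic 5S units of a 120 bp
gene + 768 bp NTS × 40 copies (real ≈ 400), oocyte-type units with NTS
length drawn once from 537–701 bp × 2000 major + 130 minor copies (real
≈ 20,000 + 1,300), a 40S-rDNA-like array of 50 units (real 400–600), U1
and H3 clusters, single-copy Rag1/Rhod, two high-copy and three low-copy
TE families, microsatellite and telomere tracts, and ~150 kb unique
blocks per chromosome. The parasite carries a native 5S array whose gene
sits at 0.42 substitutions/site from the host gene — chosen so the
*realized* similarity is ≈ 68%, the observed cross-phylum floor.

The mutation process is pure K2P: per-site substitution with the exact
transition probabilities at the programmed branch length (multiple hits
included, no indels), so realized distances are consistent estimators of
programmed ones (criterion: |mean realized − 0.3| < 0.02 at 10 kb × 200
replicates). NTS length variation between families comes from generator
sampling, not indel evolution. Within-array divergence is 0.005
substitutions/site, mimicking concerted-evolution homogeneity.

The transfer scenario plants one host somatic unit in the parasite with
gene divergence 0.01 and NTS divergence 0.36 substitutions/site — the
branch length whose realized spacer similarity is ≈ 71%, matching the
observed extended-similarity value (a p-style divergence of 0.29 would
overshoot to ~76% under a proper multiple-hit substitution process).
The contamination scenario puts a fraction f of host reads in each
library (default 0.05) and appends round(1200·f) host fragments of
1.5 kb to the assembly, sampled uniformly along the host genome — which
is copy-number-proportional sampling, since the abundant families
dominate host length. Reads are 100 bp, 8,000 per library × 2 libraries,
error rate 0.001, uniform fragment starts; all randomness flows from one
seed and identical seeds give byte-identical FASTA/FASTQ.

### What the benchmark shows — and what it does not

Passing tests establish that the *inference logic* separates the two
scenarios with high power (≥ 18/20 correct calls each way, misses only
ever inconclusive) under substitution-only evolution with clean tandem
arrays. Real data add indels and alignment ambiguity (manually curated
in practice), pseudogenes and truncated units, diverged TE copies,
GC/repeat-content mapping biases, and assembly artifacts that break the
"contamination enters in proportion to copy number" idealization.
Region similarities on real accessions therefore carry a few percentage
points of alignment-choice uncertainty that the synthetic benchmark does
not exercise, and the verdict thresholds are exposed as configuration
rather than constants.

## Problem sizes and runtime

The shipped test suite and acceptance script run the full screen on
~2 Mb host / ~0.8 Mb parasite genomes with 16,000 reads per scenario
replicate (seconds per replicate on one CPU); 20 seeded replicates per
scenario for the power checks and 10 for the acceptance metrics. These
sizes are the package's chosen desk-scale study conditions; every stage
accepts full-scale inputs with the same interfaces (1 Mb windows are the
default window width on real genomes).
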