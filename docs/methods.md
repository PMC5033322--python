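# Methods

This note documents the models, numerical choices, and limitations behind
`clademark`. It is written for users who need to know what the numbers
mean, not how the code is organised.

## The problem

Bacterial species in tight clades (>99% 16S identity) cannot be separated
by the usual single-locus barcodes, and public-database labels inside such
groups are unreliable. The package combines three independent
whole-genome lines of evidence to (re)circumscribe strains — average
nucleotide identity, core-gene phylogenomics, and encoded-function
repertoires — and then asks a supervised question: *which single core
gene best reproduces the species partition*, so that future isolates can
be placed with one marker and a PCA instead of a whole-genome pipeline.

## Fragment ANI

`ani.compute_ani_pair` follows the ANIb convention. The query genome is
cut into consecutive fragments (default 1020 nt; a trailing piece is kept
iff ≥ half the fragment length). Each fragment is searched against the
subject by exact 15-mer seeding, diagonal clustering, and an exact local
affine-gap alignment (match +2, mismatch −3, gap open −7, extend −2) of
the fragment against a window around the best diagonals; both strands are
searched. A fragment is retained iff its best hit reaches ≥30% identity
(identities / alignment columns, the BLAST `pident` convention) over ≥70%
of the fragment. ANI is the mean identity of retained fragments;
`aligned_fraction` is the retained length over the query length.

Two consequences worth knowing:

* a pair with **no** retained fragment has *undefined* ANI — reported as
  a flag/NaN, never 0, because a 0 would silently corrupt the Pearson
  correlations downstream;
* identity is computed over local-alignment columns, so a terminal
  mismatch of a fragment may be trimmed by the aligner; on ungapped
  simulations the reported identity equals a direct per-site count over
  the reported HSP coordinates to 1e-9 (tested).

Correlation clustering treats each strain's directional ANI row (diagonal
included) as its profile, computes Pearson r between profiles, and
clusters 1−r with complete linkage by default (configurable). Strains
with zero-variance profiles are reported as degenerate.

GBDP distances are computed from the retained HSPs:
d₀ = 1 − 2ΣL/(l_q+l_s), d₄ = 1 − Σid/ΣL (undefined when ΣL = 0),
d₆ = 1 − 2Σid/(l_q+l_s). Conversion to a DDH percentage requires the
caller to supply logistic coefficients; the fitted regression of the GGDC
service is not shipped, and `ddh_estimate` refuses to guess.

## Core genome and phylogenomics

Orthology is protein-level reciprocal best hits against a chosen
reference proteome: exact Smith–Waterman (BLOSUM62, gaps −11/−1) with
Karlin–Altschul e-values (gapped constants λ=0.267, K=0.041), cutoff
1e-30. Ties are broken by (bitscore, e-value, lexicographic subject id);
a strain with two hits to one reference gene keeps only the reciprocal
best (single-ortholog invariant). `core_scope="all"` demands presence in
outgroups too (filters post-speciation transfers); `"group"` restricts to
the focal strains.

Families are aligned per gene (mafft adapter by default; a built-in
progressive profile aligner otherwise), concatenated with a recorded
partition map, and trimmed with Gblocks-style rules: a column is
conserved with ≥ ⌈n/2⌉+1 identical residues, highly conserved with
≥0.85n; any-gap columns are removed; runs of >8 contiguous nonconserved
columns are removed; blocks are trimmed to highly conserved flanks and
dropped below 10 columns. All thresholds are configurable.

Distances use pairwise deletion and the p, JC69
(d = −¾ln(1−4p/3)) or K80 (d = −½ln(1−2P−Q) − ¼ln(1−2Q)) models; K80 is
the default, matching the default of the distance function in the R
package the field commonly uses for this step. Non-estimable values
(log of a non-positive argument, or no comparable sites) are flagged
missing; tree construction then refuses and suggests the p fallback
rather than imputing. The K80 implementation is cross-checked against
R `ape::dist.dna` to 1e-8 in the test suite.

Trees are Saitou–Nei neighbor joining (negative branch lengths clamped to
zero). Bootstrap resamples supermatrix columns with replacement;
supports are the percentage of replicates containing each internal
bipartition, computed over a canonical taxon ordering so results are
invariant to input order. Internal ML inference is deliberately out of
scope: the trimmed supermatrix and a RAxML-style partition file can be
exported for an external ML tool, but nothing downstream depends on ML.

## Function repertoires

Orthogroups come from Markov clustering of the all-vs-all protein
similarity graph (e ≤ 1e-5): edge weight −log₁₀e capped at 300,
normalized per strain pair by that pair's mean weight, column-normalized
flow with expansion/inflation (default 1.5) iterated to <1e-6 change or
100 rounds; clusters are the connected components of the converged flow.
Ungrouped proteins get a best-hit function against an optional annotated
database, else a private singleton column; orthogroup-derived and
fallback-derived functions keep provenance tags and are never merged into
one namespace (avoids double counting). Function matrices are binary
(strain has ≥1 member), and all-zero columns cannot occur.

Repertoires are compared with Manhattan distance (equal to Hamming count
on binary profiles) under average linkage; bootstrap probabilities are
the fraction of column-resampled replicates in which the identical strain
set reappears — ordinary BP, not multiscale AU probabilities, a
deliberate simplification recorded here as a limitation.

Tree comparison reports: Pearson correlation of cophenetic distance
vectors; Baker's γ implemented as the Spearman rank correlation of the
same cophenetic vectors; entanglement after a two-pass alternating
rotation heuristic (nodes with ≤3 children try all child permutations —
this covers the root trichotomy of an unrooted NJ tree, which is
midpoint-rooted for comparison — larger polytomies only try reversal;
exact minimization is NP-hard); and a discordance detector: a strain is
discordant when its k=3 cophenetically nearest neighbours differ between
the trees, scored by the symmetric difference of the two sets. With
species of ≤3 strains the third neighbour is cross-species and tie-prone,
so small discordance scores (2) on conspecifics are background; the
ecotype signature is the unique top score.

## Marker ranking by Random Forest

Features follow the G×O construction (genes-major, organisms-minor
column order, distance model stamped in metadata). Rows missing a gene
are flagged and that gene's block is NaN — imputation is refused, because
imputed distances would silently bias importance; single-gene prediction
abstains instead.

The forest is bagged CART with per-split feature subsampling
(mtry = ⌊√V⌋ by default) and majority vote; defaults are 100 000 trees
and seed 12345, while the test suite runs scaled-down forests
(400–1000 trees), a problem size chosen because rankings are already
stable there. Importance is Breiman's out-of-bag permutation measure:
per tree, the drop in OOB accuracy when one variable's OOB values are
permuted, averaged over all trees (trees not using the variable
contribute zero); values are *raw* (unscaled, possibly negative).
Gene-level importance aggregates a gene's O variables by mean (sum/max
selectable). Per-gene error rates retrain one forest per gene on only
its O columns and score the held-out test strains. The per-gene summary
statistics use sample variance (ddof=1) over all unordered strain pairs.

## Marker PCA and outclass calls

The marker's distance table (strains × reference organisms) is centred —
not scaled, matching the R `prcomp` default the field uses; `scale=True`
is available — and eigendecomposed; components carry a deterministic sign
convention (largest-magnitude loading positive). Each class with ≥3
labelled members gets a normal-theory ellipse
{x : (x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₂(level)} on (PC1, PC2), level 0.95 by default;
singular covariances are ridged by 1e-9 with a warning, and classes with
<3 members are reported, not silently dropped. Calls: inside exactly one
ellipse → that class; inside several → Mahalanobis-nearest, flagged
ambiguous (the level-dependence of borderline calls is real, hence the
flag); inside none → outclass. The default workflow refits the PCA
jointly on references plus new strains; projection through stored
means/loadings is available for streaming use.

## The synthetic clade generator

The genealogy is star-within-star: species ancestors diverge
independently from a clade ancestor, strains from their species ancestor.
Configured divergences are *expected pairwise* proportions (edge rates
are half), so the ANI bands of a config map directly onto observed
identities: within 0.01 / between 0.08 reproduces the ~99% within-species
vs ~90% between-species ANI structure of a tight clade. Substitutions
are i.i.d. per site, uniform over the other three bases, with no indels —
this keeps every per-site distance oracle exact. Genomes are the
concatenated core genes plus species-private accessory genes (the gene
gain/loss component of repertoires) and a species-shared random filler
block, so whole-genome ANI and core-gene distances are related but not
identical. Genes are built from stop-free codons; mutation-induced stops
translate to 'X'.

Per-gene rate multipliers scale both genealogy levels; an optional
per-gene *between* multiplier decouples the species-level signal from the
overall rate. This matters: on a star genealogy with within ≪ between,
*any* uniformly scaled gene is a clean species discriminator, so a
"diagnostic vs noise" contrast needs genes whose variation is largely
strain-private. The canonical `marker_ranking_scenario` (4 species × 4
strains, 1%/8%) therefore uses one gene with clean species signal, eight
fast-evolving genes whose species signal is weak relative to their
strain-private noise (imperfect discriminators with genuinely positive
importance), and one invariant, ribosomal-protein-like gene.

Function matrices are generated directly: core functions all-1, a private
accessory block per species (default 60), optional per-cell noise flips,
and an ecotype strain that loses a prescribed number of core functions
and gains private ones (the 171-loss/28-gain configuration gives a strain
differing from its conspecifics in exactly 199 cells).

What the generator does **not** emulate — recombination, codon structure
beyond stop avoidance, indels, rearrangement, contamination, uneven
coverage — bounds what green tests mean: they demonstrate correctness of
the algorithms and recovery of planted structure under the stated model,
not robustness to every artefact of real assemblies.

## Determinism and problem sizes

Every stochastic stage takes an explicit seed (simulation, bootstrap,
forest construction, permutation importance), and pipeline reruns under
the same seed/config are byte-identical; reports are stamped with the
seed and a config hash. Tests and the acceptance script run desk-scale
problems (genomes of a few kb, 4–24 strains, forests of ≤1000 trees),
sizes chosen so the planted structure is recovered with wide margins;
the published-scale defaults (1020 nt fragments, 1e-30/1e-5 cutoffs,
100 000 trees, seed 12345, 0.95 ellipses) remain the shipped defaults.
For genome collections at real scale the built-in aligners are the
bottleneck; the search backends are pluggable (NCBI BLAST+ tabular
adapter for RBH, external aligner for MSA) for that use.
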