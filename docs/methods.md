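# Methods

This note documents the models and numerical choices behind each stage, the
defaults and why they are what they are, what the synthetic generators do
and do not emulate, and the known limitations.

## Profile screening

The screening instrument is a position-specific scoring matrix rather than
a full profile HMM. Per match column the score of residue *a* is

    S_k(a) = log2( ((c_{k,a} + λ·b_a) / (n_k + λ)) / b_a )

with observed count `c`, column depth `n` (gaps and X excluded), pseudocount
λ = 1 and background *b* the Robinson–Robinson amino-acid frequencies.
Alignment columns with more than 50% gaps become insert states and are
dropped (standard profile practice). Scoring is local (Smith–Waterman)
against the profile with affine gaps: a run of *g* gap positions costs
`open + (g−1)·extend` with open = −11 and extend = −1, the BLOSUM62-era
defaults, in the same log2 units as the match scores; deletion and
insertion runs may not be adjacent, alignments start and end in a match,
and the score is floored at 0. 'X' scores 0 in every column; any other
non-standard character is rejected rather than silently zeroed.

The cutoff is the minimum score over the characterized transporters, with
ties at the minimum broken by lexicographic id, and the screen keeps scores
≥ cutoff (inclusive), so the calibration set always screens itself
completely. This reproduces the published calibration logic while staying
desk-scale; when fidelity to an HMMER-based workflow matters, a per-target
`--tblout` table can be imported and calibrated/thresholded identically.

The forward pass is vectorized over profile columns (the within-column
deletion recurrence is a max-plus prefix scan), and the matched segment is
recovered by re-running the same pass on the reversed score slab ending at
the winning cell; when several segments tie, one optimal segment is
reported.

## Distances, trees, supports

Maximum-likelihood inference is deliberately out of scope; the tree stage
uses Poisson-corrected distances, d = −ln(1−p), with p the mismatch
fraction over columns ungapped in both sequences (pairwise deletion), and p
clipped at 0.999 so saturated pairs stay finite. Columns with more than 20%
gaps are removed first (boundary inclusive: exactly 20% is kept). An
externally computed Newick tree (e.g. from an ML program) can be supplied
anywhere a tree is consumed.

Neighbor joining follows the Saitou–Nei Q criterion with deterministic
tie-breaking (lowest index pair); negative limb lengths are clamped to zero
with the deficit shifted to the sibling limb. Bootstrap supports resample
alignment columns with replacement, rebuild the NJ tree per replicate, and
annotate each internal edge of the point tree with the percentage of
replicates containing the same leaf bipartition; a fixed seed makes the
entire tree + support output bit-identical across runs. Rooting places the
root at the midpoint of the edge separating a monophyletic outgroup;
supports are re-attached by bipartition identity afterwards, since node
labels can migrate when a tree is re-oriented.

### Clade extraction

Clades are the maximal (closest-to-root) internal nodes with bootstrap
support ≥ 60% (inclusive by default; a strict-`>` switch exists) that
contain at least two candidates and no outgroup leaf; candidates under no
such node are reported unplaced. Two refinements make this rule well-posed:

* **Root-split support is rooting evidence, not clade evidence.** After
  outgroup rooting, the two child edges of the root are halves of a single
  bipartition — the outgroup separation. Counting it as support for "the
  whole ingroup is one clade" would collapse every analysis into a single
  clade whenever the outgroup is cleanly separated, so by default the clade
  search starts below the ingroup root (`include_root_split=True` restores
  the literal maximal reading).
* **Near-zero internal edges are collapsed first** (default threshold 0.02
  substitutions/site, configurable, never applied to leaf or root-child
  edges). A zero-length internal edge is an arbitrary resolution of an
  effectively multifurcating node, and the bootstrap lends such edges
  spuriously moderate support — on simulated star backbones we measure
  supports averaging ≈50% with excursions above 90%, which no fixed support
  threshold separates from real clades. Collapsing near-zero edges is the
  standard safeguard; in the synthetic families the false edges are an
  order of magnitude below the threshold (≤0.012) and true clade edges an
  order of magnitude above (≥0.13).

Each clade's substrate labels are the union of its characterized members'
labels; a clade with none is labeled `unknown`.

## Motifs

The motif grammar has exact residues, the `x` wildcard, and `/`-joined
alternatives binding exactly the flanking single residues (`YYxP/T` is four
positions, the last being P or T; `A/S/C` style multi-way alternatives are
accepted by extension). Scanning is over unaligned sequences, reports all
overlapping hits in ascending position, and can be restricted to a window
(e.g. alignment-derived TMH spans); transmembrane-helix prediction itself
is not performed, so region hints are annotations. Sequence 'X' matches
only the wildcard. Conservation counts a member once regardless of hit
count; the default "conserved" flag threshold is 0.9. Only the three
substrate-specificity motifs recoverable from the family literature ship as
defaults; the broader signature catalogue is user-editable input.

## Differential expression and regulons

Replicates are averaged per (strain, carbon source) on the linear
normalized scale. Clustering uses 1 − Pearson correlation of log2(mean+1)
profiles with average linkage; zero-variance genes cannot be correlated and
are placed at distance 1 from everything and flagged.

The moderated t is the two-group special case of the empirical-Bayes linear
model: per gene the pooled variance s² (df = n₁+n₂−2, on log2(x+1) data) is
shrunk toward a common prior, t = Δ/(s_post·√(1/n₁+1/n₂)) with
s²_post = (d₀s₀² + df·s²)/(d₀+df) and d₀+df degrees of freedom. The prior
(s₀², d₀) is fitted by method of moments on the scaled-F distribution of
the sample variances: with r = Var(s²)/E(s²)², d₀ = (4r·df + 2df − 4)/(r·df − 2)
and s₀² = E(s²)·(d₀−2)/d₀; when the observed dispersion does not exceed
chi-square sampling noise (r·df ≤ 2) the prior is taken as infinitely
informative (d₀ = ∞, normal reference distribution). Setting the prior df
to 0 recovers the ordinary two-sample t exactly (property-tested), and the
implementation is cross-checked against the R limma package on shared data.
All comparisons here are two-group, which is why the general design-matrix
machinery is unnecessary.

Filters use strict inequalities mirroring their printed wording: linear
fold change > 1.5 in the reduced direction (means ratio on the linear
scale, matching the linear-scale floor), BH-adjusted p < 0.01, and genes
with both condition means < 50 marked `na` and never called. BH runs over
the whole measured gene set by default, with results then restricted to the
candidate transporter list; `adjust_within_st=True` switches to adjusting
inside the candidate set only (the right choice is not derivable from the
study description, so both are available). An `increased`/`both` direction
switch reports induction as well. The RNA-seq variant requires FPKM > 10 in
at least one condition, FC > 1.5 reduced, and t-test p < 0.05.

## Synthetic data

The family generator plants a 120-residue domain (the screening target)
inside 400-residue sequences, 4 clades × 8 members by default, half of each
clade flagged as characterized references with one substrate label per
clade, 30 background decoys, and a 3-member outgroup clade. Three design
rules keep the ground truth exact rather than merely likely:

* **Infinite sites on the backbone.** Each non-motif site may mutate on at
  most one lineage (one clade, or the outgroup; per-site probabilities 0.15
  per clade and 0.25 for the outgroup, requiring n_clades·p + p_out ≤ 1).
  Clades therefore share no derived states and the backbone is an exact
  star — any grouping of clades in a tree is noise by construction.
* **Infinite alleles within clades.** Member-level substitutions (rate
  0.05, outside the domain only — the domain is modeled as under purifying
  selection within a clade) always introduce a residue unseen at that site
  in any other lineage, so member noise can never create shared derived
  states across clades either.
* **Motif truth by construction.** Motif realizations are planted once in
  the family ancestor (shared motifs are ancestral, not grouping signal);
  clades designed to lack a motif get one constrained position degraded,
  and every sequence is scrubbed of accidental matches, so the clade ×
  motif presence/absence table equals the design exactly.

What this does **not** emulate: indels (synthetic "alignments" are the
ungapped sequences themselves), realistic substitution matrices (WAG/LG),
rate heterogeneity, correlated sites, or genuinely uncertain clade
boundaries. Passing the recovery tests therefore demonstrates that the
pipeline's logic is correct under its stated assumptions, not that real
families of this difficulty are always recoverable.

The expression generator mirrors the study layout: a wild type on 8 carbon
sources and one deletion strain per TF (six TFs, each paired with its
inducing source) on that source, in biological duplicate. Baselines are
log2-normal (mean 8, sd 1.5; candidate transporter genes mean 9, sd 1,
i.e. detectably expressed on inducing sources), induction multiplies by 8,
a knockout divides the induced level by 4 on the inducing source, and
replicates carry multiplicative 2^N(0, 0.25) noise. The default regulon
plan gives each TF four exclusive targets plus three designed two-TF
overlap genes. Array-probe effects, normalization artifacts and
multi-factor designs are not emulated.

Both generators reproduce identical bytes from identical (config, seed).

## Problem sizes and determinism

The shipped defaults (35-taxon trees, 100 bootstrap replicates in the
bundled config and recovery tests, 2,000-gene expression matrices) were
chosen so a full test run plus the acceptance script complete in well under
a minute on one CPU; the tree stage scales to hundreds of sequences with
500 replicates in minutes. All randomness flows through explicit
`numpy.random.default_rng` seeds; reruns with the same config and seed are
byte-identical (timestamps are confined to the log file).

## Known limitations

* NJ on Poisson distances is a deliberate simplification of ML inference;
  on real, saturated or rate-heterogeneous families, clade boundaries and
  supports can differ from an ML tree. Import an external tree when that
  matters.
* The PSSM scorer has no insert-state emission model or E-values; scores
  are comparable only within one profile. Calibration against known
  positives is what makes the cutoff meaningful.
* The clade rule's maximality, ≥2-candidate and outgroup-exclusion details
  are one consistent reading of "well-supported clades"; nested supported
  clades admit others, which is why every knob is configurable.
* `na` handling applies to the microarray-style filter; the RNA-seq filter
  uses its own floor semantics (FPKM > 10 in at least one condition).
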