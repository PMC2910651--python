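# Methods

This note records the models, parameter choices, numerical conventions, and
known limitations of `crmrank`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Cluster scoring

A PWM is stored as per-position base probabilities derived from counts with
Laplace smoothing, p = (count + c)/(total + 4c), pseudocount c = 0.5 per cell
by default (configurable; c = 0 is allowed for probability matrices). Site
scores are log₂-odds against a 0-order background model; the background
defaults to a strand-symmetrized per-species estimate over that species' full
region set (floored at 1e-4 per base and renormalized), overridable by
uniform. Soft-masked (lowercase) bases score normally; any non-ACGT character
breaks a site but still costs gap penalty inside a window.

The region score is an additive cluster model: the best window maximizing the
sum of a non-overlapping selection of positive-scoring sites (any motif of
the model, either strand; overlapping opposite-strand matches of one locus
count once) minus `gap_penalty` bits per non-site base inside the window,
floored at 0. Probabilistic segmentation scanners reward the same structure —
dense homotypic clusters — through an HMM; the additive form was chosen
because it is deterministic and exactly verifiable against brute-force
enumeration (the suite checks equality to 1e-9 on hundreds of random cases
against an independent chain-enumeration oracle, and the numba batch kernel
against the pure-Python traceback implementation). Consequences of the
additive form: a single strong site is never penalized (its window has no
gaps), appending sequence never lowers a score, and the score is
strand-symmetric.

Defaults: `gap_penalty` 0.1 bits/base — small enough that two typical
implanted sites (~11 bits each) still pay off when ~100 bp apart, large
enough that a window never bridges unrelated hits hundreds of bases apart;
site inclusion requires a strictly positive score; sites are *reported*
(GFF-style output, ablation) above 6 bits, the conventional cluster-scanner
default. Heterotypic models: OR lets all motifs compete inside one cluster;
AND additionally zeroes regions whose optimal cluster lacks any of the
motifs. Ranking is threshold-free: all regions keep their raw scores.

## Rank integration

Per species, regions are ranked by descending score with ties broken
lexicographically by region id — reproducibility is worth more than tie
fairness at the scale involved. Rank ratios use r = R/n (not R/(n+1));
ratios are floored at 1e-12 inside the Q recursion. The joint
order-statistic probability Q (see README for the recursion) is evaluated in
plain float64, which is well-conditioned for N ≤ 16 species (the recursion's
terms are bounded by the r powers over factorials); results are clamped to
[0, 1] and N > 16 is rejected.

A species with no ortholog for a region contributes ratio 1.0 with N held
fixed ("absence of evidence", keeping Q comparable across regions); the
alternative — dropping the species and shrinking N per region — is available
as `missing_policy="drop"`.

Note that Q is *not* uniformly distributed under the null (for N = 2,
E[Q] = 1/3; the suite verifies this together with Monte-Carlo agreement of
Q itself). That is immaterial downstream: regions are simply re-ranked by
ascending Q (ties by reference ratio, then id), and genes inherit their best
region's rank.

## Enrichment

The recovery curve counts gene-set members at or before each rank; members
absent from a ranking are dropped with a logged count. AUC is the step-sum
of the curve over ranks 1..⌊f·n⌋ divided by (m·⌊f·n⌋), with integration
bound f = `top_fraction` = 0.05 by default — the bound is not dictated by the
statistic itself, so it is configurable and recorded in every report
manifest. The z-score standardizes the query AUC against the other library
motifs' AUCs (sample SD, floored at 1e-9); this construction is
self-normalizing across the library, so no separate FDR step is applied.

The expected-recovery curve is the per-rank mean of the control motifs'
recovery curves for the same gene set — not the uniform diagonal — and the
optimal cutoff maximizes the per-rank standardized excess (y − μ)/σ with σ
floored at 0.1, subject to at least 3 recovered genes (preventing one-gene
"leading edges"); ties take the smallest rank, and "no rank with 3 recovered
genes" is a reported no-cutoff outcome, not an error. Motifs at z ≥ 2.5 are
flagged as significant but never filtered.

## Synthetic bundles

The generator produces the statistical structure the method assumes, as a
pure function of its spec (including the seed): i.i.d. background sequence
(default uniform base composition, 1,000 genes × 1 region × 1,000 bp);
homotypic clusters of 3 sites sampled position-wise from the implant PWM,
placed without overlap inside one random 300-bp window of each of 50 target
regions at random strands; 3 further species produced by per-base
substitution at rate 0.25 outside logged sites and 0.03 inside them
(uniform over the 3 alternatives, no indels — orthology stays positional and
needs no alignment machinery); optional per-cell ortholog dropout; and a
"coexpressed" set of the targets diluted with random non-targets to a 50%
contamination fraction, emulating the direct/indirect mixture a perturbation
experiment yields.

The default implant motif is a proneural-shape E-box matrix (RACASCTGY-like:
six sharp core columns, three two-base degenerate columns, ~11 bits total).
This shape matters: with a near-deterministic matrix every column of which
carries ~1.9 bits, a single species already separates targets from
background almost perfectly and cross-species integration has nothing left
to add; with the realistic matrix, single-species background hits compete
with true clusters and the conservation signal carries measurable weight —
which is the regime the method exists for. Sampled sites still clear the
6-bit report threshold ≥ 90% of the time (measured in the suite).

What the generator does **not** emulate: phylogenetic tree structure
(species evolve independently from the reference), indels and alignment
uncertainty, chromatin accessibility, heterotypic co-binding, non-uniform
genomic base composition, and gene-length biases. Passing tests therefore
demonstrate the statistical machinery end to end — not performance on real
genomes, where orthology quality and background composition dominate.

Site ablation generalizes the classic E-box disruption (CANNTG → CGNNCG):
the motif's two highest-information columns (ties broken toward the motif
center, then leftmost) are set to the transition partner of their consensus
base (A↔G, C↔T), mapped through the site's strand. For a CANNTG-style
degenerate matrix this reproduces CACGTG → CGCGCG exactly. Overlapping sites
are ablated left-to-right, later overlaps skipped with a warning.

## Problem sizes and determinism

The validation experiments run the default bundle over 10 seeds (and 20
unimplanted bundles for null calibration) with a 50-motif library — about
a minute per bundle on one CPU, dominated by the numba scan/DP kernel. All
randomness flows from numpy `SeedSequence` spawns of the bundle seed;
reports are written with fixed column order and 4-decimal floats so repeated
runs are byte-identical.

## Known limitations

* The additive cluster score is not a probability; scores across motifs of
  different lengths are made comparable only through the per-species ranking.
* Upstream regions are fixed-width and not trimmed at neighboring genes;
  overlapping regions of neighboring genes each keep their own rank slot.
* The z-score inherits the noise of the control-AUC spread (49 controls by
  default); with strongly enriched sets the z saturates and differences
  between near-ceiling conditions are dominated by that noise.
* N ≤ 16 species; larger panels would need the log-space recursion.
* The leading edge is a set prediction at a single cutoff; no per-gene
  posterior is attempted.
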