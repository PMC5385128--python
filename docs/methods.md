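# Methods

`codonsel` implements codon-substitution-model inference of selection on
protein-coding genes — the analysis suite typically applied to questions
like "which vision genes diverged between giraffe and okapi, and at which
residues?" — together with an additive spectral-tuning predictor for
mammalian L-opsins and a codon-alignment simulator that generates
study-like data with known truth.

## The codon substitution model

All likelihood machinery rests on a Goldman–Yang-style Markov model on the
61 sense codons of the standard nuclear code (stop codons are excluded
from the state space; the genetic code id is a parameter throughout). The
instantaneous rate from codon *i* to codon *j* is

    q_ij = 0                          if i, j differ at >1 position or j is a stop
    q_ij ∝ π_j                        single-position synonymous transversion
    q_ij ∝ κ π_j                      synonymous transition
    q_ij ∝ ω π_j                      nonsynonymous transversion
    q_ij ∝ ω κ π_j                    nonsynonymous transition

with κ the transition/transversion rate ratio, ω = dN/dS the
nonsynonymous/synonymous rate ratio, and π the equilibrium codon
frequencies. The chain satisfies detailed balance by construction, and
P(t) = exp(Qt) is computed through the eigendecomposition of the
symmetrized matrix D^{1/2} Q D^{-1/2} (D = diag π); a generic
scaling-and-squaring path exists as a cross-check and the two agree to
1e-9 in the tests.

**Frequencies.** π is estimated from the alignment under F3x4 by default
(position-specific nucleotide frequencies, renormalized over sense
codons); F1x4, equal, and observed-codon-proportion schemes are available.
Frequencies are floored at 1e-10 and renormalized before symmetrization so
that codons absent from a small alignment do not break the decomposition.

**Rate scaling across site classes.** A single rate matrix is scaled to
one expected substitution per codon per unit branch length, so branch
lengths are in expected substitutions per codon. In mixture models the
classes on a branch share one normalizer — the mixture-weighted expected
rate of the raw (unscaled) class matrices — so a class with ω = 5
genuinely evolves faster than the purifying class, and only the
class-averaged rate is pinned to the branch length. Normalizing each
class independently (tempting, but wrong) erases exactly the rate
acceleration that the branch-site test is designed to detect. The
simulator uses the identical convention, the site-wise ω scan calibrates
every candidate matrix at the M0 rate, and grid-averaged posteriors hold
the normalizer at the MLE.

## Site-class models

| model | classes | partition structure |
|---|---|---|
| M0 | 1 | one ω everywhere |
| free-ratio | 1 | independent ω per branch, shared κ |
| M2a_rel | 0 < ω0 < 1; ω1 = 1; ω2 > 0 | ω identical across partitions |
| CmC | as M2a_rel | third class: background ω2, foreground ω3 |
| branch-site A | ω0, 1, 2a, 2b | 2a/2b take ω2 on the foreground; alt ω2 ≥ 1 free, null ω2 = 1 |

Branch-site A proportions use the standard parameterization: free p0, p1,
with the remainder split over 2a/2b in ratio p0 : p1. The
foreground/background partition comes from PAML-style `#1` labels in the
Newick input; everything unlabeled is background.

## Likelihood, optimization, and the two-stage branch-length scheme

Site likelihoods are computed by Felsenstein pruning, vectorized over
columns and classes, with per-node rescaling against underflow (the
contract is agreement with a brute-force enumeration over internal-node
states on 4-taxon trees, to 1e-8). Gap and missing codons (any triplet
containing N or partial gaps) contribute all-ones partial vectors,
equivalent to marginalizing them out.

Fitting maximizes the mixture log-likelihood with L-BFGS-B on transformed
parameters: log scale for κ, ω and branch lengths, logit-scale
stick-breaking coordinates for mixture proportions. Box bounds: ω ∈
[1e-6, 999] (branch-site alternative ω2 ∈ [1, 999]), κ ∈ [1e-3, 999],
branch lengths ∈ [1e-8, 60]. Mixture surfaces are multimodal, so fits
restart from seeded, dispersed starting points and keep the best optimum;
non-convergence is reported in a flag, never silently.

Branch lengths are handled in two stages: the M0 fit optimizes them
jointly with κ and ω; site-class models then hold them fixed (optionally
adding one global multiplicative rescale, or full joint optimization on
request). This is a deliberate, cheaper approximation to re-optimizing
every length under every model; because both members of each nested model
pair are fitted under the same scheme, the LRT comparison is internally
consistent. For the hypothesis tests the alternative model is additionally
started from the null optimum (a valid point of the alternative), which
guarantees nesting up to optimizer noise, *plus* from the default
dispersed starts, which rescues cases where the null optimum is a
degenerate trap for the richer model.

## The selection tests

- **Branch-site test of positive selection**: branch-site A alternative
  vs null, LRT referred to χ²(1). The null fixes a boundary parameter, so
  χ²(1) is conservative; a flag switches to the 50:50 point-mass/χ²(1)
  mixture null.
- **Clade-model test of selection divergence**: CmC vs M2a_rel, LRT df = 1.
  Sites with divergent-class posterior above 0.75 are flagged.
- **Empirical-Bayes site posteriors**: `neb` (default) evaluates class
  posteriors at the MLEs — exactly checkable by hand from the cached
  per-class site likelihoods; `beb-grid` averages them over a discrete
  grid (uniform prior over grid points, weighted by data likelihood) on
  the stick-breaking proportion coordinates and the focal-class ω, other
  parameters held at their MLEs, 10 points per axis by default. This
  accounts for parameter uncertainty in the spirit of Bayes empirical
  Bayes while remaining cheap and fully documented.
- **Free-ratio dN/dS**: per-branch ω with shared κ. With Q normalized to
  unit rate, a branch of length t at ratio ω_b accrues t·ρN nonsynonymous
  and t·ρS synonymous substitutions per codon (ρ = flux proportions at
  ω_b); the site counts per codon are 3f_N and 3f_S with f the flux
  proportions at ω = 1 (mutational-opportunity convention). Then
  dN = t·ρN/(3f_N), dS = t·ρS/(3f_S), and ω_b = dN/dS identically.
- **Site-wise ω**: per-site 1-D ML over ω with κ and branch lengths fixed
  from M0, maximized on a two-stage log grid (coarse sweep over
  [1e-6, 999], then a 17-point refinement inside the coarse bracket; the
  transition matrices are shared across sites, which is what makes the
  scan cheap). LRT against ω = 1 per site; all-gap sites return NaN.
- p-values are raw per-gene by default (α = 0.05); Benjamini–Hochberg
  adjusted values across genes are available and labeled `p_BH`.

## Ancestral reconstruction

Marginal posteriors over codon states at any node by the up-down
algorithm per site class, averaged with the per-site class posteriors.
Checked against a direct Bayes computation over joint internal-state
assignments on 4-taxon trees (1e-9). MAP codons are reported with their
amino-acid translation, supporting residue-history narratives (e.g.
tracing a codon through successive ancestors).

## The simulator and what passing tests show

`simulate_alignment` draws a class per site, a root codon from π, and
evolves states down the tree with the class- and partition-appropriate
transition matrices; the RNG stream is consumed in a fixed order (site
classes, root states, branches in preorder), so a seed fully determines
the output. Truth records keep per-site classes and all ancestral states.
Indels are not simulated; an optional masking rate injects gap tokens to
exercise missing-data handling.

The study-like presets use an 8-taxon tree spanning mammalian orders
(terminal branches 0.12–0.45 expected substitutions per codon, total
length ≈ 2.3) with a foreground *clade* — target taxon, sister, and their
stem — matching how clade-model partitions contrast a focal lineage
against the background. Within densely sampled shallow clades real
per-branch divergences are much smaller, but with only 8 taxa spanning
orders, ordinal-scale branches are the realistic magnitude. Preset
parameter values sit in the ranges reported for mammalian vision genes:
purifying majority class ω ≈ 0.05 on 75–90% of sites, divergent class
p2 ≈ 0.05–0.2 with background ω < 1 and foreground ω up to 3, positive
selection at ω = 5 on ~10% of sites.

What the simulator does *not* emulate: indel evolution, alignment error,
codon-usage bias beyond π, synonymous-rate variation, and lineage-specific
κ. Passing recovery and power tests therefore demonstrate correctness of
the inference machinery under the model's own assumptions, not robustness
to real-data violations of them.

Operating characteristics at the preset conditions (8 taxa, one
foreground clade): the clade-model test rejects in ≥ 80% of replicates at
600 codons with p2 = 0.2, ω2 = 0.1, ω3 = 3, and its type-I error on
300-codon null data is consistent with the nominal 0.05 by an exact
binomial check. The acceptance suite runs these at 10 power and 20 null
replicates — sizes chosen to keep a complete run at desk scale while the
binomial pass bars remain the exact equivalents of the full-replicate
rates.

## Five-sites spectral tuning

The predictor anchors the SHYTA genotype at 560 nm and subtracts additive
shifts for the low alternatives: S180A 7, H197Y 28, Y277F 8, T285A 15,
A308S 16 nm. Prose accounts of the rule sometimes give 7 nm for Y277F,
but the published per-genotype predictions (seal SHFTA = 552 = 560 − 8)
and the spectral-tuning literature are consistent with 8 nm, which this
package uses; the all-low genotype AYFAS therefore predicts 486 nm.
Residues outside a site's two allowed alternatives yield an explicit
"prediction unavailable" naming the site — the rule is defined only on
those alternatives, and guessing would be worse than declining.

Genotypes are read off query sequences through a pairwise alignment to an
annotated reference (BLOSUM62 global alignment, gap open −11 / extend −1),
so indels in a species' sequence do not shift the site numbering. The
bundled reference is a synthetic, deterministically generated sequence
carrying the canonical residues at the annotated positions — suitable for
tests and examples; real analyses should supply a real annotated
reference. Site 233 (S/T) is extracted and reported because it is
spectrally interesting (transmembrane domain 5, near the chloride-binding
region) but never enters the prediction: its shift is not established.

## Numerical and design choices, in brief

- Degrees of freedom are 1 for both LRTs, following the standard
  procedure for these model pairs; the boundary caveat for the
  branch-site null is documented above and the mixture null is available.
- Optimizer restarts default to 3 for standalone fits and 2 within the
  test wrappers (where the null-optimum start adds a third effective
  start).
- Internal-node support values in Newick input are ignored with a
  warning; missing branch lengths default to 0.1 with a warning (useful
  for topology-only input followed by joint optimization).
- Rerooting merges the two root-adjacent half-edges when the old root
  becomes degree-2 (summing lengths, foreground if either half was), so
  total length, leaf-to-leaf distances, and reversible-model likelihoods
  are invariant — all tested explicitly.
- Column filtering offers both an `all-gap` policy (drop columns with no
  sense codon) and a conservative `any-gap` policy (drop columns with any
  gap/missing state), since tools differ in how they treat gapped columns;
  `all-gap` is the default and a provenance map of kept columns is
  returned.
- The two-decimal agreement of χ²(1) tail probabilities with published
  LRT→p pairs (5.3→0.02, 4.7→0.03, 4.1→0.04, 2.8→0.09, 1.6→0.2, 0.7→0.4)
  is asserted in the acceptance tests.

## Known limitations

- No per-branch-length re-optimization under every site-class model by
  default (available via `branch_mode="joint"`, untested at scale).
- No site models M7/M8, no synonymous-rate variation, no empirical codon
  exchangeabilities, no mutation-selection models.
- The BEB grid is a documented approximation, not PAML's exact scheme;
  NEB is the default and the hand-checkable mode.
- ω estimates of very small classes on short foreground branches are
  weakly identified and can run to the upper bound (999); the LRT remains
  well behaved, but point estimates at the bound should be read as
  "large", not as measurements.
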