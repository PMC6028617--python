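# Methods

## Accessible surface area

ASA is computed with the Shrake–Rupley method: each atom is inflated by
the probe radius (default 1.4 Å, a water molecule) and sampled with a
golden-section spiral of test points (default 960); a point is occluded
when it lies within the inflated radius of any other atom, and
ASA = (exposed fraction) × 4π(r + probe)². Van der Waals radii are a
fixed Bondi-style table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80
Å; anything else 1.70 Å with a warning), so results are reproducible
rather than tied to an undocumented server default. Hydrogens are used
if present in the input and can be excluded with a flag; typical
crystallographic files have none.

Two numerical choices matter:

* **Local quadrature frames.** The spiral is oriented per atom in a
  frame built from its nearest and second-nearest neighbours
  (distance-then-index ordering, distances rounded to 10⁻⁶ Å so that
  symmetric neighbourhoods tie-break identically after a rigid motion).
  Because the frame co-rotates with the coordinates, total and per-atom
  ASA are invariant under rigid transforms to floating-point roundoff —
  not merely to sampling error. The flip side is that adding an atom
  inside another atom's 6-nearest neighbourhood may re-orient that
  atom's quadrature and shift its ASA estimate by a few points
  (≈0.13 Å² each at 960 points) even though true ASA can only decrease;
  the tests allow exactly that much. A finite point sample cannot make
  both properties exact simultaneously; exact rigid-transform invariance
  was chosen as the stronger contract.
* **Occlusion slack.** A point is occluded when d² ≤ r² + 10⁻⁹ Å², so
  exactly coincident atoms deterministically occlude each other.

At 960 points the isolated-sphere case is exact by construction and the
two-touching-spheres analytic case (spherical caps) is reproduced to
better than 1%; agreement with an independent Shrake–Rupley
implementation (biotite) on a 50-residue synthetic globule is within 2%
per residue at high point counts, with a 0.5 Å² absolute floor for
near-buried residues whose relative error is ill-conditioned.

## Shells, composition and group statistics

Residues with total ASA ≥ 5 Å² form the outer (surface) shell, the rest
the inner (core) shell; the threshold is inclusive. Compositions are
percentages of the 20 standard residue types within a shell, computed
per structure; UNK residues are excluded from numerator and denominator,
and an empty shell propagates as missing rather than as zeros so group
means are not biased. The statistical unit is the structure: group
comparisons run the Kruskal-Wallis test (tie-corrected, χ² reference)
per residue type across groups of per-structure percentages, followed by
Dunn's pairwise z tests with Bonferroni adjustment by default
(configurable: none / bonferroni / holm — the classical Dunn
recommendation is Bonferroni). All-identical samples return H = 0,
p = 1 by convention. Enrichments are reported as signed percent
differences of group means against a control group
(100·(g − c)/c; −72% reads "72% decrease").

## Structure comparison

Chains are paired by global Needleman–Wunsch alignment (BLOSUM62, gap
open 10, extend 0.5, terminal gaps free — EMBOSS-needle-like defaults);
identity is computed over alignment columns between the first and last
aligned pair, so internal gaps count against identity and overhangs do
not. Aligned residue pairs with both Cα atoms present enter a Kabsch
least-squares superposition; reflections are excluded by sign-correcting
the smallest singular value, so the rotation is always proper. Domain
RMSDs use an independent fit per domain. Domain boundaries are user
configuration (author-numbering ranges per structure); when no published
boundaries exist, a spectral bisection of the Cα contact graph (8 Å
cutoff, Fiedler-vector sign) yields a two-domain split, and ranges can
be projected between structures through the alignment. Centre-of-mass
distances default to unweighted Cα centroids, with atom-mass weighting
behind a flag; on compact domains the two conventions differ by well
under 1 Å.

## Ancestral reconstruction

The model is CpREV (chloroplast-derived empirical exchangeabilities and
frequencies, bundled as a plain-text file), normalised to one expected
substitution per unit branch length and satisfying detailed balance.
P(t) = exp(Qt) is computed by eigendecomposition of the π^{1/2}-scaled
symmetric form, which is stable for reversible models. Likelihoods use
Felsenstein pruning with per-site rescaling; gaps and ambiguity codes
are missing data (partial likelihood 1 in every state). Marginal
posteriors at an internal node combine inside (subtree) and outside
partial vectors; because the model is reversible the root placement does
not affect them, and rerooting leaves log-likelihoods unchanged to
1e-10 in the tests.

Reconstruction is empirical Bayes with fixed model parameters. Given a
posterior tree sample, the leading burn-in fraction is discarded, the
target node is mapped across trees by its exact descendant leaf set, and
per-site posteriors are averaged arithmetically over the trees
containing the clade (the coverage fraction is reported). Sample-size
bookkeeping follows total = runs × generations / sampling frequency
(floored when not divisible) and retained = round(total × (1 − burn-in)).
The max-posterior residue is taken per column, with exact ties broken
lexicographically by one-letter code for determinism.

Gap handling follows the parsimony-correction idea: each column is
coded present/absent at the leaves and a two-state Sankoff up/down pass
yields the set of most-parsimonious states at the target node; columns
whose only most-parsimonious state is "absent" are deleted from the
final sequence. Ambiguity resolves to present — the correction is meant
to remove confidently absent positions, not to second-guess columns
with substantial support. With a tree sample, the per-tree verdicts are
combined by majority, ties again resolving to present.

Site-rate heterogeneity is off by default (plain CpREV); a discrete
gamma option (4 equal-probability categories, category means) is
available behind a flag.

## Synthetic data

The globule generator emulates just enough of a packed protein for the
shell pipeline to be testable against planted truth. Beads (one per
residue) are rejection-packed inside a sphere of radius
1.5 · 1.9 Å · n^{1/3} with a 3.8 Å minimum separation (Cα-like spacing,
~30% sphere volume fraction — below random-sequential-addition jamming).
Each residue is rendered as its Cα plus a tetrahedron of filler carbons
at 1.7 Å, because a single sphere per residue at protein-like spacing
leaves probe-sized voids everywhere and buries nothing; the filler
cluster reproduces the qualitative feature that matters, a genuinely
solvent-inaccessible interior. One class-bearing pseudo side-chain atom
(O for acidic/polar-O types, N for basic, S for Cys/Met) sits 2.5 Å
from the Cα, pointing radially outward for surface residues and inward
for core residues, so the charged/polar ASA classes are exercised.
Residues deeper than 4.0 Å below the sphere surface draw their type
from the core composition, the rest from the surface composition. A
depth rule (rather than a fixed radius fraction) is used because the
solvent-burial horizon of a packed sphere sits at a roughly constant
depth regardless of size; with these defaults the ASA-based shell call
matches the planted label for ≈95% of residues across seeds, the
residual disagreement being genuine boundary residues. Default
compositions give a hydrophobic interior and a polar/charged exterior;
they are generator conventions, not estimates. Everything is
deterministic given the seed, which is stamped into output headers.

The sequence simulator draws a root from the model's equilibrium (or
takes one), samples substitutions per site from P(t) along each branch,
and applies indels as a Poisson process (rate per site per unit branch
length) with geometric lengths, insertions and deletions equally
likely, resolved left-to-right. Insertions create fresh alignment
columns spliced next to their anchor, so the output alignment contains
the true aligned sequences of every internal node. What the simulator
does not emulate: rate variation across sites (unless the gamma flag is
used downstream), indel rate variation, selection, or any
structure-sequence coupling — so passing tests demonstrate algorithmic
correctness under the model, not robustness to model misspecification
on real data.

## Validation problem sizes

The test-suite simulations use sizes chosen to give stable statistics
at interactive runtimes: 20 globules of 500 residues for
planted-composition recovery (recovered surface-Lys enrichment within
3 SE of the planted value), a 16-leaf / 200-site / depth-0.3 simulation
for root recovery (≥90%), and an 8-leaf / 4000-site / depth-1.2
simulation for posterior calibration (sites with max-PP in [0.7, 0.8)
are correct 70–80% of the time within a 3σ binomial band).

## Known limitations

* The charged/polar atom-class rules are a documented reconstruction of
  the conventions used by structure-annotation servers, which do not
  publish exact definitions; comparisons against numbers produced by
  such servers are therefore qualitative.
* The deposited-structure comparison (1U2X vs 6C8Z) requires the PDB
  files to be supplied locally; domain boundaries for real kinases are
  best given explicitly, with the automatic contact-map split as a
  fallback.
* Ancestral reconstruction consumes tree samples; it does not run the
  Bayesian tree search itself, and joint (as opposed to marginal)
  reconstruction is out of scope.
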