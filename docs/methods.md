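# Methods

`cyclodelim` implements an integrative species-delimitation workflow of the
kind used for cryptic land-snail complexes: two independent molecular
delimitations (distance-based and tree-based) are intersected into
conservative "mutual groups", species are assembled from those groups under
an explicit merge rule, each species receives a character-based DNA
diagnosis, and shell form is characterised by outline morphometrics plus an
interval classifier on caliper measurements. This note records the models,
the numerical choices, and what the synthetic data do and do not emulate.

## Distances and the barcode gap

Pairwise genetic distances are computed from an aligned barcode fragment
under the p, JC69 or K2P model with pairwise deletion: a site enters a
pair's counts only when both sequences carry a determinate base there.
K2P is the default — the customary choice for COI barcodes; the source
analyses do not pin the model down, so all three are selectable and the
choice is recorded on the matrix. Transitions are A↔G and C↔T; ambiguity
codes never enter the transition/transversion counts. A saturated pair
(logarithm of a non-positive argument) is an error unless a ceiling value
is supplied.

The barcode gap is located on the sorted vector S of all pairwise
distances. Given a prior limit on intraspecific divergence P and a
relative gap width X, the scan starts at the first distance exceeding P
(never before the third value) and returns the midpoint of the first
consecutive jump S[i] − S[i−1] that exceeds X times the mean spacing of the
distances below S[i−1] (mean of all spacings seen so far when fewer than
three are available). Absence of a gap is a valid result. This statistic
is deliberately simple: deterministic, order-free, and verifiable by
direct inspection of the sorted distances. It reproduces the known
behaviour of barcode-gap methods, including oversplitting when P sits
below the intraspecific maximum — which is precisely why the prior is
scanned (ten log-uniform values from 0.001 to 0.1 by default; the fourth is
0.00464) and the largest P at which the one-shot ("initial") and
recursively refined partitions agree in group count is selected. Groups
are single-linkage components under the threshold (any pair under the
threshold chains conspecificity). Groups with fewer than four members are
never re-split: three or fewer taxa give at most three distances, too few
for a spacing estimate.

## Poisson tree processes

On a rooted tree with branch lengths in expected substitutions per site, a
candidate partition of the tips into species classifies every branch:
branches inside the minimal spanning subtree of a species' tips are
*coalescent*, all others *speciation*. Partitions whose spanning subtrees
share an edge are rejected as non-convex. Within each class, branch
lengths are modelled i.i.d. exponential; the class rates are profiled out
by their MLEs (count / summed length), giving the closed-form profile
log-likelihood Σ_class m(ln(m/S) − 1). Branch lengths are floored at
1e-9 so zero-length branches (soft polytomies) cannot produce an infinite
rate; a class with no branches simply drops out, so the all-singleton
partition degrades gracefully to a one-class exponential fit.

The maximum-likelihood search operates on clade partitions (each species a
clade; the root species may be the whole tree). It descends by best-first
splits all the way to singletons — through likelihood valleys — keeping the
best state visited, then hill-climbs with alternating merge/split passes.
Ties break on node index, so the search is a pure function of the tree; on
every tree small enough to enumerate it has matched the exhaustive optimum
over all clade partitions.

The Bayesian sampler places a flat prior over clade partitions and runs
Metropolis-Hastings with two moves: split a uniformly chosen splittable
species at its root into its child clades, or merge the species under a
uniformly chosen node whose children are all species roots. The Hastings
ratio is the ratio of available-move counts. Defaults are 500,000
generations, 10% burn-in, thinning 100. Support of a tip set is the
fraction of retained samples in which exactly that set is a species; the
reported partition is the most frequently sampled one. On five-tip trees
the sampler's partition frequencies match the exactly enumerated posterior
to within ~1e-3 total variation at 200k generations.

A caveat the tests quantify: at a speciation/coalescent rate ratio of 20
the maximum-likelihood partition genuinely differs from the generating one
in roughly 10–15% of simulated trees (an Exp(1) speciation branch falls
below the merge-profitability length ln r/(r−1) ≈ 0.16 often enough for a
species pair to merge). This is a property of the model at that
separation, not of the optimiser.

## Consensus and species assembly

Mutual groups are the intersection of the distance- and tree-based
partitions: in strict mode, identical membership; in compat mode, a group
of the first partition also qualifies when the second merely splits it into
sub-groups wholly inside it (the provenance records the refinement). Both
modes are provided because published analyses rarely state which reading of
"confirmed by both approaches" they used.

Candidate merges are pairs of mutual groups whose MRCAs are sister nodes on
the phylogeny; the joining node's posterior probability is attached.
Non-monophyletic groups are flagged and excluded. A pair merges into one
species iff its sister support reaches the floor (default 0.83, the
smallest support accepted for a merge in the motivating study) AND the
ranges are adjacent AND the shells are similar. Range adjacency and shell
similarity are judgments supplied by the user — from maps and specimens —
not quantities the module infers; the module mechanizes the conjunction,
closes merges transitively, labels sub-groups I/II within merged species,
and keeps a replayable audit log. A mutual group left untouched is a
species by default, which also covers the case of one mutual group
containing two morphologically distinct sub-groups.

## Diagnostic nucleotide characters

A position (reported 1-based on the 658-bp COI barcode frame) is diagnostic
for a focal species iff (a) every focal individual carries a determinate
base there — gaps, missing data, or ambiguity codes in any focal individual
disqualify the site — and (b) the set of focal states is disjoint from the
determinate states of every other labelled species. Missing data in
non-focal species is ignored: absence of evidence does not break a
diagnosis, but a single determinate shared state does. Multi-state private
polymorphisms are allowed and rendered "pos:G/C"; states are ordered by
focal frequency, then alphabetically. `verify_diagnosis` re-checks a
published diagnosis string against an alignment and names the violating
taxon on failure.

## Shell morphometrics

Outlines are closed 2-D point sequences in apertural view. Resampling
places k = 200 semi-landmarks at equal arc length along the
counterclockwise-normalized polyline, starting at the declared start
landmark or, for synthetic/generic outlines, at the point of maximum x
(ties: minimum y, then lowest index) — a geometric stand-in for the
biological "widest point of the aperture on the right side", which cannot
be computed without aperture annotation. Semi-landmarks are treated as
fixed landmarks; no sliding step is applied.

Generalized Procrustes analysis centres each configuration, scales it to
unit centroid size, and iteratively rotates it to the running consensus
(proper rotations only — reflections are deliberately not removed).
Because the consensus has a free global rotation, its orientation is
gauge-fixed to the first standardized configuration each iteration;
convergence is declared when the gauged consensus moves less than 1e-8,
with a warning (and a partial result) after 100 iterations otherwise.

Procrustes coordinates have rank at most 2k − 4, so CVA first reduces the
aligned coordinates by PCA to rank min(n − g, 2k − 4) (further capped at
the numerical rank), then solves the generalized eigenproblem of the
among-group covariance (divisor g − 1) against the pooled within-group
covariance (divisor n − g). min(g − 1, rank) axes are retained and the
per-axis percentage is the eigenvalue share over those retained axes —
the definition is stated here because ordination software is not uniform
on it.

Shell size is the absolute shoelace area of the semi-landmark polygon
(self-intersection is flagged, not fatal), summarised per group as a
five-number summary. The morphotype classifier is the published interval
rule on caliper height H and breadth B in mm: *widespread* iff 23 ≤ H ≤ 31
and 28 ≤ B ≤ 35; *deviating* iff H < 21 or H > 33 or B < 26 or B > 37;
*slightly deviating* otherwise. The three regions tile the positive
quadrant; boundary values of the widespread class are inclusive. Only H
and B enter the rule — the qualitative shape wording of the morphotype
definition is not mechanized.

## Synthetic data

All generators are pure functions of their configuration (same seed ⇒
identical bytes).

*Sequences*: K species, n individuals each, length 658. Species centroids
diverge independently from a random root with per-site substitution
probability π_between/2 (symmetric, Jukes-Cantor-like), individuals from
centroids at π_within/2; defaults π_within = 0.01 and π_between = 0.15
emulate typical intra- vs interspecific COI divergence in land snails
(separation ratio 15). m_d = 2 private diagnostic sites per species are
planted: constant within the species, a single shared state elsewhere.
Independent centroid divergence also creates incidental fixed private
background states; at each such site one individual of the affected
species receives an ambiguous call (N), rotated across individuals. This
emulates the scattered ambiguous calls of real chromatograms, disqualifies
the site under diagnostic rule (a), and leaves pairwise-deletion distances
essentially untouched — so the planted sites are, by construction, the
alignment's only diagnostic characters. No indels, no rate heterogeneity,
no homoplasy between planted sites: passing tests show the pipeline's
bookkeeping and decision rules are correct, not that the method is robust
to model misspecification on real data.

*Trees*: a random-join species topology with Exp(λ_sp) branch lengths
(default λ_sp = 1), random-join within-species subtrees with Exp(λ_co)
lengths (default λ_co = 20, i.e. rate ratio 20 — interspecific branches an
order of magnitude longer than intraspecific ones, as in barcode gene
trees). The generating partition is returned as truth.

*Outlines*: ellipse-based closed curves (breadth B drawn normal per group,
height = aspect·B) with a sin 2θ spire term and optional isotropic
landmark noise; height/breadth are measured from the generated curve's
bounding box. Real shell outlines are not ellipses; the generator's job is
controlled group separation in shape and size, not realism.

*Measurements*: (H, B) pairs drawn uniformly within each morphotype
class's defining region (rejection-sampled at the class boundaries), with
the default composition 92/26/21 mirroring the morphometric dataset the
workflow emulates.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the generators at K = 3–4
species × 5 individuals (sequences, 20 seeds), 20-tip trees (ML recovery,
50 seeds), 120-tip trees (rate recovery, 50 seeds), a 5-tip tree with the
fully enumerated posterior (sampler calibration, 200k generations), and
18 outlines × 200 semi-landmarks (morphometrics) — sizes at which every
reference quantity can be recomputed exactly or by enumeration.

## Known limitations

- The gap statistic is an approximation of the published barcode-gap
  procedure, not a numerical re-implementation of any particular binary;
  only the qualitative behaviour (prior scan, initial/recursive agreement,
  oversplitting at small priors) is reproduced.
- The sampler explores clade partitions; a paraphyletic "root species" is
  representable in the likelihood (via branch classification) but is not
  proposed as a distinct MCMC state.
- CVA percentages depend on the stated axis-retention convention and will
  not numerically match software using a different one.
- Outline interpolation for damaged shells, landmark sliding, GIS range
  analysis and nomenclatural bookkeeping are out of scope.
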