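# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `inteinscan`.

## Insertion-element detection

An alignment column's *occupancy* is the fraction of rows with a non-gap
residue. An insertion element is reported for every maximal run of at least
`min_block_len` (default 30) consecutive columns with occupancy at most
`max_occupancy` (default 0.5) whose `flank_width` (10) columns on each side
average at least `flank_occupancy_min` (0.8). Occupancy is computed over
*all* rows, not over carriers: the patchy presence of the element is itself
the detection signal, and the conserved flanks encode the requirement that
the element sits at a fixed site inside an otherwise alignable host region.
Carriers are rows with at least `min_span` (0.5) non-gap fraction inside the
block; blocks with fewer than `min_carriers` (2) carriers are dropped. The
defaults separate elements of the kind studied here — tens to hundreds of
residues, present in a minority of a family — and are all exposed as
function arguments. Raising `max_occupancy` can only extend or merge
detected runs, never remove one (monotonicity; property-tested).

Elements that invaded (nearly) the whole family have no low-occupancy
signature and are invisible to this scan by construction.

## Substitution models and likelihoods

Empirical exchangeability matrices (WAG, BLOSUM62, VT, HIVb, LG, JTT,
Dayhoff) are combined with model or empirical (`+F`, Laplace pseudocount 1)
frequencies into a reversible rate matrix normalised to one expected
substitution per site per unit branch length. Rate heterogeneity uses the
discrete gamma approximation with four equal-probability categories
represented by their category means (computed from regularised incomplete
gamma functions), optionally with a proportion of invariant sites; the
mixture is renormalised so the mean rate stays exactly 1. Free-rate models
are not implemented; where a published analysis selected one, `+G4` (with
`+I` when appropriate) is the stand-in, which changes likelihood values but
not the qualitative behaviour of distance correlations or topology tests.
The Q.pfam exchangeability table is not bundled, so that model name is not
available.

Likelihoods use Felsenstein pruning with per-category log-scaling and
site-pattern compression. Gaps and `X` are missing data (all-ones tip
partials); an all-gap column contributes exactly zero log-likelihood.
Transition matrices come from a symmetrised eigendecomposition of Q (cached
per model), so `P(t)` costs one 20×20 congruence per rate category.

Branch lengths are optimised edge by edge: for a focal edge the conditional
likelihoods of the two half-trees are cached, reducing the per-site
likelihood to a 20-term exponential sum in the edge length, which a bounded
Brent search (bounds `[1e-8, 15]`, `xatol 1e-7`) optimises cheaply. Sweeps
repeat until the total log-likelihood improves by less than `tol` (default
0.01; tests that compare against oracles use `1e-6`). The total never
decreases across sweeps (asserted in tests).

## Distances, NJ, tree search

Pairwise ML distances maximise the two-sequence likelihood over the branch
length (pairwise deletion of gapped columns; coarse geometric-grid
bracketing followed by bounded Brent, `xatol 1e-6`). Distances are capped at
`d_max = 15` substitutions/site; pairs with no shared columns are imputed at
the cap with a warning. Patristic distances are path sums on a tree; both
are available because published distance-correlation analyses are ambiguous
about which variant they used — direct pairwise estimates are the default
and tree-path distances are a flag away.

Neighbor joining follows Saitou–Nei with deterministic lexicographic
tie-breaking on the smallest taxon labels of the joined clusters and
negative branch estimates clamped to zero; it recovers additive matrices
exactly (property-tested against random trees, and cross-checked against
scikit-bio's implementation on one instance).

The ML search starts from the NJ tree on ML distances and hill-climbs over
nearest-neighbor interchanges. Candidates are scored by re-optimising only
the rearranged central edge against cached partials; the best candidate is
then fully re-optimised. Near convergence, the top three candidates are
verified with full optimisation before the search stops, which in practice
closes the gap to the exhaustively enumerated optimum at six taxa to below
1e-6 lnL. A clan constraint (one or several disjoint taxon sets) is
enforced by a constraint-respecting NJ start — each clan is collapsed to a
supertaxon under mean linkage, then re-expanded as an NJ subtree rooted at
its attachment — and by rejecting any NNI whose result violates a clan.
Constrained likelihoods can therefore never exceed the unconstrained
optimum (asserted).

Bootstrap support is the standard nonparametric column resample: NJ on ML
distances per replicate, support = percentage of replicates containing each
internal bipartition of the reference tree.

Model selection fits each candidate on one fixed NJ topology, alternating
branch-length sweeps with bounded scalar optimisation of the gamma shape
(`[0.05, 20]`) and invariant proportion (`[0, 0.95]`), and ranks by
`BIC = k·ln n − 2·lnL` with k counting branch lengths plus free model
parameters (`+F`: 19, shape: 1, p_inv: 1) and n the alignment length.

## Topology tests

All tests consume a table of per-site log-likelihoods for candidate trees
(branch lengths optimised per tree beforehand) and resample site indices
with replacement (RELL), applying the same draws to every tree.

* **KH**: the observed difference between the higher- and lower-likelihood
  tree is compared against the centred bootstrap distribution of that
  difference (one-sided).
* **SH**: each tree's replicates are centred on its own mean; the per-
  replicate maximum over trees yields the null distribution of
  `lnL_best − lnL_t`. SH is conservative relative to KH (asserted on
  simulated tables).
* **AU**: at scales 0.5–1.4 (step 0.1, 10,000 replicates per scale by
  default) the bootstrap proportion BP(s) of a tree being best (exact ties
  split equally) is clamped to `[1/(2B), 1−1/(2B)]` and fitted by weighted
  least squares to `Φ⁻¹(1−BP(s)) = d·√s + c/√s`, with binomial weights on
  the probit scale; `p_AU = 1 − Φ(d−c)`. Scales whose BP sits at the clamp
  carry no information about the boundary geometry and are excluded from
  the fit; if fewer than three informative scales remain the tree is
  reported at the clamped bound with a `degenerate` flag.

Rejection is declared at `p_AU < 0.05`, mirroring the 95% confidence-set
convention; KH and SH values are reported alongside.

Type-I calibration uses an exchangeable boundary null: a balanced eight-taxon
tree of four identical cherries (pendant and stem lengths 0.3) whose central
edge is zero in truth, with the focal resolution and its NNI neighbour (each
given the small edge length 0.05, branch lengths held fixed) as candidates.
Exchangeability matters: on random birth-process trees the generating
topology retains a slight average likelihood advantage even with the
internal edge at zero, which makes measured rejection rates conservative and
says nothing about the tests themselves. At the exchangeable null the
measured type-I error at nominal 0.05 is ≈0.05 for KH and ≈0.06–0.08 for AU
over 200 simulations of 300 sites.

## Scenario simulator

The generator emulates a divergent phage protein family carrying insertion
elements with reticulate histories:

* **Host tree**: pure-birth (Yule) process started from two lineages, run
  one extra exponential epoch after reaching n taxa, so the expected
  root-to-tip depth is `Σ_{k=2..n} 1/(λk)`; default birth rate 1 with
  n = 16 gives mean depth ≈ 2 substitutions/site — deep divergence of the
  kind seen in families whose members barely align.
* **Sequences**: root drawn from equilibrium, per-site rates from the model
  mixture, transitions via `exp(Qt)`; elements evolve under the same model
  scaled by `element_model_scale` (default 1, since no element-specific
  model is established).
* **Element histories**: each element originates on `n_origins` branches
  (length-weighted, uniform position); carriers descend vertically;
  transfers occur as a Poisson process at `hgt_rate` per carrier lineage
  per unit time, the donor uniform among carriers and the recipient uniform
  among other contemporaneous lineages (the simplest exchangeable null; a
  transfer into an existing carrier replaces its element). Homing is an
  instantaneous terminal event: one group member's element is copied
  verbatim into every member, reproducing the identical-elements-in-
  diverged-hosts signature directly rather than via a rate process.
  Histories are redrawn (up to 100 times) until the carrier count lies in
  `[min_carriers, max_carrier_fraction·n]` — the simulation is conditioned
  on the element being observable and patchy, which is the regime the
  detector targets.
* **Gene loss** drops a fraction of taxa per cluster from the emitted
  family (homing-group members protected), emulating sporadic distribution
  across phage clusters; losses are logged.
* **Ground truth**: host tree with node times, per-origin element
  genealogies (homing copies attached as zero-length edges), true column
  intervals, carrier sets, and an ordered event log from which carrier sets
  can be independently replayed (tested).

Cluster labels are assigned contiguously along the tree's leaf order, so
clusters are phylogenetically coherent; metadata records a shared location
label for homing-group members. What the simulator does **not** model:
nucleotide-level processes, indels within elements or exteins (alignment is
known and exact, so detection precision/recall of 1.0 on simulated data says
nothing about alignment-induced errors on real families), selection on
element function, within-host population dynamics.

The two canonical study conditions used by the validation protocols are
frozen in `inteinscan.validation`: a *vertical* scenario (single origin, no
transfer) and a *transfer* scenario (two origins — i.e. two element sequence
types — `hgt_rate = 1.5`, and a homing sweep through four hosts scattered
across the tree), both 16 taxa × 300 extein columns with an 80-residue
element. The two-origin choice reflects the empirical situation that
motivated the package, where the intein population comprises two distinct
types whose members sit intermingled among divergent hosts.

## Transfer statistics

R² is the squared Pearson correlation over unordered carrier pairs of
element versus extein distance. Pairs sharing a tip are not decorrelated —
this matches how such correlations are usually computed on distance
matrices — so a Mantel permutation p-value (taxa relabelled, 999
permutations) is attached as a diagnostic. Zero variance raises an error
rather than returning 0. Leave-one-out recomputes R² without one taxon's
pairs; the scan over all taxa reports the exclusion that maximises R² (the
likeliest single outlier). Invasion groups are connected components of the
graph joining carriers whose element p-distance is at most `identity_eps`
(default 0: strict identity), reported when the component has at least
`min_group` (2) members and mean pairwise extein distance at least
`min_extein_divergence` (0.1 substitutions/site). Raising `identity_eps`
can only grow components (monotone). For elements whose copies fall into
two families, the two sides of the longest internal edge of the element
tree are reported descriptively, with no test attached.

## Problem sizes and tolerances in the shipped protocols

Validation protocols run at sizes chosen to exercise the full pipeline:
oracle checks at 6–12 taxa and 150–400 sites; calibration at 200 × 300-site
simulations with 2,000 RELL replicates per scale; scenario recovery at 16
taxa × 20 seeds per arm with 5,000 replicates. `scripts/acceptance.py` uses
the same protocols at slightly smaller counts (3 search-oracle seeds, 150
calibration simulations, 8 scenario seeds per arm). Distance optimisers are
bounded with `xatol 1e-6`; tree-level comparisons against oracles use lnL
tolerance 1e-6; all remaining tolerances are stated where they are used.

## Known limitations

* NNI-only search: no SPR/TBR; adequate at the taxon counts used here, and
  oracle-checked at 6 taxa, but large families may need external tree
  software for the unconstrained tree (any newick tree can be supplied to
  the test suite).
* No free-rate models, partitioned models, or codon/nucleotide support.
* The shuffle significance test permutes whole sequences uniformly;
  composition-window-preserving shuffles are not implemented, so E-values
  for low-complexity sequences are optimistic.
* Real alignments carry alignment error and indels the simulator omits;
  site-set boundaries on real data should be reviewed (the scan's
  column-resolution choices are exposed for exactly that reason).
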