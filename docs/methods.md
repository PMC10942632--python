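# Methods

## Rate model and coordinate system

All statistics live on the branches of a rooted master species tree.  A
gene tree is required to be the master topology pruned to the gene's
species subset; a branch of a pruned tree is identified across genes by
the descendant-species set of the *minimal* master branch whose
descendants, restricted to the gene's taxa, equal the branch's own
descendant set.  This keying is injective, reduces to the identity when
no taxa are missing, and attributes a path merged by pruning to its
leaf-most master branch.  How to attribute merged paths is a genuinely
open design point — nothing in the data distinguishes the candidates —
and the minimal-key rule was chosen for being well defined and
deterministic; trees are used as rooted, with no re-rooting.

## Relative evolutionary rates

Let `l_gb` be gene *g*'s length for branch *b* and `m_b` the genome-wide
expected length of that branch.  The genome-wide lengths are estimated by
alternating two closed-form steps: per-gene scales
`s_g = Σ_b l_gb / Σ_b m_b` (sums over the gene's branches) against a
provisional per-column mean, then `m_b = mean_g(l_gb / s_g)`, refined
once more.  A fixed iteration count keeps the estimate deterministic; the
alternation contracts quickly and further passes change `m_b` by less
than the noise level of any realistic dataset.

The default RER is the centered log-ratio

    RER_gb = ln((l_gb/s_g + ε) / (m_b + ε)) − mean_b(·),   ε = 1e-9

The pseudo-length ε is applied *after* descaling by `s_g` so that
multiplying a gene's branch lengths by any constant leaves its RERs
unchanged exactly, not just approximately.  A second method
(`residual`) uses studentized residuals of `√l` on `√(s_g m_b)` per gene;
both satisfy the same contract — a gene proportional to the master tree
has RER ≡ 0, per-gene mean RER is 0, and missing branches are never
imputed.  The log-ratio default was chosen because its closed form makes
every downstream test independently recomputable by hand.

## Pairwise ERC

For genes *a*, *b*: restrict both RER vectors to branches present in
both; if the two trees share fewer than `min_shared_species = 15`
species the pair is filtered (not an error).  Each restricted vector is
Winsorized with `k = 3` per tail (the three most extreme values condensed
to the fourth), then Pearson-correlated, then Fisher transformed:

    ftERC = arctanh(r) · √(n − 3)

with `n` the shared-branch count and `r` clamped to ±(1 − 1e-12) so the
statistic stays finite at |r| = 1.  The √(n − 3) factor is the inverse
null standard deviation of arctanh(r), which is what makes pairs with
different branch counts comparable; under simulated independence the
empirical ftERC variance stays within a few percent of 1 for
n ∈ {20, 50, 200} even with Winsorization applied.  Winsorization is
applied per pair, to the restricted vectors, because the correlation
must see the condensed values on exactly the branches it uses; applying
it once per gene globally would condense against extremes on branches
the pair does not share.  Pairs left constant after restriction are
filtered with reason "zero variance".

## Gene-set permutation test

A set's statistic is the arithmetic mean ftERC over its unordered in-set
pairs, excluding filtered pairs and, optionally, pairs annotated as
physically interacting (masking isolates the co-functional signal).
Sets need more than four members present in the dataset.  The null is
B = 1000 random sets of the same size drawn uniformly without replacement
from all genes with computed RERs; each null set is scored under the same
filtering rules, and a null replicate with zero usable pairs is redrawn
(and counted).  All permutation p-values in the package use the add-one
convention p = (1 + #{null ≥ observed})/(1 + B): the smallest reportable
value at B = 1000 is 1/1001, and p is never 0.

## Domain-level ranking statistics

Complex members are decomposed into domains (InterProScan-style
intervals, 1-based inclusive; overlapping hits are kept by default, with
an optional sweep-line merge).  All inter-protein domain pairs of a
complex form the edge list, ranked by ftERC descending (ties broken by
domain ids for determinism), with label 1 for annotated physical
contacts.  Intra-protein pairs are excluded from the negative class by
default: same-protein domains share their gene's rate history trivially
and would dilute the contrast of interest; the flag
`include_intra_protein` restores them for sensitivity analysis.

* **ROC-AUC** counts positive-over-negative score pairs with midpoint
  credit for ties; it equals U/(n₀·n₁) identically and the trapezoidal
  area under the tie-aware curve.  Significance is a one-tailed
  Mann–Whitney U test (exact enumeration for tie-free samples with
  n₀ + n₁ ≤ 12, otherwise the normal approximation with tie and
  continuity corrections), alternative: physical pairs rank higher.
* **Permutation null per complex**: the ranked list is fixed and the n₁
  positive labels are reassigned to a uniform random subset of positions,
  B = 1000 times, with the AUC recomputed through the rank-sum identity.
  The study-wide test averages, per replicate, each complex's b-th
  permuted AUC and compares the mean observed AUC against that null.
* **Proportional rank**: within one protein pair with T ≥ 2 inter-protein
  domain pairs, a physical pair at (tie-averaged) rank R scores
  (T − R)/(T − 1) — 1 if ranked first, 0 if last, null expectation 0.5.
  Multiple physical pairs are averaged.  The complex-level null draws,
  per replicate, one uniformly-random label placement per protein pair
  and averages the resulting scores.  Protein pairs with no physical
  annotation, T < 2, or all pairs physical are excluded (the statistic is
  undefined there) and logged.

## Synthetic studies

The generator emulates a large multi-species ortholog dataset.  The
master tree is a Yule (pure-birth) tree: starting from the root's two
lineages, k active lineages wait Exp(k·λ) before a uniformly chosen one
splits, until S lineages exist and receive one final Exp(S·λ) hold.
Under this convention E[total tree length] = (S − 1)/λ exactly, which the
tests check by Monte Carlo.

Rates follow a latent-factor Gaussian model per branch: unit-variance
factors for each module (weight √rho_mod), each designated physical
domain pair (√rho_phys), and each unit's idiosyncratic noise
(√(1 − rho_mod − rho_phys)).  The population branch-wise correlation
between two units is therefore exactly the sum of their shared weights —
the quantity ERC estimates — which is what makes quantitative recovery
tests possible.  Branch lengths are `m_b · exp(sigma_noise · RER)`,
multiplicative log-normal noise around the master tree; species are then
dropped i.i.d. with probability `dropout` and the tree pruned.  All
randomness streams from a single seed with a per-unit counter, so any
unit is reproducible independent of generation order.

Defaults: S = 40 species (comfortably above the 15-shared-species
filter), sigma_noise = 0.3 (pipeline RERs then recover latent RERs with
per-gene correlation ≥ 0.95 when no taxa are missing), modules of 6
members with 2–3 domains per protein, physical protein pairs formed from
consecutive members with one physical domain pair each.  What the
generator does **not** emulate: phylogenetic covariance among branches
(factors are i.i.d. across branches), clustered taxon missingness,
alignment/tree-estimation error, and rate heterogeneity along a single
branch.  Passing calibration and recovery tests therefore demonstrates
the statistical machinery is correct under its own assumptions, not that
real datasets satisfy those assumptions.

## Calibration findings and numerical choices

* The set-level permutation test is calibrated: on a fully null study
  (300 independent background genes) the fraction of 500 random sets with
  p ≤ 0.05 sits inside [0.03, 0.07].
* The domain-AUC label-permutation p-value is uniform under the fully
  null model (rho_mod = rho_phys = 0; KS p ≈ 0.3 over 200 complexes,
  exact 5% tail).  With module correlation present (rho_mod > 0) but no
  physical boost, the p-values become mildly *conservative* (shifted
  toward 1, mean ≈ 0.55 at rho_mod = 0.3): the shared module factor and
  shared-domain structure make edge-list entries dependent, which label
  permutation does not model.  The test never becomes anticonservative,
  so significant complexes remain trustworthy; this behavior is inherent
  to label-permutation on ERC edge lists, not an implementation artifact.
* Monte-Carlo permutation p-values are unbiased for their exhaustive
  counterparts; convergence checks average independent replicates rather
  than relying on a single B = 1000 run, whose own 2·SE band any seed
  misses ~5% of the time by construction.
* Tie handling everywhere is the standard tie-aware choice: midpoint
  counting for AUC, average ranks for proportional rank, tie-corrected
  normal approximation for Mann–Whitney.
* Degenerate inputs fail loudly and specifically: complexes lacking a
  positive or negative class are skipped and listed in the run manifest;
  pairs below the species or branch thresholds carry machine-readable
  filter reasons that the pipeline tallies.

## Problem sizes

The shipped experiments use S = 30–36 species, universes of 100–300
genes, 20–200 replicate modules/complexes, and B = 1000 permutations —
sizes at which every Monte-Carlo margin in the tests is several times its
standard error while a full run of the suite plus the acceptance script
completes in a few minutes on one CPU.  All thresholds
(min_shared_species = 15, winsor_k = 3, B = 1000, member_min = 5) are
surfaced as configuration, none hard-coded.

## Known limitations

* RER estimation is the transparent closed-form variant, not a
  reimplementation of any particular published weighted-regression
  pipeline; phylogenetic GLS corrections are out of scope.
* The 15-species filter is interpreted as shared *species*; the
  shared-branch count is what enters √(n − 3).
* Winsorization condenses 3 values per tail (config-switchable); whether
  the convention should instead be 3 overall is underdetermined.
* Tree estimation from alignments, ortholog inference, and retrieval of
  curated complex/pathway memberships are upstream of this package: it
  consumes newick trees and TSV manifests.
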