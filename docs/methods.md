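# Methods

`campart` quantifies the relative importance of five community assembly
processes — heterogeneous selection (HeS), homogeneous selection (HoS),
dispersal limitation (DL), homogenizing dispersal (HD) and a residual
'drift' class (DR, which also absorbs diversification and weak
selection/dispersal) — from a taxa-by-sample abundance table and a rooted
phylogeny, by running null models within phylogenetic bins and integrating
the bin-level outcomes with abundance weights.  This note records the
model, the numerical choices, and what the simulation benchmark does and
does not establish.

## The partitioning model

**Phylogenetic binning.**  Taxa are partitioned into bins of close
relatives within which niche preference is assumed conserved.  Three
algorithms are provided: distance-to-centroid (most abundant unassigned
taxon absorbs everything within radius `d_s`), pairwise (greedy cliques
with all pairwise distances `< d_s`) and the default tree truncation.  The
tree algorithm takes the coarsest partition of the tree into clades whose
tip-to-tip diameter is `< d_s` (recursion from the root; "as short as
necessary" is interpreted as cutting at internal nodes).  Bins smaller
than `n_min` merge into the bin with the nearest relative (single-linkage
cophenetic distance by default; mean linkage available).  Merged bins lose
their "strict" flag.  Defaults follow the settings used on this kind of
data: `d_s = 0.2`, `n_min = 24` for the simulation benchmark and 12 for
field-scale tables.

Within-bin phylogenetic signal is assessed by Mantel correlation between
within-bin phylogenetic distances and absolute niche-value differences
(the niche value of a taxon is its relative-abundance-weighted mean of an
environmental factor).  A bin passes at Pearson R > 0.1 with one-tailed
permutation p < 0.05; `optimize_nmin` picks the `n_min` maximising the
number of passing bins, breaking ties by higher mean R, then by smaller
`n_min`.

**Null models.**  Selection is read from the beta mean pairwise distance
(betaMPD), the abundance-weighted mean phylogenetic distance between the
bin's members in two communities (self-pairs included; the statistic is
invariant to uniform rescaling of either abundance vector).  The null
shuffles taxa across tree tips; the default scope permutes **within each
bin**.  An across-all-taxa scope is available, but with phylogenetically
compact bins it places every bin's members at random tips, so the null
betaMPD always sits near the whole-tree mean distance and every bin reads
as selection regardless of the data; the within-bin scope is also the one
under which neutral data give betaNRI ~ N(0,1).  Dispersal and drift are
read from bin-restricted Bray-Curtis dissimilarity ranked within a
taxonomic null that preserves each sample's richness exactly and draws
taxa with probability proportional to occurrence frequency, filling
abundances multinomially with mean-relative-abundance weights (each drawn
taxon receives one individual first, so richness is conserved exactly
with integer counts).  The rank is expressed as the modified Raup-Crick
metric RC in [-1, 1], with ties (equality to 1e-9) counting one half.

**Classification.**  Each (sample pair, bin) receives exactly one label:
betaNRI > 1.96 gives HeS, betaNRI < -1.96 gives HoS; otherwise RC > 0.95
gives DL, RC < -0.95 gives HD, and the remainder is DR.  Boundary values
are non-significant.  Because the per-bin null ensembles at realistic
per-sample bin occupancies (a handful of members) are visibly skewed, the
pipeline also provides the *direct* significance test — the observed
betaMPD against the two-sided empirical 2.5%/97.5% quantiles of its own
null ensemble — and the benchmark runs use it (`significance="direct"`);
the standard-effect-size classifier remains the default of `run_icamp`
and the contract of `classify`.

A bin absent from **both** samples of a pair is excluded and the
remaining weights renormalized.  A bin present in exactly one sample has
a well-defined Bray-Curtis of 1 but no phylogenetic information: it is
classified by RC alone (selection is never claimed without phylogenetic
evidence).  Discarding such pair-bins instead would systematically bias
dispersal limitation downward.

**Integration.**  Pair-level importances are the abundance-weighted bin
fractions P(tau|u,v) = sum_k w_uvk W_tau,uvk with w_uvk =
(f_uk + f_vk)/2; they sum to one by construction.  Group-level importance
is the mean over pairs, which equals the abundance-weighted sum of
bin-level importances exactly when no pair-bin was excluded.  Bin
contributions BP are the pair-averaged weighted operators (so they sum to
the group importance), and relative contributions BRP = BP / P(tau).
Stochasticity is the summed importance of HD, DL and DR.

**Entire-community baseline (QPEN).**  The same nulls applied to whole
communities: abundance-weighted beta mean nearest taxon distance
(betaMNTD) standardised against an across-all taxa shuffle (threshold
|betaNTI| = 2, following the conventions of that approach) and
whole-community Raup-Crick Bray-Curtis.  Group importances are fractions
of pairwise turnovers per label.

## The simulation benchmark

The generator produces datasets with known per-pair process expectations:
four plots (LA, LB on a low-value environment; HA, HB on a high-value
one) on two islands (A = {LA, HA}, B = {LB, HB}), six local communities
per plot; every community holds exactly `local_size` individuals of
`richness` species.  Desk-scale defaults: regional pool J = 2e5
individuals, fundamental biodiversity number theta = 500, locals of 2000
individuals and 100 species, 1140-species tree;
`SimulationConfig.full_scale()` restores J = 2e7, theta = 5000 and
20000-individual communities.

**Tree.**  A coalescent genealogy (the n-conditioned limit of a
birth-death process at speciation-extinction equilibrium), rescaled to
unit root-to-tip depth; a forward birth-death simulation is available.
The equilibrium shape concentrates node depths near the tips, giving few
large bins at `d_s = 0.2` (around a dozen for 1140 tips) — the regime in
which per-bin null models retain power with 100-species samples.  A
pure-birth tree instead yields ~30 small bins whose per-sample occupancy
(2-3 members) saturates the bin-wise Raup-Crick metric.

**Trait (niche optimum E in [0, 1]).**  Three regional pools differ in
phylogenetic signal, targeted at Blomberg's K of 0.15 / 0.9 / 5.5:

* medium (MPS): Brownian motion, ancestral state 0.5, reflected at the
  boundaries, diffusion rate 0.15 per unit depth;
* high (HPS): decelerating-rate ("early burst") Brownian motion with the
  rate decaying as g^-t (g = 2000) over unit depth, base rate 40;
* low (LPS): a mean-reverting (Ornstein-Uhlenbeck) trait with stationary
  variance 0.14 and the reversion rate bisected per draw to K = 0.15.
  A mean-reverting model keeps significant signal *within short
  phylogenetic distances* while erasing tree-wide signal — the stated
  property of the low-signal pool; Brownian motion plus white noise (also
  implemented, `lps_model="bm_noise"`) has the opposite profile.

Rates were calibrated once against the K targets on the unit-depth
equilibrium tree (the literature values are tied to a different tree
scale).  A draw is accepted when K lies within +/-50% of the target *and*
the pool holds enough species adapted to each environmental optimum
(default ~2.6% of the pool within 0.05 trait units of 0.05 and of 0.95);
without adapted species a selection regime is unrealizable.  Blomberg's K
is computed from the phylogenetic covariance matrix (observed-to-expected
MSE ratio against the Brownian expectation).

**Process pools.**  Species are assigned to selection / dispersal / drift
pools in the target abundance fractions (tolerance 2%), allocated by
whole bins (`d_s = 0.2`, `n_min = 24`), so close relatives share a
governing process and the default situations are process-pure at the
analysis-bin scale; mismatched grids (the complex-bin robustness mode)
and species-level assignment with `d_s`-ball propagation are options.
Lineages holding environment-adapted members are allocated to selection
first (cheapest adequate lineage per optimum); if whole-bin granularity
cannot reach the target fractions the assignment falls back to species
level with a progressively smaller conservatism radius.

**Community assembly.**
*Selection* is lineage-structured environmental filtering: the selection
part's richness spreads over lineages by pool share; within a lineage the
occurring members are drawn by Gaussian fitness rank
exp(-(EV - E)^2 / (2 sigma_E^2)), sigma_E = 0.015, via Gumbel top-k on
log weights (so fitness ranks survive floating-point underflow), and
individuals follow the same Gaussian across all drawn members.  Each
environment therefore concentrates abundance on its best-adapted lineages
while every lineage stays represented by its best-adapted members — the
structure the within-bin null reads as HoS within an environment and HeS
across environments.  Fully deterministic whole-community filtering is
not detectable even in principle: replicate communities become
taxonomically identical, and a consistent taxa relabeling leaves the
betaMPD of identical compositions unchanged (betaNRI ~ 0) while RC
saturates at -1, i.e. the data would read as homogenizing dispersal.  An
optional per-sample log-fitness lottery (`selection_lottery`) adds
demographic turnover among similarly fit members; it defaults to off.
*Competition* (optional, default fraction 0) ranks competitors by
iterated niche difference nd = sqrt(sum_j 0.5^j (E_i - E_j)^2), the first
drawn at random from the ten best-fitting candidates, with geometric
(0.5^h) abundances.
*Dispersal* builds disjoint island pools (species drawn by metacommunity
weight; island B from the remainder) with Dirichlet-concentrated
abundances (concentration m1 x local size, mimicking strong drift at low
immigration m1 = 0.01); locals draw 99% from their island pool and 1%
from the metacommunity (m2 = 0.99).
*Drift* draws locals from a Dirichlet around the metacommunity with
concentration local_size x m/(1-m), m = 0.5 — the stationary law of
moderate immigration.

**Ground truth.**  Per pair, the expected importance of a process is the
pair-mean relative abundance of the species it governs, with selection
species counting toward HoS within one environment and HeS across,
dispersal species toward HD within an island and DL across, drift species
toward DR (competition species, when simulated, are booked under a
combined selection column and excluded from the HoS/HeS split).  The 15
situations per scenario enumerate all (selection, dispersal, drift)
compositions on a 25% grid.

**What the benchmark does and does not show.**  Simulated communities are
exactly zero-sum, exactly richness-constrained, free of sequencing noise,
and their regional pool is fully observed; passing the benchmark shows the
estimator recovers designed process mixtures under these idealized
conditions, not that it is unbiased on field data (compositional noise,
unobserved taxa, tree error).  Replicate benchmark runs vary noticeably
with the tree and trait seed, particularly in how much between-environment
selection weight is recoverable; the low-signal scenario reproduces the
known degradation (homogeneous selection largely misread as homogenizing
dispersal, inflating stochasticity).

## Statistics

Quantitative agreement uses the two factors of Lin's concordance
correlation coefficient with population (divide-by-n) moments: qACC
penalises location/scale shifts, qPRC is the Pearson correlation.
Qualitative agreement scores dominant-process identification through
one-vs-rest confusion cells per process (a wrong call is one false
positive, one false negative and three true negatives); dominant-process
ties break by the fixed order HeS, HoS, DL, HD, DR and carry a `*` flag.
Method comparison uses a one-sided bootstrap over situations (independent
resampling of the two score vectors, ties counting one half, so identical
methods give p near 0.5).  Cohen's d uses the pooled standard deviation
with the conventional magnitude classes (boundaries belong to the lower
class; the absolute value is rounded to 12 decimals to keep constructed
boundary cases stable).  Group differences use a two-sided
label-permutation test of the mean difference.

Environment linkage works on pairwise matrices (per factor, the |u - v|
difference and the (u + v)/2 mean matrix).  Mantel, partial Mantel
(residualising both matrices on a control) and multiple regression on
distance matrices with forward AIC selection use label permutations that
can be constrained within blocks (e.g. plot identity under repeated
measures; the permutation never moves a sample across blocks).  MRM
predictors are log-shift-transformed (values shifted by the minimum,
zeros replaced by 0.05 x the smallest positive value before the natural
log) and standardised; coefficient p values permute the response matrix
within blocks.  The logit option applies a binomial-type link to
fraction-valued process matrices before correlating — a pragmatic
approximation to a quasibinomial regression on distances.  Raw p values
are reported without multiplicity correction.

## Numerical choices and degenerate inputs

* Null standard deviation of zero makes betaNRI 0 with a warning
  (non-significant).  RC ties count one half after rounding to 1e-9.
* Taxa with zero total abundance are legal table rows (they serve as the
  null reference frame of a known regional pool) and never enter the
  taxonomic null's occurrence draws.
* All randomized operations take explicit integer seeds; orchestration
  spawns per-stage seeds from a master seed (kept below 2^31).
* Degenerate Mantel inputs (zero-variance matrices) return NaN and are
  flagged non-significant.
* The benchmark runs at 200 randomizations per null (the analysis of
  randomization-count sensitivity shows betaNRI at 1000 vs 5000
  randomizations correlates above 0.98; 200 keeps the full three-scenario
  benchmark around four minutes on one core).
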