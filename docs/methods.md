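# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## Pseudo-chronogram construction (`tree.date_tree`)

Community phylogenetics needs branch lengths in time, but megatree
topologies typically come with only a handful of fossil-calibrated node
ages. `date_tree` follows the branch-length-adjustment ("bladj") recipe:

- tips are fixed at age 0; the root at `root_age` (default 137 My, the age
  of the eudicot crown group in the standard angiosperm calibration);
- every internal node named in the age table keeps its age;
- every other internal node is placed so that node ages along the path from
  its nearest dated ancestor to its nearest dated descendant-or-tip are
  evenly spaced by node count. Branch lengths are then age differences.

Implementation detail: nodes are assigned in preorder, each anchored at its
parent's (already assigned) age and its nearest dated descendant, with ties
between equally near dated descendants broken toward the larger age (the
most constraining choice, and a deterministic one). On unbranched chains
this reproduces exact even spacing; on branching paths it additionally
guarantees that ages never increase from root to tip, which a purely
per-node interpolation cannot (two nodes on one path may disagree about
which dated descendant is "nearest"). Inconsistent constraints (a node older
than its dated ancestor, or a root age below a constraint) raise an error;
zero-length branches are permitted, negative ones are not. Re-dating a dated
tree with the same constraints is a no-op.

The result is a *pseudo*-chronogram: with few constraints, even spacing
minimizes branch-length variance but does not estimate divergence times.
Downstream indices should be read as relative, not absolute, time.

## Diversity indices and the randomization null (`community`)

MPD and MNTD are computed with incidence (presence/absence) weighting, which
matches floristic-list data; abundance weighting is deliberately out of
scope. The null model reshuffles tip labels of the pool phylogeny. For
incidence data this is equivalent to drawing a uniform random subset of pool
tips with the observed richness, which is how replicates are generated
(vectorized over permutations). The SES denominator uses the sample standard
deviation (n−1); NRI/NTI are the negated SES of MPD/MNTD, and |index| > 1.96
flags significance at the two-sided 5% level, reading the SES as
approximately standard normal under the null.

Choices worth knowing:

- The randomization pool is the full supplied tree (or distance matrix). To
  restrict the null to a subset (e.g. a woody-only pool), prune the tree
  first; the growth-form tables in the pipeline use the full pool.
- Per-site random streams are derived by hashing (master seed, site id,
  metric), so results are independent of site order and of how many other
  sites are processed.
- If a site's sample is the whole pool, every relabelling returns the
  observed value; the result carries an explicit degenerate flag instead of
  a number.
- An `exhaustive=True` option enumerates all equal-size subsets, useful as
  an exact oracle for small pools.
- 200 null permutations make the SES noticeably heavier-tailed than normal
  (the null SD is estimated); at the default 1,000 the 1.96 threshold holds
  its nominal rate to within the tolerance used in the calibration tests.

## Life-form harmonization and trait signal (`traits`)

Source floras use heterogeneous life-form vocabularies. The harmonization
rules map them onto the five Raunkiaer states: aerophytes, epiphytes and
hemiparasites become phanerophytes; cacti and succulents become
phanerophytes when tall, chamaephytes otherwise; climbers become therophytes
if they senesce in the dry season, otherwise phanerophytes or chamaephytes
by size. When different sites report different life forms for one species,
the state with the least protected buds wins (phanerophyte > chamaephyte >
hemicryptophyte > cryptophyte > therophyte). Missing attributes needed by a
rule raise an error rather than guessing. Reader options exclude exotics,
ferns/lycophytes and genus-level records, with a logged count.

Signal is tested under the fixed-tree, character-reshuffle model. The
statistic is the minimum number of unordered state changes, computed by
Hartigan's set dynamic program, which is exact on multifurcating trees
(essential for megatrees full of polytomies): at each internal node the
optimal state set is the set of states carried by the maximal number of
children, and every child outside that majority costs one change. The
implementation is batched across permutations (boolean membership tensors),
so 999 reshuffles of a thousand-tip tree cost milliseconds. The p-value is
(1 + #{null ≤ observed}) / (n_rand + 1).

Because the change count is integer-valued with heavy ties, the rank test is
conservative on small trees: at 32 tips the empirical size at α = 0.05 is
about 3%. Size calibration in the acceptance suite therefore uses a 128-tip
tree, where the statistic's support is fine enough for near-nominal size
(measured ≈ 5%). This is a property of the test itself, not of the
implementation.

## Spatial statistics (`spatial`)

Distances are great-circle (haversine, spherical radius 6371 km); a planar
option treats coordinates as already projected. The correlogram sorts all
n(n−1)/2 site pairs by distance and cuts them into k classes holding an
equal number of pairs (remainder to the first classes; ties kept adjacent by
stable sort), the convention matching "equal number of pairs per class"
correlograms. Class centroid = mean member distance. Within a class the
weights are binary (row-standardized available, not default) and Moran's I
uses the n/S₀ normalization. Per-class p-values come from permuting the
value vector across sites (two-sided, add-one smoothing, 999 permutations by
default — the permutation count is a package choice).

PCNM filters: inter-site distances are truncated at t (default: the largest
minimum-spanning-tree edge, the smallest t keeping the neighbour graph
connected); entries beyond t are replaced by 4t; the matrix −D²/2 is double
centered and eigendecomposed; eigenvectors with positive eigenvalues,
largest first, are the filters. Each is centered, and the set is mutually
orthogonal; signs are fixed by making the largest-magnitude loading
positive. The first filter captures the broadest spatial gradient and is the
one the pipeline passes to the ANCOVA (more can be admitted by
configuration). Eigenvalues ≤ 10⁻⁸ × the leading magnitude are treated as
zero.

## Regression stage (`models`)

`ols_fit` wraps ordinary least squares with named terms, t-based two-sided
p-values and Ezekiel-adjusted R²; rank-deficient designs raise an error
naming the collinear columns. `vif_screen` computes VIF_k = 1/(1 − R²_k)
and iteratively drops the worst predictor until all VIF ≤ 10 (threshold a
package choice; exact collinearity reports an infinite VIF and goes first).
The ANCOVA design is intercept + climate terms + treatment-coded substrate
dummies (sedimentary reference, so coefficients are the crystalline and
inselberg contrasts) + one spatial filter; coefficient flags default to
α = 0.10, the correlogram to α = 0.05, both configurable.

Variance partitioning uses the three-fit identity: with X the climate block
and W the substrate dummies, R²(Y~X∪W) = a+b+c, R²(Y~X) = a+b,
R²(Y~W) = b+c, so the shared fraction is b = (a+b) + (b+c) − (a+b+c). The
default flavour is adjusted R² (fractions may then be slightly negative);
raw R² is available. The combined fit uses a minimum-norm least-squares
solution with the effective design rank, so total redundancy between the
blocks (W a linear image of X) is legal and simply appears as shared
variation.

## Synthetic studies (`simulate`)

The generator emulates the structure of a regional floristic study:

- **Pool tree**: pure-birth (Yule) tree, ultrametric, with one extra
  exponential waiting time appended below the youngest split so no pendant
  edge has zero length. Arbitrary time units.
- **Life forms**: symmetric Mk process (Poisson change events along
  branches, uniform jump among the other states; default 5 states = the
  Raunkiaer alphabet). Low rates yield clade-structured traits.
- **Niche optima**: Brownian motion from a root value of 0; tip covariance
  equals shared path length × σ².
- **Sites**: uniform coordinates on an `extent_km` square anchored in a
  semi-arid tropical latitude band; climate covariates are Gaussian-process
  draws with covariance exp(−d/range) (diagonal jitter 10⁻⁸), scaled to
  plausible climate units (temperature 25 ± 1.5 °C, annual precipitation
  700 ± 150 mm, driest-quarter precipitation 30 ± 15 mm); substrate classes
  are spatially blocked by longitude terciles.
- **Assembly**: neutral = uniform draw of the target richness; filtering =
  uniform draw among species whose niche optimum lies within the tolerance
  of the site environment (nearest-optimum fill if too few qualify);
  repulsion = greedy max–min patristic subset (exact max–min selection is
  combinatorial, and only the sign of the induced overdispersion matters).

For filtering to bite, site environments must live on the scale of the
realized niche optima; `match_environment_to_niche` maps environment ranks
onto evenly spaced niche quantiles (5th–95th by default), preserving the
spatial rank structure of the GP draw. The calibration/recovery studies use
a 300-species pool, 40 sites, richness 40 and tolerance 0.25 niche-SD —
deliberately strong filtering. Because the clustered fraction of any single
study varies widely between pool/niche realizations, recovery tests pool
three independent replicates.

All generators hash (master seed, purpose, …) into independent sub-streams,
so adding one generator call never perturbs another's output, and identical
seeds give byte-identical files.

What the generator does **not** emulate: real floristic composition,
migration or biogeographic history, abundance structure, observation error
in life-form assignment, or correlated niche axes. Tests passing on
synthetic data show the machinery is correct and calibrated under its own
assumptions — not that any particular empirical system satisfies them.

## Problem sizes used in the test and acceptance suites

Null calibration of the indices uses 1,000 neutral sites at 200
permutations each; signal-test size uses 500 replicates of 199 reshuffles on
128 tips; ANCOVA coverage uses 5,000 simulations of 400 sites (2-SE coverage
equals P(|t_df| ≤ 2), so large residual df is the regime where the ≥ 95%
statement holds); the published-correlogram reproduction runs in under a
second. These sizes keep every Monte-Carlo standard error small relative to
the tolerance it is checked against.

## Known limitations

- Even-spacing dating is a convention, not an estimate; node ages between
  calibrations carry no uncertainty statement.
- Incidence-only metrics; no abundance-weighted MPD/MNTD, no richness- or
  occupancy-constrained matrix nulls beyond the tip-label shuffle.
- The discrete-signal test reports no effect size beyond the change counts;
  continuous-trait statistics (Blomberg's K, Pagel's λ) are out of scope.
- Correlograms use isotropic distance classes only; no variograms, no
  Gabriel/Delaunay connectivity.
- Regression is plain OLS: no spatial-error (SAR/CAR) models, no mixed
  effects, no multiple-testing correction across coefficients.
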