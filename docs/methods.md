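# Methods

`rumenage` implements the full analysis chain used in lifetime surveys of
the rumen microbiota — bacteria, archaea, anaerobic fungi and ciliate
protozoa sampled cross-sectionally from fourteen age groups between 7 days
and 12 years — together with a ground-truth simulator that makes every
stage testable without sequence data.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Feature tables and filters

Count tables are samples x features matrices of non-negative integers, one
per kingdom.  Rarefaction subsamples each sample to a fixed depth without
replacement using exact multivariate-hypergeometric draws; samples below
the depth are dropped with a warning (standard amplicon practice).  The
per-kingdom default depths (bacteria 7158, archaea 3794, fungi 4761,
protozoa 1818 reads) are the depths at which rarefaction curves plateau in
rumen amplicon data of this kind.

Two detection regimes are implemented, with deliberately different
prevalence comparisons:

* **detected** taxa (per age group): mean group relative abundance > 0.1%
  AND present in *strictly more than* half the group's samples;
* **core** taxa: prevalence > 50% within *every* age group and overall
  mean relative abundance > 0.01%;
* **age-specific** taxa: prevalence *>= 50%* within one group (the
  boundary is inclusive here, exclusive for "detected", mirroring the
  different wordings these filters carry in the field).  An optional
  `exclusive` flag additionally requires the taxon to fail the 50% bar in
  every other group; the default is non-exclusive, since keystone taxa
  recur across age groups in practice.

Prevalence denominators are the samples actually profiled for that kingdom
and group, not the full animal design.  Richness estimators are the
bias-corrected Chao1, `S_obs + F1(F1-1)/(2(F2+1))`, and Good's coverage,
`1 - F1/N`.

## Diversity

Faith's PD, unweighted and weighted UniFrac are computed through
scikit-bio with the rooted conventions of mainstream amplicon pipelines:
PD includes the path to the root, and weighted UniFrac is unnormalized
("raw") unless requested otherwise.  PCoA is computed directly by Gower
double-centering of -D^2/2 and symmetric eigendecomposition: negative
eigenvalues are reported but excluded from coordinates and
proportion-explained, with no correction applied.  PERMANOVA is computed directly from the among/within
sum-of-squares decomposition of the distance matrix, with the whole label
permutation set evaluated in one vectorised pass (calibration studies run
hundreds of tests) and the +1 permutation convention (p is never exactly
0); the pairwise variant runs all group pairs and BH-adjusts.  Alpha-diversity group comparisons follow
the Kruskal–Wallis omnibus / pairwise Mann–Whitney pattern with BH
adjustment; degenerate all-identical inputs report p = 1 with a warning.

## Microbiota age and maturation

The maturation model regresses chronological age on taxon relative
abundances with random-forest regression (mtry = p/3, minimum node size 5,
the regression conventions of the randomForest tradition):

1. **Importance.** Out-of-bag permutation importance — the increase in a
   tree's OOB mean-squared error when one taxon's values are permuted —
   averaged over trees and over `n_repeats` (default 100) independently
   seeded forest rebuilds.  Constant taxa score exactly 0.
2. **Taxon-count selection.** Taxa are ranked by mean importance and the
   10-fold cross-validated error is traced over a halving grid of taxon
   counts (p, round(p/2), ..., 1), repeated `n_repeats` times with fold
   reshuffling.  The selected count is the smallest whose mean error is
   within 5% (configurable) of the global minimum.
3. **Sparse model and microbiota age.** A forest fit on the selected taxa;
   its out-of-bag R^2 is recorded, and the **microbiota age** of each
   training animal is its out-of-bag prediction.  Resubstitution
   predictions are *not* used: they memorise chronological age and erase
   the maturation plateau.
4. **Plateau detection.** A cubic smoothing spline of microbiota age
   against log10 chronological age, with the penalty chosen by
   leave-one-out cross-validation restricted to an effective-df band
   (3.5 to ~0.8 n): unrestricted selection on a dozen noisy points
   degenerates into either a straight line or an interpolant.  The
   community is mature from the smallest sampled age at which the fitted
   curve stays within 10% of its fitted rise of the plateau level (the
   weighted mean fitted value over the oldest three sampled ages); if no
   age before the oldest qualifies the plateau is "not reached".  A
   relative criterion makes the call invariant to positive rescaling of
   microbiota age.  Two guards: constant microbiota age matures at the
   first sampled age (warned), and a fitted rise smaller than twice the
   residual standard deviation is "no trend", never a plateau.

**Scale of the regression.**  The sampling design is geometric (7 d to
12 y), so the forests regress log10(age) and predictions are
back-transformed to days.  On the days scale the squared-error loss is
dominated by the 5–12-year groups; because taxon trajectories saturate by
the maturation age, that variance is irreducible, early-life resolution
contributes almost nothing to MSE, and the taxon-count selector can never
justify early-life discriminatory taxa.  Log-age weighting gives every age
decade equal standing.  For the same reason the pipeline fits the plateau
spline on log10(microbiota age) (prediction noise is multiplicative) and
applies the plateau band on that fitting scale, where the noise is
homoscedastic.  The plain days-scale variant remains the default of
`fit_spline_and_detect_maturation` for externally supplied curves.

A detection on the height of the fitted curve was chosen over a
slope-threshold rule after direct comparison: the four post-maturation age
groups span only ~13% of the log-age axis, so group-mean noise produces
tail slopes far above any reasonable fraction of the maximum slope, and
smoothing strong enough to remove them linearises the curve; the slope
rule missed planted plateaus at every smoothing level, while the height
band recovers them reliably and still calls a curve that rises to the end
of the range "not reached" on the days scale.

**Known limitation.**  With the log-scale band, a curve that is still
rising steadily at the very end of the design cannot be distinguished from
a plateau one grid point before the oldest age — a consequence of the
log-compressed spacing of the old groups, not of the estimator.

## Co-occurrence networks

Spearman correlations (tie-corrected, two-sided p via the t
approximation, listwise sample handling) over all taxon pairs, BH-adjusted
on the upper triangle.  Two edge regimes: the **core** regime requires
|rho| > 0.3 AND adjusted p < 0.05; the **age-specific** regime requires
|rho| >= 0.5 with no p filtering.  Isolated taxa are dropped, so node
counts refer to connected taxa only.  Edge signs are metadata; topology
and betweenness are computed on the unweighted, sign-ignored graph.

The topology summary reports node and edge counts, average degree 2E/N,
density 2E/(N(N-1)), mean local clustering (degree < 2 contributes 0;
global transitivity co-reported), and the mean shortest-path length over
connected unordered pairs (NaN when no such pair exists).  Keystone taxa
are the top-k nodes by unnormalized betweenness centrality (k = 3 within a
kingdom, 5 across kingdoms), ties broken by score then lexicographic id.
The meta-community network matches samples across kingdoms via
(animal id, age group), computes relative abundances within each kingdom,
pools the taxa, and applies the selected regime.

## Synthetic communities

The generator draws, for each kingdom and sample, a latent log-abundance

    baseline_i + effect_i * (s_i(age) - 1/2) + sigma * z_i,

where `s_i` is a saturating log-age ramp over the taxon's colonisation
window (clipped to [0, 1]) and `z` is standard normal with planted
structure: exchangeable correlation blocks via shared Gaussian factors,
bridging hub taxa loading on several block factors, and cross-kingdom
links via factors shared between kingdoms.  Latent vectors pass through a
softmax and a Dirichlet-multinomial draw at a lognormal per-sample depth.
Kingdoms are truncated at their detection onsets (bacteria 7 d, archaea
14 d, fungi and protozoa 30 d), and per-group sample counts are uneven
(5–7), as in real lifetime designs.

Default study conditions: three planted age-discriminatory taxa per
kingdom with staggered windows (early: onset to 6 months; middle: 3 months
to 2 years; late: 1 year to 5 years) and effects of ±2.5–3 natural-log
units; a true maturation age of 1825 days (all windows close by then, so
every planted trajectory is constant beyond it); latent noise sigma 0.7
and Dirichlet concentration 300, chosen so the sparse model's explainable
variance lands in the ~70–80% regime typical of microbiota-age models.
The staggered windows are essential, not cosmetic: taxa sharing one
trajectory shape are mutually redundant, and a correct taxon-count
selector will prune all but one of them.

The network benchmark variant plants two six-taxon blocks (latent rho
0.8) and one hub bridging both inside an 80-taxon single-kingdom
community at concentration 1200, with structural taxa drawn moderately
abundant (baseline N(0.6, 0.3)).  These values sit in the window where
the planted structure is actually measurable, and both ends of the
abundance spectrum break the benchmark for physical reasons worth knowing
about: a dominant guild induces compositional-closure correlations above
the 0.3 edge threshold between entirely unrelated taxa, while rare
structural taxa have their planted correlations attenuated below it by
count and overdispersion noise — the hub is the canary, since a two-block
bridge caps its latent correlation with any single member at
0.7 * sqrt(0.8) ~ 0.63 before attenuation even starts.

What the simulator does *not* emulate: taxonomic misassignment, chimeras,
strain-level variation, batch effects, repeated measures on the same
animal, or genuinely compositional interactions (the correlation structure
is planted in latent space, and closure is a by-product).  Passing
recovery benchmarks therefore shows the estimators are correct and
well-calibrated under the stated generative model, not that real rumen
data will satisfy their assumptions.

## Problem sizes and defaults used in validation

The validation suite runs the full pipeline on 20 simulated communities
(~80 bacterial samples, 30 taxa each) with 20 model rebuilds per stage and
reduced forest sizes (importance 60 trees, CV 25, sparse model 400), which
keeps per-seed cost near half a minute while leaving the selection and
plateau behaviour unchanged relative to larger forests.  PERMANOVA
calibration uses 500 null data sets at 199 permutations; UniFrac axioms
are checked on 50 random 5-tip trees against a path-set oracle;
betweenness is checked against brute-force shortest-path enumeration on
100 random graphs of up to 12 nodes.
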