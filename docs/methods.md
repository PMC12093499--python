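# Methods

## Input model and containers

The unit of input is one symmetric, zero-diagonal, nonnegative parcel×parcel
matrix of fiber bundle capacity (FBC) per subject, framed by an atlas table
whose row order fixes the canonical parcel order. Seeds (here: insular
cytoarchitectonic areas) are flagged in the atlas; the default target axis is
every non-seed parcel, so a seed's undefined self-edge never enters any
statistic (passing an explicit target list re-includes seeds as targets,
with self-edges carried as the zero diagonal).

Hemispheric atlases are merged by base name: each merged edge (A, B)
aggregates the four homologous edges A_L–B_L, A_L–B_R, A_R–B_L, A_R–B_R.
The default aggregation is the mean, which keeps the FBC scale comparable
across cohorts and parcel sizes; `sum` is available and equals 4× the mean
whenever all four edges exist, which also covers the reading of hemisphere
combination as pooling of edge mass. Matrices are read from TSV with parcel
ids as header row and first column, reindexed to canonical order; relative
asymmetry up to 1e−6 is treated as floating-point I/O noise and resolved as
(M + Mᵀ)/2, anything larger is rejected as a likely transposition bug.

## Trimmed-mean fingerprints

Connectivity of seed i to target t is the trimmed mean over subjects of
FBC(i, t): sort, drop ⌊n·f⌋ observations from each tail, average the rest.
The trim fraction f defaults to 0.10 per tail and is a single global
parameter inherited by every downstream stage (fingerprints, bootstrap
nulls, cluster-level profiles), keeping the observed statistic and its null
exactly comparable. f = 0.10 discards the plausible share of
tractography-scale failures in large population cohorts without biasing the
location of a log-normal-like edge distribution appreciably.

## Bootstrap specificity

For each target t the null distribution is built by resampling single FBC
values with replacement from the pooled (subject × seed) values for t —
n_subjects values per iterate, 10,000 iterates, trimmed mean as the iterate
statistic. Drawing exactly n_subjects values gives the null statistic the
same sampling variance as the observed fingerprint entry; using the same
trim keeps the test internally consistent (a `statistic="mean"` switch
exists). The threshold is the empirical 99th percentile (configurable); a
value above it is *target specific*, and *globally elevated* when it also
exceeds the analogous threshold from the pool over all targets and seeds.
Classification order matters: the global check applies only on top of target
specificity, so globally-elevated ⊆ target-specific by construction.

Whether the null should resample single values or whole subject rows is an
open interpretive point; single-value resampling is implemented and noted
here. Per-target RNG substreams are derived as
`SeedSequence([master_seed, crc32(tag)])`, so adding or removing a target
never perturbs another target's null, and every null is reproducible from
the master seed alone.

### Type-I calibration

`calibrate_type_one` measures the realised false-positive rate on simulated
exchangeable-null cohorts (all effect multipliers 1). Its null cohorts are
drawn *without* the generator's whole-subject outlier mechanism, because
calibration is defined under the sampling model the bootstrap assumes
(exchangeable pooled values). Under those conditions the measured rate is
≈0.006–0.01 at the 99th percentile; the mild conservatism is intrinsic to
the pooling rule, since the tested seed contributes its own values (1/8 of
the pool at 8 seeds) to the null that judges it. With contamination switched
on (5% of subjects × 4), the test becomes strongly conservative (≈0.002):
bootstrap pools occasionally contain more outlier values than the trim can
remove, inflating the null's right tail, while the observed per-seed trimmed
mean always discards the few outlier subjects. That direction of error is
the safe one — contamination can only suppress, never inflate, false
positives — and is reported separately by the acceptance script.

## Feature selection and clustering

Targets flagged for at least one seed form the clustering feature set; an
empty set is a hard error advising larger effects or cohorts. Distances are
Manhattan sums of absolute fingerprint differences over the features, with
no feature scaling by default (the clustering is meant to reflect absolute
FBC differences; a z-score switch exists). Hierarchical clustering is
average linkage (UPGMA) via scipy, validated by the cophenetic correlation;
merge-height ties resolve to the smallest canonical condensed-order pair.
k-means (scikit-learn, 50 greedy-k-means++ restarts from a fixed seed —
cheap insurance at 16-entity scale) is run over the k range.

**Elbow rule.** k\* maximises the discrete second difference of
**log**-inertia. The log is essential: a raw second difference of any
steeply decreasing convex curve peaks at the first large drop regardless of
where the true elbow sits, which misidentifies k on hierarchically nested
cluster structure; the log version peaks where the *relative* inertia drop
collapses, and is exactly invariant to global rescaling of the features.
The curve is padded with k_min−1 (k = 1 is the total dispersion, no fit
needed) and k_max+1 so that every requested k, including the boundaries, is
a candidate; ties break to the smallest k; a singleton k range is returned
as-is with a warning. Inertia is floored at 1e−12 of its maximum before the
log to tolerate duplicate entities.

MDS is classical (Torgerson): eigendecomposition of the double-centered
squared-distance matrix — deterministic, unlike SMACOF. Eigenvalues below
1e−9 of the leading one are zeroed (numerically empty axes), and each axis
is sign-flipped so its first nonzero coordinate is nonnegative, making
embeddings comparable across runs.

The cluster-of-clusters stage rebuilds fingerprints at cluster level —
per subject, the mean over member seeds, then the trimmed mean over
subjects — and reruns the same distance/UPGMA/k-means/elbow pipeline
(requires ≥ 3 clusters).

## Contrasts and replication

Per-subject cluster values are means over (member seeds × targets in the
region). The top cluster (highest mean; ties go to canonical column order
with a logged warning) is compared against every competitor with a
one-sided unpaired Welch t-test. The samples come from the same subjects,
so a paired test would be arguable; the paper-style protocol does not
specify, and unpaired Welch is the conservative default (a `paired` switch
exists). A contrast passes only if every competitor is beaten at α = 0.01
and the effect-size gate holds: Cohen's d (pooled SD) with a 95% percentile
bootstrap CI (2000 resamples, both samples resampled independently) whose
lower bound exceeds 0.8. `ci_rule=False` switches to the looser
point-estimate gate (d > 0.8). The CI level is an assumption; nothing in
the protocol fixes it.

Replication concordance compares two cohorts' specificity maps cell-wise:
above threshold in both or in neither → concordant, in exactly one →
discordant; symmetric in cohort order by construction. Because each cohort
is tested against its own bootstrap thresholds, a global FBC scale
difference between cohorts (e.g. a second cohort at twice the scale)
cancels and decisions replicate.

## Integrative connectivity

A source q is of *limited strength* in target t's profile when (i) it is
connected at all (FBC > 0 — a zero edge is no connection), (ii) it is not
among the "strongest" sources (FBC above t's bootstrap threshold — the same
per-target 99% null as the specificity stage, the single bootstrapped
per-target threshold this pipeline defines), and (iii) it ranks within the
top fraction (default 50%) of the remaining eligible sources by FBC. The
alternative reading — top 50% of the *full* profile minus the exclusions —
is available as `rank_scope="full"`; the "remaining" reading is the default
because the exclusion clause otherwise does nothing whenever the strongest
connections would rank in the top half anyway. Ranks are taken column-wise
(per target profile), ties at the cut break by canonical parcel order.

The integrative fraction of parcel p is its row-sum over the mask divided by
(n−1): the share of other parcels' profiles holding p at limited strength.
Fractions are binned as [0%, 5%), [5%, 15%), …, [85%, 95%), [95%, 100%]
and labelled "0%-4%", "5%-14%", …, "65%-74%", …, "95%-100%". Hub overlap
categorises every parcel by which of two candidate hub areas appear in its
limited-strength profile (only_a / only_b / both / none).

The manifold embedding wraps UMAP (established algorithm; internals not
re-derived here) with n_neighbors = 15, min_dist = 0.1 and a fixed seed, in
exact single-threaded mode so results are deterministic; the fuzzy
neighbor-graph edge weights are exported alongside the coordinates.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the data's geometry. Edges are log-normal (FBC is positive and
right-skewed) with location log(10) and scale 0.4 — arbitrary units, chosen
once; no claim of realism — optionally per-parcel locations for
heterogeneous target strengths. A seed–target edge whose target belongs to
the seed's planted group affinity gains log(multiplier) in location
(default multiplier 3). `round(0.05·n)` subjects are whole-subject outliers
with all values × 4, emulating tractography scale failures — exactly the
contamination the trimmed mean exists to tame. A second cohort reuses the
planted structure with independent noise and a global scale factor
(emulating a replication data set with elevated FBC). Everything is
bit-reproducible from one integer seed.

The default configuration (`make_paper_atlas`) mirrors the motivating
study design: 107 merged parcels (214 hemispheric), 16 insular seeds
partitioned into six groups — three dorsal anterior, one ventral anterior
(Id10 alone, orbitofrontal affinity), superior posterior (Ig1+Ig2, auditory
and parietal-opercular affinity) and inferior-to-middle posterior (visual
and temporal affinity) — with pairwise disjoint affinity target sets so
that recovery is well-posed. The exact membership of the areas with no
distinctive connectivity of their own (Ia1–3, Ig3, Id9) is an emulation
choice. Reference cohort sizes are ~914 and ~204 subjects; tests and the
acceptance script use 50–200 subjects, which the planted effect sizes make
ample.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: spatial/geometric structure (no distance-dependent
connectivity, no shared tracts inducing correlated edges), inter-subject
anatomical variability beyond a global scale factor, covariate effects
(age, sex), and non-multiplicative measurement error. Recovery results here
certify the statistical machinery, not performance on any real connectome.

## Problem sizes and runtime conventions

The validation suite runs type-I calibration at 50 subjects × 8 seeds ×
30 targets × 10,000 bootstrap iterates × 200 replicate cohorts (48,000
decisions); cluster recovery, contrasts and replication at 200 subjects on
the full 107-parcel configuration with 2,000 bootstrap iterates (the
bootstrap is only a pipeline stage there, not the object under test, and
the recovery statistics are insensitive to the iterate count); determinism
checks at 20 subjects. These sizes make every Monte-Carlo tolerance in the
tests a small multiple of the corresponding standard error.

## Known limitations

- The bootstrap specificity test is deliberately conservative under
  subject-level contamination (see calibration above) and mildly
  conservative under the pure null because the tested seed is part of its
  own pool; both biases shrink as the number of seeds grows.
- The elbow rule assumes a single dominant curvature point; genuinely
  hierarchical data with two elbows will surface only the sharper one (the
  cluster-of-clusters stage exists for the second level).
- No multiple-testing correction is applied anywhere, matching the
  fixed-percentile protocol this package implements; with many targets the
  family-wise error of the specificity map is correspondingly large.
- Cluster-level replication reuses the discovery cohort's cluster labels in
  both cohorts; label instability between cohorts is reported by the
  clustering stage (differing compositions), not by the concordance map.
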