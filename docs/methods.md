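# Methods

## Coordinates and intervals

Internally all coordinates are 0-based half-open, so `length = end − start`
holds exactly and two adjacent intervals share zero bases. Header-dialect
CNV tables, gene/UTR TSV tracks and site tables carry 1-based inclusive
coordinates and are converted on read (`start − 1`); BED inputs are taken
as-is. The source databases never state their convention uniformly, so
this conversion is a package convention, not a property of the data.
Chromosome names are compared after stripping a leading `chr`.

Reciprocal overlap of two intervals is the overlap length divided by each
interval's own length, taking the minimum; it is symmetric, lies in
[0, 1], equals 1 only for identical intervals, and is defined as 0 across
chromosomes (an error there would complicate all-pairs scans for no
benefit). Cross-type pairs (loss vs gain) are never compared anywhere:
the models are type-specific throughout.

## The feature registry

Each feature is declared, not inferred: name, aggregation kind
(max/min/mean/count/length), source track, selector, and — for
categorical counts and dosage counts — the category code. Declaring the
aggregation direction is the point of the scheme: a score whose high end
is deleterious must aggregate by max over the CNV, a score whose low end
is deleterious by min; inferring direction from data would silently break
on sparse resources.

The default registry has 79 entries: 1 length; 24 max-aggregated scores
(gene-level pLI, Episcore, HIPred; site-level REVEL, GERP++ RS, CADD,
DANN, phyloP/phastCons, SiPhy, LRT, Eigen, PrimateAI, and further dbNSFP
columns); 10 min-aggregated (LOEUF, RVIS, o/e ratios, HI index, SIFT,
SIFT4G, FATHMM, PROVEAN); 2 mean-aggregated (GHIS, CDTS); 7 element
counts (protein-coding, pseudogene, ncRNA genes; 3′/5′ UTRs; OMIM and
Morbid genes); 6 cCRE class counts; 12 dosage counts (HI and TS genes at
codes 0/1/2/3/40/NA); and 17 categorical-prediction counts (the
Deleterious code of all seven predictors plus the benign/tolerated codes
of SIFT, LRT, both PolyPhen2 variants and FATHMM). The named anchors
(length, pLI_max, LOEUF_min, GHIS_mean, Episcore_max, GERP_RS_max,
three_prime_UTR_num, LRT_pred_D, the cCRE and dosage blocks) are fixed by
the scheme; the tail entries are a documented stand-in drawn from standard
dbNSFP/gnomAD score names, and the whole registry is user-overridable via
a plain-text config (`cnvpatho registry show` prints the default).

## Annotation semantics

"Overlap" for attribute counts means any shared base (≥ 1 bp); sites
overlap when their position falls inside the half-open CNV interval. No
fractional-overlap threshold is applied — counts behave the way gene
counts behave in comparable annotation tools, and a threshold would add a
free parameter the scheme does not define. Gene-level scores contribute
one value per overlapping gene, site-level scores one per overlapping
position. Empty aggregations are explicit missing values; a CNV
overlapping one site with score 0 is distinct from a CNV overlapping no
site. Aggregation sorts its inputs before reducing, so feature values are
exactly invariant to record order in the bundle (this matters for the
bitwise-determinism guarantees). A numeric score column wholly absent from
a bundle annotates as all-missing (resources are legitimately sparse); a
categorical predictor absent from the site table is a configuration error,
since a count of zero and an unconfigured predictor are different claims.

Missing cells are filled with per-feature medians computed on the
*training partition only* — the leakage-safe reading; whether the original
procedure fit medians before or after splitting is unstated. A feature
entirely missing in training imputes to 0 with a warning recorded in the
matrix flags; failing outright would make small synthetic runs unusable.

## Curation rules

Per-source filters are listed in the README. Choices the sources leave
open:

- "Conflicting pathogenicity" means one member in {benign, likely benign}
  and the other in {pathogenic, likely pathogenic}; uncertain significance
  conflicts with neither (ACMG practice, and it keeps VUS records usable).
- Conflicting pairs at ≥ 70% reciprocal overlap remove **both** members:
  no survivor rule is defined by the procedure, and symmetric removal is
  deterministic and conservative. Conflicts are detected over the original
  set and applied once — no cascading re-evaluation, whose order
  dependence would break determinism.
- The combined dbVar assertion "pathogenic/likely pathogenic" maps to
  likely pathogenic (the conservative tier).
- DECIPHER rows passing `observations > 0 ∧ frequency > 1%` are *retained
  as benign* — frequent variants are expected benign under selection.
- Validation thinning keeps the shorter member of concordant pairs at
  ≥ 90% reciprocal overlap, implemented shortest-first greedily (ties
  break by record id), which also resolves chains deterministically.
- Records are canonically sorted before any pair rule, so shuffled input
  yields the identical retained set.

Every curation stage returns a report whose counts are conserved
(input = retained + Σ excluded), asserted in tests.

## Models

XGBoost (`tree_method="hist"`, single thread) with
`multi:softprob` for the five-tier task and `binary:logistic` for the
binary task; class order is least → most pathogenic, and argmax ties break
toward the more pathogenic class (clinical conservatism). The binary task
admits only benign and pathogenic rows; other tiers are excluded upstream.
Splits are stratified 7:3 by class. Class imbalance is handled by
stratification only — no resampling — mirroring the original training
regime; a class-weight option would be a one-line extension but is off by
default.

Tuned hyperparameters and default search bounds: `eta` log-uniform
[0.01, 0.3]; `gamma` [0, 5]; `max_depth` {2..10}; `min_child_weight`
[1, 10]; `subsample` [0.5, 1]; `nrounds` {50..1000}; everything else at
XGBoost defaults. The tuner is a seeded random search under stratified
k-fold CV (default 10 folds) maximizing mean one-vs-rest AUC over the
classes present in each held-out fold (plain AUC for binary); the
best-scoring trial wins, first trial on ties. Trial count and bounds are
config knobs. The fitted model is saved as a single JSON archive: booster,
task, hyperparameters, training seed, imputation medians and the registry
fingerprint; prediction refuses a matrix whose registry fingerprint
differs and imputes missing cells with the stored medians.

## Metrics and statistics

AUC uses the midrank formula `U/(n₁n₂)`, so it is exactly the Mann-Whitney
statistic, handles ties, and is invariant under strictly increasing score
transforms. Degenerate metrics (zero denominators, classes absent from the
truth) report 0 with an explicit flag instead of raising, so batch
comparison tables never abort. Multiclass summary accuracy is plain top-1;
per-class metrics are one-vs-rest.

`mann_whitney_u` computes U from midranks; the two-sided p-value is exact
by full enumeration of group assignments for pooled n ≤ 12 (deviation
definition: P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|)), else the normal
approximation with tie and continuity correction. Kruskal-Wallis delegates
to scipy with the all-tied case defined as H = 0; post hoc comparisons are
all k(k−1)/2 pairwise Mann-Whitney tests with Bonferroni multiplication
capped at 1. Group comparisons in feature reports use benign as the
reference, two-sided.

SHAP attributions are the exact tree-path-dependent Tree SHAP values
computed by XGBoost itself (`pred_contribs`). Additivity (row sum + base =
margin) is checked at 1e-6 relative to the attribution scale with a unit
floor — contributions are emitted in float32, so a purely relative check
diverges when a row's margin crosses zero. Feature ranking sums |SHAP|
over rows (and class margins), ties resolved by registry order. Dependence
thresholds smooth attributions with a running median (window 51) along
sorted feature values before locating the first sign change; an eyeballed
threshold would not be testable. The differential benign-vs-pathogenic
analysis ranks features by Mann-Whitney p on log10(x+1) values (the +1
offset because count features are legitimately zero; `median_diff` ranking
is available), keeps the top 10, and drops rows whose selected features
are all zero.

## The synthetic generator

`FixtureSpec` defines the study conditions: a 2 × 10 Mb toy genome; 400
genes (biotypes 50/20/20/10% protein-coding/pseudogene/ncRNA/other, 10%
morbid ⊂ OMIM, dosage codes drawn across 0/1/2/3/40/NA), gene and site
scores uniform within each score's documented range (pLI ∈ [0,1],
LOEUF ∈ [0,9], …) with ~10–15% missing; 4000 scored sites; 600 cCRE
regions. CNV lengths are log-normal (benign median 20 kb, spread 0.8);
pathogenicity effects are monotone across the five tiers (interpolation
factor 0, ¼, ½, ¾, 1): median length multiplied by `length_ratio`^t
(default 4), probability `morbid_enrichment·t` (default 0.6) of centring
on a morbid gene, and a `site_d_rate_shift` (default 0.3) raising
Deleterious-call density inside morbid genes. All lengths are clipped to
the curation range [50 bp, 5 Mb]. These defaults are what the package
treats as a realistic planted-signal regime — large, morbid-gene-hitting
CNVs being more often pathogenic — and are the conditions under which the
recovery tests run.

What the generator does **not** emulate: realistic human annotation
density or linkage between scores, genuine breakpoint effects, database-
specific file idiosyncrasies, and the severe class imbalance of real
archives. Passing tests therefore demonstrate correctness of the machinery
and recoverability of planted effects, not real-data performance; the
original corpus-scale accuracies require the actual database releases.

Randomness: one mandatory seed fans out through spawned
`numpy.random.SeedSequence` streams, one per track, so artifacts are
bit-reproducible and growing one track never perturbs another. The raw
per-database fixture tables are fixed by construction — the seed only
shuffles row order — and ship with a ground-truth manifest of expected
counts per filter rule.

## Problem sizes

The test suite exercises the planted-signal recovery at 2,000 CNVs per
class (binary), with brute-force oracle comparisons on a ≤ 100 kb toy
genome with ≤ 200 interval records; the acceptance script additionally
trains five-tier models at 2,700 CNVs per type. These sizes were chosen as
the smallest at which the planted effects are comfortably recoverable and
the null is tight around 0.5.

## Known limitations

Breakpoint-level effects, nested/multi-allelic SV representation, TAD
boundaries and constrained coding regions are out of scope. The registry's
tail entries stand in for an unpublished full feature list. The tuner is a
random searcher, adequate for the modest search space but without
model-based trial proposal. Real VCF/GFF release files are not parsed —
inputs are the plain-text table formats documented in `resources.py`.
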