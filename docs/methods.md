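# Methods

## Model

The recommender is user-based collaborative filtering with neighbourhoods
restricted to clusters of clinically similar patients. Users are patients,
items are anti-diabetic drugs, and the rating is an ordinal encoding of the
per-encounter dose-change token: 0 = drug not administered, 1 = dose
decreased, 2 = dose increased. `Steady` (administered, dose unchanged) has
no published value on this scale; the default maps it to 1, keeping
"administered" distinguishable from "not administered" while staying inside
the {0,1,2} range, and is configurable (`PreprocessConfig.dose_encoding`,
constrained to `No → 0` and monotone `No ≤ Down ≤ Up`).

The predicted rating for patient *u* and drug *d* is the cosine-weighted
mean over same-cluster patients *v* ≠ *u* with r(v,d) > 0 and sim(u,v) > 0:

    r̂(u,d) = Σ_v sim(u,v) · r(v,d) / Σ_v sim(u,v)

Similarity uses the *full* rating rows including zeros — the matrix is
dense by construction, a 0 is an observed non-prescription — while the mean
runs only over patients who actually received the drug, so non-prescriptions
never pull predictions toward zero. Ratings are not mean-centred: on a
3-level scale where 0 means "not administered", subtracting user means would
conflate prescription breadth with dose direction. Neighbourhood predictions
are therefore convex combinations of observed neighbour ratings and stay
inside [min, max] of those ratings.

Fallbacks when no qualifying neighbour exists: the cluster's mean nonzero
rating for the drug, then the cohort-wide mean nonzero rating, then 0 for a
drug never administered anywhere; each prediction carries a provenance flag
(`neighbors` / `cluster_mean` / `global_mean`). In ranked recommendation
lists, `global_mean` scores sort *below* all cluster-backed scores. The
rationale: the global mean is a cohort prior, not evidence about this
patient's group, and for a drug that is exclusively dose-increased wherever
it is used the prior equals 2.0 exactly — without the tier rule such drugs
would tie with, and alphabetically displace, genuinely supported
recommendations in clusters that never use them. Ties within a tier break
alphabetically by drug name; already-administered drugs are not excluded
from lists (configurable via `use_predicted`/observed scoring).

Exactness caveat: because the weighted mean averages over *all* qualifying
neighbours, an exact duplicate of a patient inside a cluster is recovered
exactly only when the cluster is otherwise unanimous about the drug (or the
duplicate is the sole neighbour); the convexity bound above is the guarantee
that always holds.

## Preprocessing

Order of operations: deduplicate (keep each patient's first encounter in
file order) → keep patients with ≥ `min_medications` (default 2) non-`No`
drug tokens → column selection → numeric transformation. Column-selection
rules, each recorded in a drop report `{column, reason, statistic}`:

* `identifier`: explicit list (default: encounter id, patient id, payer
  code, weight, medical specialty).
* `missingness`: missing fraction > 0.50.
* `imbalance`: one value covering > 0.95 of rows — applied to non-drug
  columns only. Drug columns are governed by the prevalence rule instead:
  a drug administered to ~1% of patients is 99% "No" yet clinically
  informative, so the imbalance rule would wrongly discard exactly the
  rare-drug columns the prevalence floor is meant to adjudicate. The rule
  is also suppressed when n ≤ 1/(1−threshold), where every column is
  trivially near-constant.
* `low_prevalence`: drug administered to < 0.5% of the (post-filter)
  patients.

Transformations: age bracket `[L−U)` → midpoint (5, 15, …, 95); gender →
0/1 (rows with unmappable gender are dropped, never imputed); lab summaries
(`max_glu_serum`, `a1cresult`) → 1 if the test was performed, 0 otherwise;
medication-change and diabetes-medication flags → 0/1; readmission →
NO → 0, >30 days → 1, <30 days → 2 (ordered by clinical severity,
configurable); race → five one-hot indicators with missing race mapped to
`Other`; primary diagnosis → nine one-hot disease categories from the
ICD-9 three-digit prefix (circulatory 390–459 & 785, respiratory 460–519 &
786, digestive 520–579 & 787, diabetes 250.xx, injury 800–999,
musculoskeletal 710–739, genitourinary 580–629 & 788, neoplasms 140–239,
everything else including V/E codes → other — the grouping conventional
for this data set). Secondary diagnoses are parsed but unused. The output
separates clinical features from encoded drug columns; clustering consumes
their concatenation, the recommender the drug block.

## Patient grouping

* Standardisation uses the population standard deviation (denominator n);
  zero-variance columns are removed before standardisation (they carry no
  grouping information) and the fitted pipeline records which columns it
  uses.
* PCA components keep the smallest k whose cumulative explained-variance
  ratio reaches the target (default 0.62; an integer selector such as 8
  fixes k outright). Component signs are fixed by making each component's
  largest-magnitude loading positive, so scores are reproducible across
  runs and feature orderings.
* K-means: k-means++ initialisation, n_init = 10, max_iter = 300,
  tol = 1e-4, seeded. DBSCAN grid default:
  eps ∈ {0.3, 0.5, 0.8, 1.2, 2.0} × min_samples ∈ {5, 10, 20}.
* Silhouette: Euclidean metric on the PCA scores; DBSCAN noise points are
  excluded both from the silhouette mean and from downstream CF
  neighbourhoods; singleton clusters contribute 0. Above 20 000 points a
  seeded subsample of that size is scored (the pairwise cost is quadratic);
  all cohorts in this repository are far below the cutoff, so scores are
  exact here.
* Selection: argmax silhouette over all candidates; ties break toward
  fewer clusters, then K-means over DBSCAN, then the smaller parameter.
  Degenerate candidates (< 2 clusters) are skipped. When the winner is
  DBSCAN, the evaluation stage carries the best K-means candidate forward,
  because held-out patients need nearest-centroid assignment and density
  clusters have no centroids.
* New patients are assigned by nearest centroid (ties → lowest label) from
  their standardised, PCA-projected clinical features — their ratings play
  no part, which is what serves rating-free new patients.

## Evaluation protocol

Patients (never individual cells) are split by a seeded permutation into
round(0.8·n) training and the rest test (5177 patients → 4142/1035). The
grouping model is fitted on training patients only; test patients are
assigned by nearest centroid. MSE averages squared error over test *cells*
with an observed nonzero rating — predicting true zeros is excluded, since
a zero means "not prescribed" rather than an observed dose of zero — with
the test row driving similarity but all neighbour ratings coming from
training patients. Precision@N (default N = 3) counts a drug as relevant
when its held-out dose value exceeds 1; patients with no relevant drug are
excluded from the mean and reported separately. Cell-averaging for MSE and
the fixed top-N denominator are deliberate conventions, stated here because
reasonable alternatives (patient-averaged MSE; denominator = list length)
exist.

## Synthetic cohorts

The generator emits raw-schema encounter tables whose ground truth is known
and carried in a sidecar, never in the data. Each of G planted clusters
(default 6, size proportions 875:910:412:1369:646:965 over a default 2000
patients) holds a profile: dominant race and primary-diagnosis category
(default concentration 0.95 — minority shares of ~5% per categorical
attribute, so the planted partition remains the dominant geometric
structure), gender balance, an age-bracket window placing mass between 45
and 85 years, Poisson utilisation-count means, cluster-dependent admission
type / discharge disposition / admission source / readmission mixes (in
real cohorts these correlate with the patient group; modelling them as
independent would plant axis-aligned structure that crosses the clusters),
and a drug-dose signature over ten active drugs — three `Up` drugs and one
`Steady` drug per cluster, with insulin prevalent in three clusters and
absent in the other three. The remaining medication columns are always
`No`, feeding the prevalence filter; `?` markers are injected into weight
(97%) and medical specialty (60%), feeding the missingness filter; a
configurable fraction of patients (default 10%) receives a duplicate
encounter differing only in encounter id, so deduplication is exercised and
ground truth does not depend on which encounter survives.

Noise dials: `dose_noise` resamples an active drug's token uniformly with
the given probability (default 0.1 — the single source of dose
stochasticity over otherwise deterministic signatures); `feature_noise`
blurs count means lognormally; `label_flip` draws a patient's attributes
from a different cluster while the recorded truth keeps the original label.
`SyntheticConfig.strong_separation()` zeroes all noise and concentrates
every categorical to a point mass — the signal-recovery regime in which the
pipeline should (and does) recover the planted structure essentially
perfectly.

What the generator does *not* emulate, hence what passing tests do not
show: real encounter data has correlated missingness, hundreds of ICD-9
codes with heavy tails rather than a handful per category, temporally
ordered repeat encounters with evolving regimens, dose signatures far less
crisp than three-`Up`-drugs-per-group, and cluster structure that is at
best partial. Synthetic results certify the machinery (filters, encodings,
grouping, prediction, ranking, metrics), not clinical performance; the
optional `examples/uci_reproduction.py` exists for the latter comparison.

## Problem sizes and numerical choices

Tests and the acceptance script use cohorts of 250–2000 patients (the
default experiment: 2000 patients, 80/20 split; parameter recovery: ten
seeds at n = 2000; signal-recovery grid: n = 800 over dose noise
{0, 0.2, 0.4} × three seeds). Standardisation tolerance 1e-10; silhouette
and DBSCAN agree with brute-force reference implementations to 1e-9 in the
test suite; K-means uses a fixed default seed of 42 with per-stage child
seeds derived from one global seed via a CRC-based splitting scheme, so
every artifact is byte-reproducible at fixed seed.

## Limitations

Item-based CF, latent-factor models, drug-metadata (content-based) features
and hybrid cold-start strategies are out of scope by design. The system
ranks only drugs present in the training matrix (new-item cold start is
unsolved here). The dose scale collapses `Down` and `Steady` by default;
clinical use would demand a richer outcome model and, above all, validation
on real prescribing data — the recommender reproduces prescribing patterns
of similar patients, which is an explainable but purely correlational
signal.
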