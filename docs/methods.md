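# Methods

`targetnb` predicts the protein targets of orphan small molecules from
structure alone. Each target on a panel gets an independent two-class
Bernoulli Naïve Bayes model trained on known actives plus a large set of
inactives — experimental where available, "putative" (sphere-excluded)
where not — so that both the presence *and absence* of substructural
features contribute evidence. This note describes the model, the data
conventions, the numerical choices, and exactly what the synthetic
panels used for testing do and do not demonstrate.

## Compound representation

Structures enter as SMILES and are standardized deterministically:
largest covalent fragment (salts and counter-ions dropped), charge
neutralization where chemically valid, explicit-hydrogen removal, and a
canonical tautomer chosen by RDKit's enumerator. Standardization is
idempotent and byte-deterministic; agreement with any particular vendor
standardizer is not a goal.

Training-set structure filters: 100 Da < MW < 900 Da (strict bounds), at
least one carbon atom, and none of a configurable disallowed-element
list (default Li, Be, B, F, Na, Al, Si, Ar, Ti, Fe, Zn, Br). The default
list is intentionally kept as configuration: excluding fluorine and
bromine is unusual for drug-like chemistry and a user may well want to
relax it.

Compounds are encoded as 2048-bit hashed circular Morgan fingerprints at
radius 2 (the ECFP_4 configuration), the de facto standard descriptor
for ligand-based target prediction. Similarity is the Tanimoto
coefficient over set bits; two all-zero fingerprints are defined as
maximally similar (1.0), a case real featurized molecules never produce.

## Training-set assembly

A bioactivity record is labelled **active** when it is a quantitative
binding/functional endpoint (IC50, EC50, Ki, Kd) at ≤ 10 μM with a
curation confidence score ≥ 5, **inactive** when the source asserts
inactivity, and discarded otherwise. The 10 μM cut-off admits both
marginally and highly active ligands; confidence 5 keeps multi-domain
protein assignments that stricter cut-offs (8–9) would discard.

Per target, duplicate structures collapse to one instance; a compound
recorded as both active and inactive for the same target is kept as
active only (the active side is the curated one) and the conflict is
counted in the assembly report. Targets with fewer than 10 actives are
dropped — there is too little signal to learn from, and cross-validation
folds of such classes are frequently empty.

### Sphere-excluded putative inactives and balancing

Most targets have far fewer measured inactives than the 1:100
active:inactive ratio the models are trained at. The shortfall is made
up by *sphere exclusion*: candidates are drawn uniformly at random
(seeded, without replacement) from a background compound pool and
accepted only if their maximum Tanimoto similarity to every active is
strictly below an exclusion radius. The radius is the empirical quantile
of the actives' nearest-neighbour similarity distribution — the smallest
observed value covering ≥ 95 % of neighbour pairs (ties toward the
smaller value). On the large public corpus this method was developed
against that quantile is Tc 0.424, which the package ships as the stock
radius for users who do not recompute it; on a synthetic or user panel
it is recomputed from the data. Oversized inactive sets are uniformly
undersampled (seeded) to exactly the target ratio. Actives are never
modified, and every sampling decision is reproducible from the seed
recorded in the class provenance.

## The classifier

For a query fingerprint **x** = (F₁, …, Fₙ) and class C ∈ {active,
inactive} the class-conditional likelihood is the Bernoulli product

    P(x | C) = ∏ᵢ P(Fᵢ|C)^{Fᵢ} · (1 − P(Fᵢ|C))^{1−Fᵢ}

so an absent feature explicitly penalizes a class in which that feature
is common. Feature conditionals are add-α smoothed empirical
frequencies, P(Fᵢ|C) = (cᵢ + α)/(N_C + 2α) with α = 1 (Laplace) by
default, guaranteeing 0 < P < 1. Posteriors follow from Bayes' theorem
with empirical class priors (uniform priors are selectable); all
arithmetic is done in log space with max-shift normalization. Tests pin
the implementation to an explicit-product brute-force evaluator over
exhaustive small feature spaces (2⁸ inputs, 1e-9 tolerance) and to an
independent reference implementation.

A separate *activity-only* multiclass model — one Bernoulli NB over
targets-as-classes, trained on actives alone — serves as the baseline
ranking method: the posterior for one target is normalized against the
probability that the query is active on every other panel target.
Target ranking ties break by stable panel order.

Empirical priors at 1:100 imbalance mean a query needs roughly 4.6 nats
of likelihood evidence before the active posterior exceeds 0.5. This is
intentional: it is what keeps the inactive side of the confusion matrix
near-perfect, at the cost of recall for small or diffuse classes — small
classes additionally suffer because conditionals estimated from few
actives are biased toward 0.5 by smoothing, which systematically
depresses the active-class likelihood relative to the (much better
estimated) inactive class.

## Decision thresholds

Raw posteriors become binary calls in one of two ways:

- **Default rule**: active iff P(active) > 0.5 (strict — "activity if
  P(activity) exceeds P(inactivity)").
- **Calibrated per-target threshold**: active iff score ≥ t (inclusive),
  where t is found by stratified 5-fold cross-validation: out-of-fold
  probabilities are produced by refitting on the other four folds, every
  grid value t ∈ {0.100, 0.101, …, 1.000} (step 0.001) is applied, and
  for each of F1, accuracy, precision and recall the grid point with the
  best fold-averaged metric becomes that metric's threshold.

Numerical conventions: precision is 0 when nothing is predicted active
and F1 is 0 when precision + recall is 0; ties in the grid argmax break
toward the smallest threshold, with averaged values within 1e-12 of the
maximum counted as tied so that mathematically identical metrics reached
through different confusion counts (F1 = 2/3 via 0.5·1.0 vs
(5/9)·(5/6)) do not resolve on a last-ulp rounding difference. Fold
assignment is a seeded per-class round-robin deal, which keeps every
fold's class count within one example of exact proportionality and keeps
working (with a warning) when a class has fewer members than folds.

The value of a calibrated threshold over the default rule is summarized
by the enrichment ratio R = log₂(metric_with / metric_without); zero
denominators are flagged (±∞ / undefined) rather than imputed, and
flagged values are excluded from summaries.

## Evaluation statistics

- **Confusion metrics** with the zero-division conventions above,
  computed per fold and averaged.
- **PR-AUC**: trapezoidal integration of precision over recall across
  all score cut-points. The curve is anchored at recall 0 with the
  strictest cut-point's precision (not the conventional precision = 1
  sentinel), so that completely uninformative constant scores integrate
  exactly to the positive prevalence.
- **BEDROC** (α = 20, the community-standard early-recognition weight):
  implemented directly as (S − S_min)/(S_max − S_min) with
  S = Σ_actives exp(−α·rankᵢ/N), which is algebraically the standard
  RIE-normalized definition and is exactly 1/0 at the ranking extremes.
- **Top-k recall/precision** over per-compound ranked target lists.
- **Paired model comparison**: two-sided Wilcoxon signed-rank on
  per-target metric pairs, zero differences discarded; an all-tied input
  short-circuits to p = 1 with a warning (the underlying routine would
  reject it). At least six pairs are required.

## Applicability domain

The AD score of a query against a target is its maximum Tanimoto
similarity to the model's training actives (actives by default — the
activity-relevant chemical space; inactives can be included). Bands:
**reliable** ≥ 0.3, **caution** [0.1, 0.3), **low** [0.03, 0.1),
**unreliable** < 0.03. The two upper cut-offs bracket the empirically
observed grey zone in which NB posteriors for true actives swing between
extremes; below 0.03 the training data simply does not cover the query.
The 0.2–0.3 and 0.03–0.1 intervals are not separately labelled by the
underlying analysis, so the bands are made contiguous; all cut-offs are
configurable.

## Synthetic panels

Desk-scale testing cannot use the multi-hundred-million-point corpora
the method is designed for, so the `synthetic` module generates
fingerprint panels with exactly controllable structure:

- Each target class draws a seed bit pattern at density 0.05 (≈ 102 of
  2048 bits — the sparsity scale of real ECFP_4 fingerprints).
- Actives are *density-preserving mutations* of the seed: each seed
  on-bit is lost with the mutation rate m, and every position gains a
  compensating noise bit at rate g = ms/(1 − s(1 − m)). Expected bit
  density is therefore identical at every m, intraclass similarity
  decreases strictly monotonically from 1 (m = 0) to background level
  (m = 1), and separability comes from pattern structure, never bit
  count. (A naive symmetric per-bit flip fails both properties: density
  grows with m, and intraclass Tanimoto turns non-monotone above
  m ≈ 0.25 because dense random vectors are mutually similar.)
- Inactives and the sphere-exclusion candidate pool are background draws
  at the same density; optionally, "experimental" inactives can instead
  be drawn as mutations of the class seed at their own rate, emulating
  measured inactives that share scaffolds with actives.
- Compounds are fingerprints directly — no SMILES round trip — for speed
  and exact similarity control. A separate hard-coded fixture of ~20
  real drug-like SMILES (including a salt, sub-100 Da molecules,
  blacklisted-element compounds and a > 900 Da macrocycle) exercises the
  structure-handling path end to end.

What the panels do **not** emulate: hashed-bit collisions, the heavy-
tailed bit-frequency distribution of real fingerprints, activity cliffs,
assay noise, and the correlation structure of real chemical series.
Passing the synthetic recovery checks therefore demonstrates the
correctness and the qualitative behaviour of the pipeline (imbalance
handling, similarity→performance coupling, sphere-exclusion effects),
not the quantitative accuracy attainable on real bioactivity data.

### Study problem sizes

Chosen once, as the package's reference conditions:

- **Recovery panel**: 20 targets × 50 actives, 1:100, mutation 0.05 —
  a tight, well-populated panel on which 5-fold CV must achieve mean
  active recall ≥ 0.9 and inactive recall ≥ 0.99.
- **Similarity gradient**: mutation rates {0.1, 0.25, 0.4, 0.55, 0.7,
  0.85, 0.95} (evenly spanning tight classes to background scrambling),
  10 targets × 30 actives at 1:100 per rate; per-class F1 must correlate
  positively (Spearman) with the top-5-neighbour class similarity.
- **Sphere-exclusion direction**: 10 targets × 30 actives whose
  experimental inactives are near-active analogues (inactive mutation
  0.4) at 1:10; topping up to 1:100 with sphere-excluded background must
  raise mean CV precision.
- **Threshold direction**: 20 targets × 200 actives at 1:5 with heavy
  class overlap (mutations 0.4/0.55, 256 bits) — a regime where scores
  genuinely overlap, calibration matters, and the calibrated thresholds
  generalize (half the class calibrates, half is held out);
  recall-optimal thresholds must give higher recall and lower precision
  than precision-optimal thresholds on the held-out half. At 1:100 this
  comparison is degenerate: active posteriors pile up below the 0.1
  grid floor and all thresholds tie; with too few calibration
  compounds the precision-optimal threshold is too noisy to carry its
  ordering to held-out data.

## Known limitations

- Bernoulli NB assumes feature independence; correlated substructure
  bits (ubiquitous in real chemistry) make posteriors overconfident.
  The AD bands exist precisely because raw posteriors cannot be read as
  calibrated probabilities far from the training data.
- The sphere-exclusion sampler guarantees dissimilarity from actives,
  which inflates internal-validation performance for classes balanced
  this way; evaluation reports tag inactive origin so the two regimes
  can be separated.
- Putative inactives are presumed, not measured; a fraction are
  inevitably false negatives in truth.
- Model persistence uses NumPy `.npz` archives (exact float64 round
  trip, version- and fingerprint-config-checked on load); files are not
  interchangeable across incompatible format versions by design.
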