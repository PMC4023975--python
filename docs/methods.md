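# Methods

## Study model

A study is one compound's dosing experiment in male rats: treated groups at
one or more doses and sacrifice times, a time-matched vehicle group per
time point, a liver histopathology report per animal, and up to four
measurement matrices (clinical chemistry in serum, metabolite profiles in
serum and liver, transcripts in liver).  Platforms may cover different
sample subsets — metabolite profiling typically skips part of the design —
and missing cells are first-class everywhere.  Control matching uses the
key `(study_id, time_h)`: vehicle animals are never borrowed across
studies, because independent studies have independent baselines.

Doses keep their unit as free text (designs mix mg/kg and mM/kg); they are
only ordered within a treatment, never compared across treatments.

## Preprocessing

All values are log2-transformed and centered by subtracting the
time-matched vehicle-group mean *on the log2 scale* (a geometric mean on
the raw scale).  This is deliberate: an arithmetic mean of raw intensities
would shift borderline two-fold calls.  Vehicle groups are therefore
centered at zero exactly.  A vehicle group of size one is allowed with a
warning; a sample with no matched vehicle group, or a parameter with no
observed control value in the matched group, yields missing deltas plus a
warning rather than an imputed baseline.  Rounding to two decimals happens
only when report tables are serialized, never in computation.

## Classification

Histopathology anchors the labels.  The qualifying findings are
apoptosis/single-cell necrosis, inflammation, hepatocellular vacuolation
not attributable to fat, hemorrhage, and necrosis; any qualifying finding
of any grade makes the animal **positive**, irrespective of serum enzymes.
Otherwise a control-centered log2 delta ≥ 1 (inclusive — "at least
two-fold") in either ALT or AST makes it **increased**; the rule is
one-sided, decreases never trigger it.  Everything else, and every vehicle
animal, is **negative**.  Vehicle animals whose data contradict the label
(noise can push an enzyme past two-fold) are forced negative with a
warning: their deviations define the zero point of the centering, so they
are negative by construction.

Animals missing both enzymes keep their histopathology-driven label with
`alt_ast_evaluable=False` and are excluded from every confusion-matrix
cell when the ALT/AST rule is scored as a diagnostic.  With labels built
this way, the rule's false positives are exactly the evaluable increased
animals — an invariant the tests assert.

## Marker discovery

Per platform, each parameter is tested positive vs negative with a
two-tailed pooled-variance t-test (df = n₊ + n₋ − 2) on the deltas, with
the increased class held out so that possible early-injury animals do not
dilute the negative class.  The t statistic is computed vectorized
in-package; scipy's implementation serves as an independent cross-check in
the tests.  Degenerate cases: identical constant groups give (t = 0,
p = 1); zero pooled variance with unequal means gives p = 0 with a
"degenerate variance" note; parameters with fewer than two observed values
in either class are skipped with a logged reason, not imputed (this covers
analytes with sparse coverage such as GGT).

Benjamini–Hochberg adjustment runs within each platform separately, over
the testable parameters only.  A marker is significant when FDR < 0.05 and
|logFC| > 1 (strictly), where logFC is the positive-minus-negative
difference of class means; since the negative class is approximately
centered at zero the two candidate definitions (class-mean difference vs
positive-class mean) nearly coincide, and the difference form is symmetric
and directly testable.  Ranking is by p-value, then |logFC| descending,
then parameter id — the last tie-break exists purely for determinism.

Class profiles are Gaussian kernel densities of the per-parameter class
means, one bandwidth for all classes from Silverman's rule on the pooled
means (fallback 0.1 when the spread is degenerate), evaluated on a shared
grid extended six bandwidths beyond the data so each density integrates to
one within 1e-6.  The heatmap matrix orders columns
control-negative / treated-negative / increased / positive and rows by
platform (transcripts, serum metabolites, liver metabolites, clinical
chemistry), keeping missing cells distinct.  Negative-class animals whose
|delta| exceeds two-fold on at least three of the top-ranked markers are
flagged, with the triggering markers and fold changes listed — the signal
to re-read that animal's slides.

## Enrichment

The transcript selection for over-representation is the prefix of the
p-value ranking below 10⁻⁷, capped at 500, fold change ignored.  Each term
is scored with the one-sided Fisher exact test, i.e. the hypergeometric
upper tail P(X ≥ overlap) with the annotated measured transcripts as the
population.  No multiple-testing correction is applied at this stage (term
p-values are reported raw, conventional reporting threshold 10⁻⁵); term
sets are taken as given from GMT input, without ontology-graph
propagation.

## Synthetic data generator

The generator stands in for the wet-lab design so that every stage is
testable without animal data.  Defaults emulate the modeled study: 280
animals (180 treated across eight compounds, 100 vehicle), groups of 5
(three Cyclosporine A groups and two Erythromycin groups of 4, matching
the printed per-treatment totals), time points 1.5/3/6/24 h, platform
sizes 23 / 50 / 80 / 500 parameters.  Metabolite platforms omit the
non-profiled groups, so they cover a subset of samples.

Each animal carries a latent severity
`potency(treatment) · (dose/dose_max)^1.3 · (time/24 h)^0.3`, multiplied by
log-normal noise (sd 0.25 on the log scale).  The dose exponent > 1 keeps
low-dose groups quiet; the mild time exponent reflects that even early
sacrifices of potent treatments show effects.  Potencies are chosen so the
histopathology threshold separates the overtly toxic regimens (ANIT high
dose, Erythromycin, Methylene Dianiline, Phalloidin high dose) from
enzyme-only responders (Amineptine, Tetracycline) and inert regimens
(Cyclosporine A, Glibenclamide).  Severity drives three layers:

* **Histopathology** — a finding is drawn with probability
  `logistic((severity − 2.0)/0.25)`; extra findings (inflammation,
  necrosis, hemorrhage) switch on at progressively higher severity.
  Non-toxicity observations ("glycogen content") appear at random and are
  never classified on.
* **Serum enzymes** — ALT and AST receive a shift `1.0 · severity` on the
  log2 scale, so animals with severity near 1 straddle the two-fold rule:
  the "increased" phenotype is produced mechanistically, below the
  histopathology threshold, and the classifier has to rediscover it.
* **Planted markers** — each effect is the full shift Δ times a monotone
  fraction of severity: a convex quadratic ramp reaching the effect's
  `increased_fraction` (default 0.5) at the enzyme-rule severity, linear
  to 1 at the histopathology threshold, constant beyond.  The convex start
  keeps sub-threshold animals nearly quiet, so the negative class stays
  close to zero and the increased class lands between negative and
  positive — the geometry that validates the three-way partition.

Measurement noise is Gaussian on the log2 scale (sd 0.5), which puts
P(|N(0, 0.5)| ≤ 1) ≈ 95.4% of large-sample control deviations within
two-fold with rare excursions toward four-fold — the stated control
envelope.  Raw values are `2^(baseline + effect + noise)`; GGT carries a
40% missingness rate to mimic its reduced coverage.  The default planted
effects are 5 clinical-chemistry analytes, 5 metabolites per matrix and
58 transcripts, with magnitudes in the range real marker tables span
(ALT/AST come from the severity coupling rather than planted specs, so the
clinical-chemistry platform yields 7 recoverable markers).

Randomness is counter-based: every parameter row and every animal has its
own Philox stream keyed by a stable hash of (seed, purpose, platform, id).
A fixed config is therefore bit-stable, and adding parameters to a
platform never reshuffles the draws of existing ones.

What the generator does **not** emulate: pharmacokinetics or
compound-specific mechanisms; correlated parameters (noise is independent
across parameters, so FDR behavior under dependence is untested);
platform-specific technical artifacts (batch effects, intensity-dependent
variance); and the time-course structure of individual markers.  Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated noise model, not performance on real correlated omics data.
One visible consequence of the simple enzyme coupling: every synthetic
histopathology-positive animal also shows a large ALT/AST rise, so the
simulated rule sensitivity is near 100%, higher than real studies where
early sacrifices show morphology without enzyme leakage; likewise the
synthetic increased class is somewhat larger than the emulated design's,
because independent enzyme noise at sd 0.5 fires the two-fold rule
spontaneously in a few percent of treated, histopathology-negative
animals.

## Numerical and design choices

* Threshold semantics: the enzyme rule is inclusive (Δ ≥ 1); the
  fold-change filter is strict (|logFC| > 1).  Both boundaries are
  unit-tested.
* BH adjustment is delegated to `statsmodels`; the test oracle is an
  independent brute-force step-up enumeration.  Fisher tails are
  `scipy.stats.hypergeom`; the oracle is direct combinatorial counting.
* The acceptance-style Monte-Carlo suites use reduced problem sizes chosen
  for statistical adequacy: 200 seeds × 500 parameters for null
  calibration (pooled type-I error pinned within its 99% binomial
  interval), 50 seeds at class sizes 25 vs ~130 for planted-marker
  recovery.
* The pipeline summary surfaces every threshold; two runs with the same
  configuration are byte-identical (round-trip-safe float parsing, sorted
  JSON keys, no timestamps).

## Known limitations

* FDR guarantees are only as good as independence across parameters; real
  omics matrices are correlated.
* The nine-term result of a real transcript-enrichment analysis depends on
  the annotation release and ontology propagation, which are out of scope;
  the enrichment stage is exercised on synthetic term sets.
* Dose/time severity maps are stand-ins: no quantitative dose–response
  information per compound is modeled.
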