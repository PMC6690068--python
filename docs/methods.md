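# Methods

## Problem setting

Given per-target bioactivity records (compound structure, measurement
relation, pChEMBL value = −log10 of a molar half-maximal activity), the
package builds two kinds of binary activity models per protein target and
compares them under a shared evaluation protocol:

- a **QSAR arm**: a class-weighted random-forest classifier whose output is
  P(active) per compound;
- an **MCP arm**: a Mondrian (class-conditional) conformal predictor
  wrapped around the same forest, whose output is a pair of p-values and,
  at each significance level ε, a prediction set ⊆ {active, inactive}.

## Curation model

Records are kept when the relation is '=' (exact measurement) or '<'
(censored: activity weaker than the reported value, treated as
high-quality inactive evidence), a pChEMBL value is present, the row is
not flagged as a potential duplicate, carries no data-validity comment,
its activity comment is not "inconclusive"/"undetermined", and its source
is in a configurable allow-list (default: literature = 1 and
DrugMatrix = 15). When an optional `standard_type` column is present, a
priority list (IC50 before Ki) selects one activity type per
(target, structure, source) before aggregation, reflecting that DrugMatrix
reports both and the two are close.

Structures are reduced to non-stereospecific canonical SMILES, so
stereoisomers collapse to one compound. Within a (target, structure)
group the median of the '=' pChEMBL values is used; a structure with only
'<' records is carried as censored-inactive. Measured values take
precedence over censored ones for the same structure — '=' is the
higher-information measurement, and pooling a censored bound into a median
of exact values has no clean interpretation.

Labelling uses the Illuminating-the-Druggable-Genome thresholds
(kinase 7.5, GPCR 7, nuclear receptor 7, ion channel 5) with 6.5 for any
other family; a value exactly at the threshold is active (the thresholds
are published as "≥"). A target is retained when it has ≥ 2 distinct
publications (checked first, as the retention rules are ordered) and
≥ 40 actives / ≥ 30 inactives at its family threshold; failing the counts,
everything is relabelled at the 6.5 default and the counts re-checked.
Relabelling never changes the compound set, only the labels.

## Features

2048-bit Morgan fingerprints (radius 2) concatenated with six
physicochemical descriptors (MolWt, NumHDonors, NumHAcceptors,
NumRotatableBonds, MolLogP, TPSA), the descriptors min–max scaled to [0, 1].
The scaler is fitted on each model's training portion only and applied to
test/calibration/external compounds (avoiding leakage through the split);
a `scaler_scope="global"` switch fits once per dataset instead, for runs
that prioritise matching a single-scaler workflow. Out-of-range values are
not clipped; a constant column maps to 0. Feature order is fixed (bits
then descriptors) and preserved bit-exactly through the CSV round-trip.
Structures are canonicalized as given; salt stripping and charge
neutralisation are assumed to have happened upstream.

## Mondrian conformal prediction

The conformity score of a compound for class c is the forest's predicted
probability for c. Calibration keeps one sorted score list per true class.
For a new compound with score σ_c, two p-value conventions are provided:

- **literal**: p_c = #{s ∈ cal_c : s < σ_c} / n_c — the direct counting
  rule with strict ties;
- **adjusted** (default): p_c = (#{s : s ≤ σ_c} + 1) / (n_c + 1) — the
  finite-sample-corrected definition whose per-class coverage guarantee
  (error rate ≤ ε under exchangeability) is exact.

Both are exposed because the tie/correction convention is a genuine free
choice in the counting formulation; the mode used is recorded in outputs.
Class c enters the prediction set iff p_c > ε, giving the four categories
single-active / single-inactive / both / empty, and sets are nested in ε
by construction.

The calibration split (30% of the training portion) is stratified on the
label rather than purely random: on small imbalanced targets a purely
random split can leave a class's calibration list empty, which makes the
predictor undefined. This is a deliberate, logged deviation from a plain
random split.

## Evaluation protocol

Per target, 100 (default) stratified 80/20 splits are drawn; both arms use
exactly the same split seed per repeat so their test sets coincide. The
QSAR arm trains on the full 80%; the MCP arm splits that 80% into 70%
proper-training / 30% calibration, so its underlying model sees 30% less
data — accepted deliberately so each method uses 100% of the target's data
in its own way. A compound's outcome is the median of its per-repeat
predictions over the repeats in which it was a test compound (a compound
is never predicted by a model it helped train); prediction sets are then
derived from the median p-values ("median-then-assign"). Compounds that
never landed in a test set are reported missing, not imputed — at 100
repeats this is vanishingly rare, at the reduced repeat counts of the
synthetic suites it simply shrinks the evaluated set. The QSAR hard-class
rule is P(active) ≥ 0.5 (the conventional majority-probability cut; no
alternative is suggested by the modelling setup).

Metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), CCR = their mean.
For prediction sets, `incl` counts 'both' as correct with the whole class
as denominator, while `excl` removes 'both' compounds from numerator and
denominator; **'empty' assignments are errors in both variants** (only
'both' has a defined special treatment; this choice shapes the
high-confidence excl numbers and is therefore stated prominently).
Validity at ε: the rate of compounds whose true class is outside the
prediction set must not exceed ε; 'both' always contains the truth.
Family-level aggregation is the unweighted mean over a family's targets.
Tanimoto diagnostics report the median |A∧B|/|A∨B| over all cross-set
fingerprint pairs (all pairs, not per-test-compound maxima — the
alternative reading; all-pairs is the plainer statistic), with 0/0 := 0.

Temporal validation: targets modelled in release A are evaluated on
release-B structures absent from A for that target, labelled with the
*training* release's threshold (the model's decision boundary should not
drift with the validation data). External compounds are predicted by every
repeat's models and median-aggregated; metrics are pooled over targets
because per-target new-compound counts are small (per-target rows are
suppressed below 10 compounds by default).

## Synthetic data generator

The generator emulates the structure of a curated bioactivity extraction,
not its chemistry. Defaults describe a realistic mid-size target panel:
400 compounds per target (near the real median of ~391), active:inactive
ratio 0.8 (the real panel's median), three publications, 30% of inactives
reported as censored '<' rows, and small rates (2–5%) of duplicate
measurements, flagged duplicates, "inconclusive" rows and '>' relations so
every curation filter fires on realistic input.

Class structure: 8 informative fingerprint bits drawn Bernoulli(0.5 ± s/2)
per class over a Bernoulli(0.1) background, plus six pseudo-descriptors
from class-shifted normals (shift 1.5·s·σ). The separability knob s was
fixed at bit-count 8 so that s≈0.5 gives a Bayes error near 10% — the
difficulty regime of a typical QSAR panel (CCR ~0.8–0.9) — while s=0 is
exactly chance and s≥0.8 is near-perfectly learnable. Measured pChEMBL
values are drawn ≥ 0.3 log units away from the family threshold so
labelling is unambiguous unless a test asks for boundary cases. SMILES
mode draws structures from a fixture list of ~200 valid chain/benzene
molecules (including stereo pairs that collapse under canonicalization);
feature mode emits opaque structure tokens with precomputed feature rows
and is the default for model-level work.

What the generator does **not** emulate: real chemical-space clustering
(series/scaffold structure and train–test similarity gradients),
inter-assay variability beyond a uniform margin, correlated fingerprints,
or family-dependent difficulty. Passing the synthetic suites therefore
demonstrates the machinery's correctness and its statistical guarantees
under exchangeability — not attainable performance on real extractions.

## Benchmark suites and problem sizes

The suites in `conformal_qsar.suites` run desk-scale versions of the study
conditions, sized to finish in minutes on one core: 100-tree forests,
6–9 repeats, 20–50 targets of 250–400 compounds (library defaults remain
300 trees / 100 repeats). Observed behaviour mirrors the real-data
findings directionally: ≥ 98% of Mondrian models valid at every confidence
level with per-class error below ε; the 'both' fraction rising and the
'empty' fraction falling as confidence goes 70→80→90%; chance-level CCR at
zero separability and ≥ 0.9 at s = 0.9; and temporal CCR matching internal
CCR on exchangeable release pairs while dropping sharply under a
separability shift. The weighting suite uses separability 0.7 for its
ratio-0.15 targets: at harder settings the minority class is unlearnable
for either configuration and the weighted-vs-unweighted comparison
degenerates (both collapse to majority voting).

## Known limitations

- Conformal validity is guaranteed only under exchangeability; the
  median-over-repeats aggregation makes empirical error conservative
  (below ε) rather than exactly ε.
- The literal p-value mode has no finite-sample guarantee; it exists for
  faithfulness to the counting formulation and differs from adjusted mode
  by O(1/n_cal).
- Curation reproduces source filters as column filters on the input table;
  it does not reproduce upstream database semantics (duplicate flagging,
  pChEMBL computation from raw values).
- The generator's independence assumptions make synthetic targets easier
  than real ones at matched nominal difficulty; absolute metric values on
  synthetic data are not forecasts for real extractions.
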