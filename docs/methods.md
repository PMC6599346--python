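# Methods

## Model

`fixensemble` treats each of seven in-silico predictors as a fixed binary
classifier of missense-variant effect and builds a meta-classifier on top
of them. Two layers:

**Per-tool layer.** Each tool has a registry entry (`ToolSpec`) recording
its native score range, its dichotomisation threshold and side, and its
rescaling transform:

| tool | native range | deleterious when | rescaling to [0, 1] |
|---|---|---|---|
| SIFT | [0, 1] | score < 0.05 | 1 − score |
| PolyPhen-2 HumDiv | [0, 1] | score ≥ 0.5 | score |
| PolyPhen-2 HumVar | [0, 1] | score ≥ 0.5 | score (evaluation only) |
| SNAP2 | [−100, 100] | score > 0 | (score/100)² |
| MutationAssessor | [−6, 6] | score ≥ 1.9 | 0 if < 1.9, else log₅(min(score, 5)) |
| PANTHER (subPSEC) | [−10, 0] | score < −3 | 1 if deleterious else 0 |
| PROVEAN | [−14, 4] | score ≤ −2.5 | 1 if deleterious else 0 |

Boundary conventions that needed a decision: SIFT at exactly 0.05 is
tolerated (benign); MutationAssessor at exactly 1.9 is medium impact
(deleterious); PANTHER at exactly −3 is probably benign; PROVEAN at
exactly −2.5 is deleterious, matching the tool's own published cutoff
convention. SNAP2's sign is taken from the tool's documentation
(positive = effect). MutationAssessor scores above 5 are clamped so the
log₅ transform cannot exceed 1; scores outside any native range are
clamped with a logged warning rather than rejected, since web-service
exports occasionally overshoot. Two deliberate quirks of the published
transform are kept as-is: (s/100)² is even, so a strongly neutral SNAP2
score of −90 rescales to 0.81, and PANTHER/PROVEAN contribute only 0/1.
PolyPhen-2 HumVar is binarized and evaluated like any other tool but never
enters a combined score.

**Combination layer.** With rescaled member scores s_i and weights w_i,

    gP = mean(s_1..s_6),  wgP = Σ w_i s_i / Σ w_i

The weighted denominator Σ w_i (each unit term of the unweighted
denominator replaced by that tool's weight) makes wgP a weighted mean, so
the score is a convex combination in [0, 1] and the shared 0.5 cutoff is
meaningful; a score exactly at the cutoff is deleterious. gP/wgP6 combine
SIFT, PolyPhen-2 HumDiv, SNAP2, MutationAssessor, PANTHER, PROVEAN; wgP4
drops the last two (the least accurate). Weights come either from the
proportional rule w_i = acc_i / max(acc) (`compute_weights`, or
`EnsembleClassifier(weights="accuracy")` fitted on labelled calls) or from
the published default set {1, 0.974, 0.924, 0.896, 0.850, 0.772}. The two
do not coincide on the published accuracy column — the provenance of the
printed defaults is not recoverable — so both are exposed and the printed
defaults are the default for reproduction runs. A variant missing any
member score receives no combined score or call (renormalising weights
over observed members is available behind `combine`'s caller but off by
default, to keep calls comparable across variants).

## Evaluation

Phenotype is dichotomised from residual FIX activity: severe when activity
∈ [0, 5] % (the interval is closed at 5 — the clinical moderate band 1–5 %
belongs to the severe side), non-severe above 5 %. When only a clinical
label is available, severe/moderate map to severe and mild to non-severe;
when both are present and disagree, the activity measurement wins and the
conflict is logged.

A deleterious call on a severe variant is a true positive; sensitivity =
TP/(TP+FN)·100, specificity = TN/(TN+FP)·100, accuracy = (TP+TN)/n·100.
Strata with an empty class (the propeptide has no non-severe variants)
make a ratio 0/0: such metrics are reported as 0 % with a cleared
`defined` flag rather than NaN, keeping stratified reports rectangular
while staying machine-distinguishable. The deleterious fraction
(deleterious calls / all calls) is computed as a separate quantity from
accuracy; the two are distinct despite coinciding numerically in some
published per-tool summaries. Concordance between k call vectors is the
fraction of variants on which all k agree, over variants where all calls
are present. Variants lacking a call for a tool are dropped from that
tool's metrics with the dropped count reported.

Domain groupings: each of the five domains alone, the light chain
(Gla + EGF-1 + EGF-2), and all five domains together (`all_five`, alias
`leader_plus_light`). The association report defaults to the four-way
stratification (all five, Gla, EGF-2, light chain).

## Association tests

For each (grouping × tool) the 2×2 table of call (deleterious/benign) by
severity (severe/non-severe) is tested with the uncorrected Pearson χ²
(df = 1) and the two-sided Fisher exact test under the point-probability
rule (sum of hypergeometric probabilities, at fixed margins, no larger
than the observed table's) — the SPSS/R convention. No continuity
correction and no multiple-testing correction are applied, matching the
analysis this package reproduces. Tables with a zero margin have an
undefined χ²; those rows carry NaN statistics and a `degenerate` flag.
Significance at α = 0.05 is a flag column, never a filter. Both tests are
delegated to scipy (`chi2_contingency(correction=False)`,
`fisher_exact`); the test suite checks them against an independent exact
integer-arithmetic enumeration (all 2×2 tables with n ≤ 30, agreement to
1e−12) and the closed form n(ad−bc)²/∏margins.

## Synthetic data generator

The generator emulates the structure of the study table, not any real
variant: 215 variants with exact per-domain severe/non-severe counts
(11/2, 16/0, 55/16, 41/27, 39/8 across signal peptide, propeptide, Gla,
EGF-1, EGF-2; 162/53 overall). Severe variants draw FIX activity uniform
on [0, 5] %, non-severe uniform on (5, 100] %, with a consistent clinical
label, so both dichotomisation paths are exercised. For each tool an
intended call is drawn Bernoulli at the tool's (sensitivity, specificity)
operating point given the true class, and a raw score is then drawn
uniformly within the correct side of that tool's threshold inside its
native range — uniform because no score distribution is available to
emulate; a draw landing on the wrong side of a boundary is redrawn, so
binarization recovers the intended call exactly. Same seed, same config ⇒
byte-identical tables. Positions are drawn inside per-domain residue bands
(signal peptide −46..−19, propeptide −18..−1, Gla 1..92, EGF-1 93..129,
EGF-2 130..192) in signed Yoshitake numbering.

The study-mimic preset uses the published overall operating points for
SIFT (0.932/0.189) and MutationAssessor (0.92/0.264); the other tools'
overall sensitivity/specificity were not published, so their preset points
were fixed once so that each tool's expected deleterious count at the
162/53 composition matches its published count (PolyPhen-2 HumDiv
0.914/0.226 → 189, HumVar 0.864/0.264 → 179, SNAP2 0.877/0.208 → 184,
PANTHER 0.870/0.189 → 184, PROVEAN 0.840/0.245 → 176).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: tool errors are independent across tools,
whereas real conservation-based predictors are strongly correlated. The
combined functions therefore average away more error on synthetic data
than they can in reality (on the preset, gP/wgP6/wgP4 look more sensitive
than any member tool, and concordance between tools is lower than
observed on real variants). Checks of combined-function behaviour on
synthetic data are structural and property-based for this reason, not
value-for-value. Raw scores are also uniform within threshold sides, so
score *magnitudes* carry no signal beyond the side of the threshold.

## Numerical and reporting choices

Percentages are kept unrounded internally and in machine output; the
acceptance report rounds to 4 decimals (tiny p-values keep 3 significant
digits instead). Generated raw scores and activities are rounded to 4 and
3 decimals respectively so tables round-trip through TSV exactly. The
problem sizes used by the verification suite — 10,000 per class for
parameter recovery, 10,000 replicates of n = 400 null tables for the χ²
type-I-error check, exhaustive Fisher enumeration up to n = 30 — were
chosen to keep binomial/enumeration error far below the asserted bounds
while completing in about a minute.

## Limitations

* Inter-tool correlation is not modelled (no covariance information
  exists to calibrate it).
* No VCF/HGVS-DNA parsing, numbering liftover, or retrieval from variant
  databases; the predictors themselves are never invoked — raw scores are
  inputs.
* No ROC/AUC analysis (all metrics are at the fixed thresholds) and no
  alternative consensus schemes (majority vote, logistic meta-learners).
* Domain assignment is data-driven: only the EGF-1 residue interval ships
  as a default; other domain boundaries must come from the input table or
  user configuration.
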