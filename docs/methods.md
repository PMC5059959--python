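# Methods

This note documents the statistical procedure the package implements, the
choices made where the procedure's published description leaves room, and
what the synthetic cohorts do and do not establish.

## The discriminant equation

A low-mass-ion discriminant equation (LOME) is a signed linear score over a
small panel *D* of discriminative ions selected from a MALDI-TOF peak table:

    DS(sample) = Σ_{i ∈ D} w_i · x_i

where `x_i` is the sample's Pareto-scaled intensity on reference ion `i` and
`w_i` its weighting factor from a PCA-based discriminant analysis.  A sample
screens positive when DS exceeds the decision threshold — 0 under the sign
rule, or a cut-point trained on the training set.  DS exactly 0 screens
negative: the strict inequality favors specificity, which is the binding
requirement in a screening context where false positives trigger invasive
follow-up.

## Two-stage training

Samples are trisected into Sets A1, A2 and B, stratified by class (and
clinical stage when available) so each stratum's three set sizes differ by
at most one.  Groups excluded from training can be routed directly to Set B;
they contribute per-group specificities but never the headline confusion
counts.  The stages are:

1. **Reference measurement (Set A1 only).**  Each replicate measurement of
   the A1 samples is tabulated on its own consensus axis, normalized,
   Pareto-scaled and fitted with PCA-DA.  The replicate with the best
   training separation (sensitivity + specificity at DS threshold 0; ties
   by Fisher ratio, then lower replicate index) becomes the *reference mass
   spectrum*; its axis anchors all further alignment and its PCA-DA fit
   supplies the loading vector.
2. **Preliminary candidates (search algorithm 1).**  On the weighted
   reference table, an ion qualifies when |weighted intensity| > 0.1
   (strict) in strictly more than half of the intensity columns.
3. **Panel selection (search algorithm 2, Set A = A1 ∪ A2).**  Replicate
   measurements of every sample (excluding the reference replicate) are
   aligned to the reference axis, normalized and Pareto-scaled with
   statistics fitted on Set A columns and then frozen, weighted, and
   averaged per sample.  The germination/growth search below picks the
   panel on the averaged Set A table.
4. **Evaluation.**  Set B columns are transformed with the frozen Set A
   statistics; nothing about Set B influences the model (verified by a
   leakage test: permuting Set B labels leaves the bundle hash unchanged).

## PCA-DA reconstruction

The discriminant analysis is principal component analysis followed by a
two-class Fisher discriminant on the retained component scores:

- PCA is computed *uncentered* (SVD of the column observations).  A
  Pareto-scaled training table has zero row means by construction, so this
  coincides with ordinary PCA there, while keeping the model strictly
  linear: the back-projected direction `w` satisfies `DS_j = Σ_i w_i x_ij`
  with no intercept, which is what lets the same loading vector score
  held-out columns transformed with frozen statistics.
- Components are retained up to the smallest number explaining ≥ 95% of the
  variance, capped at `n_columns − 2` (both configurable).
- The Fisher direction uses the pooled within-class covariance with a tiny
  diagonal ridge (1e-8 × trace/dim) for numerical safety.
- The sign convention makes the target class score positive, and `w` is
  scaled so the training DS has unit pooled within-class standard deviation
  — the usual canonical-variate convention.  This scaling matters: it is
  what makes "per-ion contribution > 0.1" a meaningful sparsity criterion,
  with most ions contributing trivially to the DS and the discriminative
  tail standing out.

## The combinatorial search

Every combination is judged by the sum of its sensitivity and specificity
at DS threshold 0 on the averaged training table.  Ties are resolved by
(1) fewest ions, (2) largest Fisher's discriminant ratio
`(mean₁ − mean₀)² / (var₁ + var₀)`, then lexicographic ion order so the
whole search is deterministic.

**Germination.**  If some single candidate separates the training set
perfectly it is the panel.  Otherwise all 2- and 3-ion combinations are
scored and the best is repeatedly set aside until at most one candidate
remains; the set-aside units are then grouped 2 or 3 at a time, treating
each unit as atomic (a unit's DS is the sum of its members' weighted
intensities, forced by DS linearity), hierarchically until a single unit
remains.  The best unit formed anywhere becomes the seed set.  Singleton
candidates are eligible for seed selection alongside formed units: this is
this package's reading of the procedure, and it guarantees the panel never
scores below any individual candidate.

**Growth.**  All 1-, 2- and 3-ion additions from the remaining candidates
are tried; the best strictly improving enlargement becomes the new seed and
the step repeats.  Acceptance requires strict improvement of a quantity
bounded by 2, so termination is guaranteed and the accepted sequence of
scores is strictly increasing (asserted by tests on the recorded trace).

Leftover candidates never consumed by germination remain available to the
growth pool, and growth may add any candidate outside the seed, including
ions that sit in other germination units.

The exact search evaluates all C(P,2) + C(P,3) combinations; a configurable
cap (default 64) bounds P, keeping the strongest candidates by median
absolute weighted intensity and warning when it engages.  Tests always run
the exact algorithm with small P; an independent trajectory oracle
(recursive enumeration with brute-force scoring, branching over residual
ties) verifies that the implementation returns a reachable outcome attaining
the best reachable score for P ≤ 12.  Notably, branching over *all*
maximum-score choices while ignoring the tie-break priorities can reach
higher final scores than the deterministic algorithm; the priorities are
part of the procedure, so the oracle honors them.

## Preprocessing conventions

- **Alignment** assigns each sample peak to the nearest reference ion in
  relative distance `|mz_peak − mz_ref|/mz_ref`, within a 300 ppm tolerance
  (boundary inclusive); ties go to the lower m/z; peaks landing on the same
  ion are summed, conserving total ion current.  Import filters keep peaks
  with intensity ≥ 10 (inclusive) and at most the 10000 most intense.
- **Total-area normalization** scales every column to the mean of the
  fitted columns' intensity sums, so the average training column is
  unchanged.  Peak heights stand in for areas, since the peak lists are
  centroided.
- **Pareto scaling** is `(x − mean)/√sd` per ion with the sample (n−1)
  standard deviation; zero-variance ions map to 0.  After fitting, each ion
  row has mean 0 and variance equal to its original standard deviation.
- Consensus axes (needed before a reference axis exists) pool all peaks of
  the contributing measurements, sorted, starting a new ion wherever the
  gap exceeds the tolerance, with the cluster mean as the axis value.

## Synthetic cohorts

No spectra are distributed with the method, so the package ships a
generator that emulates the study design: one target class plus several
non-target classes (default 4 × 30 samples), six replicate measurements per
sample, 2000 baseline ions drawn uniformly on m/z 50–2500 with a 600 ppm
minimum spacing (twice the matching tolerance, so alignment is unambiguous
by construction; a switch disables it to stress-test alignment), log-normal
baseline intensities (median ≈ 1000, log-sd 1), a small set of planted ions
whose target-class log-intensity is shifted by ±`effect_size`, multiplicative
replicate noise of CV `noise_cv`, and Gaussian per-measurement mass jitter
(default SD 50 ppm, comfortably inside the matching tolerance given the
spacing).  One seed sequence drives everything; each sample consumes its own
deterministically spawned substream, so cohorts are byte-identical under a
fixed seed.

The default noise structure is replicate noise only.  An optional
`sample_log_sd` adds ion-level biological variation between samples; it
defaults to 0 and is a stress knob, not part of the emulated study
conditions.  With it enabled, a known limitation becomes visible: a
*down*-shifted marker cannot be separated perfectly by the sign rule alone,
because the Pareto mean is a mixture mean pulled toward the majority class,
leaving the implicit cut-point well inside the majority cluster's noise.
The growth phase then patches the training set with noise ions.  This is a
property of the method (threshold-at-the-scaled-mean), not of the
implementation; the trained-threshold mode mitigates it.

What passing tests show: the pipeline recovers planted panels, validates
near-perfectly at the simulated effect sizes, and leaks nothing from the
validation set.  What they do not show: performance on real serum spectra,
with correlated ions, isotope envelopes, adducts, batch effects and
detector saturation — none of which are simulated.

## Numerical choices and degenerate inputs

- Score ties in the search compare within 1e-12; growth requires
  improvement beyond the same tolerance.
- Fisher ratios with a zero denominator score +∞ when the means differ and
  0 when they do not.
- Undefined screening ratios (zero denominators) are reported as `NA`,
  never 0; reported percentages round half-up to 2 decimals, full precision
  is kept internally.
- Threshold training scans midpoints of consecutive sorted DS values; ties
  resolve toward maximal specificity, then the smaller threshold.
- Model bundles serialize floats via `repr` (exact for float64) and reload
  with round-trip parsing, so a saved model re-scores identically.
- Problem sizes in the test-suite simulations (e.g. 300-ion cohorts for the
  shared pipeline fixture, 10-candidate pools for the exhaustive oracle,
  20–50 seeded runs for the recovery and null suites) are desk-scale
  choices: large enough to exercise every stage, small enough that the
  whole suite runs in minutes on one CPU.

## Known limitations

- The mzML reader is a minimal decoder for centroided spectra (standard
  binary arrays, 64/32-bit floats, zlib or none); no chromatograms, vendor
  formats, or numpress codecs.  There is no mzML writer.
- Only two-class (target vs rest) discriminants are provided.
- No baseline correction, recalibration, isotope handling or profile-mode
  peak picking: inputs are centroided peak lists.
- The hierarchical germination grouping and the growth pool's composition
  follow the reading documented above; the published description leaves
  both under-specified, and the search trace records every accepted step so
  a run can be audited against either reading.
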