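# Methods

## Estimation model

For two ROI time series of length *n*, the leave-one-out (LOO) Pearson
correlations *r₁ … rₙ* are computed by deleting one volume at a time.  The
implementation centers each series once and downdates the sufficient
statistics (Σx, Σx², Σxy) per deletion, which makes the all-pairs
computation O(n·K²) instead of O(n²·K²); a dedicated brute-force deletion
loop serves as the test oracle and agrees to ~1e−15.

Summaries per pair:

- θ = mean(rᵢ) — the jackknife correlation mean;
- SE = √[((n−1)/n)·Σ(rᵢ−θ)²] — the standard jackknife standard error;
- Bias = (n−1)(θ − r̂) with r̂ the full-sample Pearson correlation;
- a two-sided Student-t confidence interval θ ± t₁₋(1−level)/2, n−1·SE,
  clamped to [−1, 1].

**Selection rule.** If |Bias| ≤ `bias_tol` the estimators agree and θ is
carried forward.  Otherwise the CI bound of smaller absolute value is
selected.  For positive correlations this is the literal lower limit; for
negative correlations the literal lower limit would *increase* the
magnitude, so the rule is stated in terms of magnitude to preserve its
conservative purpose (never inflate an edge that is under suspicion).
Selection operates on signed values; positivization happens afterwards.

**bias_tol = 0.05 (default, configurable).** Because Bias scales the gap
(θ − r̂) by (n−1), at n = 220 this tolerates |θ − r̂| ≈ 2.3×10⁻⁴ — i.e. it
effectively demands estimator agreement.  Empirically (seeded tests), on
clean white-noise data |Bias| stays below ~0.005 and the rule fires on
<0.01% of pairs, while isolated strong contamination pushes |Bias| past
the gate.  A caveat worth knowing: the jackknife bias statistic is most
sensitive to *isolated* outliers.  When several spike volumes share the
contamination, each single deletion removes only a fraction of it and the
clean-deletion drift partially cancels the spike-deletion drops, so |Bias|
grows only slowly with contamination; the gate then fires on a small
fraction of pairs.  The acceptance script measures this fraction rather
than assuming it.

**Confidence level and reference distribution.** A 95% two-sided
Student-t interval with n−1 degrees of freedom on the jackknife SE —
standard jackknife practice; both are configurable.

**Degenerate inputs.** A series that becomes constant after any single
deletion raises an error naming the ROI and volume rather than emitting
NaN; real inputs that trip this indicate extraction problems upstream.
All correlations are clamped to ±(1−10⁻¹²) before the Fisher transform.

## Edge significance and networks

Selected correlations are positivized (absolute value — edge sign is
discarded by design), transformed to z = ½·ln((1+r)/(1−r)), and tested
with the classical Fisher normal approximation: |z|·√(n−3) ~ N(0,1) under
the null, two-sided p.  The companion test of the printed transform is the
natural choice; *n* is the number of volumes actually used (220 by
default; the stacked row count for group networks), with no
effective-sample-size correction for autocorrelation.  Edges with
p < α (default 0.001) form the binary adjacency; there is deliberately no
multiple-testing correction across the 1128 edges — the design uses a
fixed per-edge threshold.  Diagonal conventions: r-matrices 1, z and
adjacency 0, p 1.

Group networks stack per-subject series standardized column-wise (zero
mean, unit variance within subject) before concatenation; without this,
between-subject mean differences masquerade as correlation.  The identical
estimation chain then runs on the stack.

## Graph summaries

- weighted degree: Σⱼ A[i,j]·z[i,j] — z weights restricted to significant
  edges;
- binary degree and Watts–Strogatz local clustering
  C_i = 2·triangles_i/(k_i(k_i−1)) on the binarized graph (C_i = 0 for
  k_i < 2) — the simplest clustering notion for a thresholded graph;
- network density: significant edges / (K(K−1)/2);
- density tertiles: cohorts are split into high/medium/low thirds by
  descending density, ties broken by input order, remainders assigned to
  the denser classes first — a deterministic formalization of the
  qualitative high/medium/low continuum;
- the degree table joins two groups' weighted degrees on ROI, annotated
  with subnetwork labels, sorted descending on the first group.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, not BOLD
physiology:

| parameter | default | meaning |
| --- | --- | --- |
| `t_volumes` | 220 | volumes per subject (TR = 2 s) |
| `ar1_phi` | 0.3 | AR(1) coefficient, a plausible BOLD autocorrelation |
| `spike_rate` | 0.02 | per-volume probability of a global artifact |
| `spike_amplitude` | 4.0 | artifact size, in units of per-ROI SD |
| `r_within` | 0.6 SM/Visual, 0.3 DMN blocks | within-subnetwork coupling |
| `r_between` | 0.1 | between-subnetwork coupling |
| `n_subjects` | 22 | per group |

Innovations are multivariate Gaussian with a block correlation matrix
(eigenvalue-clipped to PSD if a parameter combination requires it), passed
through an AR(1) filter — the same φ for every ROI, so the cross-ROI
correlation structure is preserved — then contaminated with global
same-signed spikes that shift every ROI of a selected volume by
`spike_amplitude` SDs.  Shared spikes inflate plain Pearson correlations,
giving the jackknife something to resist.  Density classes scale the
within-block correlations by 1.0/0.6/0.3 (high/medium/low), reproducing a
one-knob density continuum across a cohort.  Per-subject RNG streams are
derived as `seed + subject_index`, so extending a cohort never perturbs
existing subjects.

What the generator does **not** model: hemodynamic response shape,
physiological noise, spatial smoothness, non-Gaussian tails, or
subject-specific covariance heterogeneity beyond the density classes.
Passing tests therefore demonstrate the estimator's statistical behaviour
under the assumed structure, not performance on real BOLD recordings.

## Problem sizes in tests and the acceptance script

Statistical checks run at the study dimensions where they are cheap
(220 volumes, 48 ROIs, 22-subject stacked groups) and are scaled in
replicate count where precision is the driver: the null calibration uses
200 replicate subjects × 24 disjoint (hence independent) pairs = 4800
null edges, judged against 3 binomial standard errors; spike robustness
pools 200–400 contaminated subjects; block-structure recovery uses 20
seeded 22-subject group runs.  Convergence checks of the generator use
T = 5000 on small matrices.  All stochastic tests are seeded and
deterministic.

## Known limitations

- The Fisher normal test assumes independent volumes; with AR(1)
  autocorrelation the effective sample size is smaller than *n* and edge
  p-values are anti-conservative.  Calibration tests therefore run on
  white-noise nulls; a correction is out of scope by design.
- The bias gate's insensitivity to clustered contamination (above) means
  the pipeline's robustness at realistic spike rates comes mostly from the
  smallness of |θ − r̂|, not from frequent CI-bound substitution.
- Weighted degree uses positivized z weights on significant edges; other
  weight conventions would change the table's absolute values but not the
  subnetwork ordering the tests check.
- BrainNet Viewer export writes zero coordinates (with a warning) unless
  an MNI centroid table is supplied; none is bundled.
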