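# Methods

## Recording model and segmentation

The unit of analysis is an RR (NN) interval series: beat instants
`t_0 < t_1 < …` in seconds and intervals `rr_i = (t_{i+1} − t_i)·1000` ms.
The default tilt protocol places supine at [0, 300) s, tilt at
[315, 495) s and resupine at [510, 810) s, with the two 15-s tilting
transitions excluded.  An interval belongs to a phase iff its
*terminating* beat time falls in the phase's half-open window and in no
excluded window; this assigns every interval to at most one phase and
avoids double counting at boundaries.  The supine window starts at
recording onset (no extra stabilization period is assumed).  A segment
needs at least 60 intervals (≈1 min of beats) to be analyzable;
insufficient segments are carried through marked, never silently dropped.

Artifact handling is automated: an interval is flagged when outside
[300, 2000] ms or deviating more than 20% from the centred 11-beat
running median.  Policies: `flag_only`, `delete` (drop flagged intervals;
kept beats retain their true timestamps, so deletions leave gaps rather
than shifting time), `interpolate` (replace by the local running median —
the pipeline default, as it preserves the beat grid the spectral stage
interpolates over).  Flagging more than 20% of a recording raises a
warning, or an error in strict mode.

## Metric conventions

All dispersion statistics use the sample (n−1) convention, which makes
the Poincaré identity `2·SDNN² = SD1² + SD2²` exact and keeps
`CSI·SDR = 1` by construction.  Mean heart rate is `60000/mean(rr)`
rather than the mean of instantaneous rates — less noisy on short
segments.  RMSSD and pNN50 require at least two successive differences.

The triangular index uses the conventional 1/128-s (7.8125-ms) histogram
bin width with bins anchored at 0 and no density smoothing.

Spectral analysis: the tachogram (rr against terminating beat time) is
cubic-spline resampled at 4 Hz, linearly detrended, and the PSD estimated
by Welch with Hann windows of `min(120 s, segment span)` at 50% overlap.
Band powers are trapezoidal integrals of the PSD over
VLF [0.0033, 0.04), LF [0.04, 0.15), HF [0.15, 0.40) Hz.  Total power is
*defined* as VLF + LF + HF, which makes the normalized units identity
`LF(nu) + HF(nu) = 100` exact whenever TP > VLF.  On a 180-s tilt
segment the VLF estimate rests on a handful of Fourier bins and is
reported but not interpreted.  Estimates on segments under 120 s warn.

Sample entropy follows the standard template-counting definition: both
the length-m and length-(m+1) template sets are truncated to the first
n−m windows, matches use Chebyshev distance ≤ r, self-matches are
excluded, defaults m = 2 and r = 0.2·SDNN.  A zero-variance series, or
zero match counts, yield NaN — never ±inf.  Undefined values propagate as
NaN through panels and deltas; a completeness count travels with the
delta table.

CVI uses the base-10 logarithm of the product of the Poincaré axis
lengths (4·SD1)(4·SD2), the convention under which resting values fall
near 4.5.

## Statistical pipeline

Relative changes %Δ1 (supine→tilt) and %Δ2 (tilt→resupine) are computed
per subject and metric, then summarized as group medians with
linear-interpolation (type-7) quartiles.  Summarizing changes of
medians instead would conflate within- and between-subject variation.

Test selection is a deterministic function of a Shapiro–Wilk gate
(α = 0.05 in every group; undersized or zero-variance groups force the
non-parametric path).  Omnibus: one-way ANOVA or tie-corrected
Kruskal–Wallis with the chi-square reference on k−1 df.  Pairwise:
paired t / Wilcoxon signed-rank for matched contrasts, Welch t /
Wilcoxon rank-sum otherwise.  Welch rather than pooled-variance t is the
default because group variances are not assumed equal.  Signed-rank
handling of zeros follows Wilcoxon's method (discard), with the exact
null distribution for n ≤ 25 without tied magnitudes and the
continuity-corrected normal approximation otherwise; all-zero difference
vectors give p = 1 with a note.  Bonferroni families are the pairwise
contrasts of a single metric (3 phase pairs, or k(k−1)/2 group pairs),
matching the per-table correction style of tilt-HRV reports; no
correction is applied across metrics.  Significance codes are
*, **, ***, **** at p < .05/.01/.001/.0001 on the adjusted p, rendered as
contrast letters repeated per star.

The permutation specificity test shuffles the group-label vector across
subjects (group sizes conserved), recomputes the per-metric
Kruskal–Wallis p for each permuted dataset, and reports the add-one
empirical rank `(1 + #{p_perm ≤ p_obs})/(n_perm + 1)`, which cannot be
exactly zero; a metric is "specific" when its rank is ≤ 0.05.  One
shared permutation per dataset is applied to all metrics, preserving
cross-metric correlation (an independent-streams mode exists behind a
flag).  Non-finite values drop a subject for that metric only, with the
count reported.  At least 100 permutations are required; 10,000 is the
conventional default.

## Synthetic cohort generator

Beats come from an integral pulse frequency modulation (IPFM) model: the
instantaneous rate

    m(t) = r0(t)·[1 + a_VLF sin(2π f_VLF t + φ₀)
                    + a_LF sin(2π f_LF t + φ₁)
                    + a_HF sin(2π f_HF t + φ₂)] + ε(t)

is integrated on a 0.125-s grid and a beat fires at each integer crossing
of the integral.  This produces tachograms with genuine band structure —
the property the Welch stage assumes — rather than RR values sampled
directly from a distribution.  Phase-wise parameters (`r0`, amplitudes)
switch at the protocol boundaries through cosine ramps placed inside the
excluded transitions.  Per-subject oscillator frequencies are drawn once:
f_LF ~ U(0.08, 0.12), f_HF ~ U(0.20, 0.30), f_VLF ~ U(0.012, 0.03) Hz.
ε is white rate noise with SD 0.015·r0.

Group effect sizes are programmed through three numbers per group —
supine HR median, %Δ1 HR median, and the tilt HF-withdrawal factor
(amplitude ratio; HF power scales with its square).  Default medians for
the four-group scenario (Vata-like 68.51 bpm / +19.79% / 0.576,
Pitta-like 70.54 / +19.21 / 0.653, Kapha-like 72.27 / +14.32 / 0.796,
Mixed 70.78 / +15.74 / 0.657) encode the blunted Kapha-like and brisk
Vata-like orthostatic responses the analysis is designed to resolve.
Because withdrawal factors are meant in the RR-amplitude domain, the
rate-fraction amplitudes during tilt are multiplied by the subject's HR
ratio; otherwise the HR rise itself would deepen every measured power
change by the squared RR shrinkage.  The LF and VLF amplitudes rise on
tilt (×1.15 and ×1.5 RR-domain) so that SD2 and LF(nu) increase while
SDNN stays roughly flat — the characteristic tilt signature.  Baseline
HF amplitude declines linearly with age (1.2%/year past 18), giving the
age-band comparisons a real effect to find.

Between-subject dispersions are design choices, fixed once: supine HR SD
8 bpm, %Δ1 HR SD 4.5 points, HF-factor SD 0.06, amplitude SDs ~20% of
their means, resupine HR jitter 1.5%.  They produce IQRs narrower than a
real clinical cohort's (real %Δ1 HR IQRs span ~15 points), so the
generator represents a *cleaner* population: passing recovery tests shows
the pipeline is unbiased and correctly ordered, not that any given
clinical sample size is adequately powered.

Other idealizations: no baroreflex feedback or respiratory coupling
(oscillator frequencies and phases are constant within a subject), no
ectopy or measurement artifacts (the cleaning stage is exercised by unit
tests instead), stationarity within phases, and metadata (BMI, blood
pressure) carried as inert covariates.  Determinism: every subject's
stream is seeded from the cohort seed via `SeedSequence`; the same seed
reproduces byte-identical output files.

## Problem sizes and numerical notes

The validation suite uses scaled-down cohorts chosen for stable
statistics: 40 subjects (10/group) for the population sign pattern, 60
per group for effect-size recovery (a group median's sampling error is
then ≈0.7 points, comfortably inside the ±2 check), 25/group with 500
permutations × 60 replicates for permutation power, and 200 replicates
of a 60-subject exchangeable null for calibration (95% binomial band
2.2–8.6% around the nominal 5%).  Sample entropy is validated against an
O(n²) brute-force double loop; the production path vectorizes the same
definition with `pdist`, so agreement is exact, not approximate.
Kruskal–Wallis keeps the chi-square p even at tiny n (its small-sample
behavior is checked against exhaustive label-assignment enumeration by
rejection ordering, since the chi-square approximation cannot equal the
discrete permutation p numerically).

## Known limitations

- The spectral stage targets short-term recordings; no Lomb–Scargle
  option for heavily gapped series (after `delete` cleaning, the spline
  bridges gaps).
- VLF on 3-min segments is reported but unstable by construction.
- No covariate adjustment (sex, BMI) in the group comparisons; the
  metadata supports adding it.
- The contrast-letter legend is fixed per run; with more than four
  groups letters are assigned in enumeration order.
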