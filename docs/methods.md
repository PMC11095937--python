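# Methods

## Trace analysis

### Detection model

Each ROI trace is ΔF/F sampled uniformly (1 Hz by default). For every
stimulus event the pre-stimulation baseline is the mean and SD of the 20 s
immediately preceding the event onset; when that window would overlap the
preceding event's response window it is truncated at that window's end (with
a warning). Per-event baselines absorb slow drift without requiring a global
detrending step.

A response is *detected* when the trace exceeds
`baseline_mean + 2 x baseline_sd` for at least `ceil(3 s x rate)` consecutive
samples inside the response window. The response window is onset + 15 s
(10 s stimulus plus a 5 s decay allowance, since peaks can lag the pulse);
both windows, the SD multiplier and the sustain duration are configurable
(`DetectionCriteria`). At 1 Hz the sustain rule is >= 3 consecutive
supra-threshold samples (closed count). A zero-variance baseline reduces the
threshold to the baseline mean and is logged. The peak amplitude is the
window maximum minus the baseline mean; the AUC is the trapezoidal integral
of the baseline-subtracted trace with the integrand clipped at zero, so AUC
is always nonnegative.

The K⁺ (depolarization) event is scored with the same rule. A "robust" K⁺
response is therefore operationalized as: detected by the 2 SD / 3 s rule
with a positive peak. Neurons failing it are nonresponsive regardless of
urine events (configurable via `k_required`).

### Classification and indices

A neuron "responds to" a stimulus when at least one of its two presentations
is detected (requiring both is available via `require_both_presentations`;
the stricter rule only shrinks the generalist/specialist sets). Classes:
generalist (both stimuli), specialist_A/B (exactly one), K_only (neither),
nonresponsive (no K⁺ response).

All amplitudes are normalized to the same ROI's K⁺ peak. RI uses the mean
normalized peak of *both* presentations per stimulus — including
presentations that individually failed detection — because the index is
defined on the average evoked amplitude, not on the detection calls;
negative measured peaks are clipped to zero first, which keeps RI and ReI in
[-1, 1]. A urine-responsive neuron whose two amplitude means are both zero
has an undefined RI and is excluded (logged). ReI is computed per stimulus
from the two consecutive presentations, once from normalized peaks
(`rei_amp`) and once from AUCs (`rei_auc`); the AUC integral uses the
response window only, not the full inter-stimulus interval.

Reported percentages are rounded half-up to one decimal, which reproduces
published worked-example fractions exactly (e.g. 10,258 / 16,715 -> 61.4).

## Molecular profiling

Detection of a compound in a sample means abundance above
`detection_threshold`, default 0 (any positive intensity counts; upstream MS
identification FDR control is out of scope). Presence = detected in >= 3
samples of a group; enrichment = >= 6; uniqueness in a binary comparison =
>= 4 in one group and 0 in the other; row reduction drops compounds with
<= 3 detections in both compared groups. Thresholds are absolute counts
tuned to the reference design of 10 individuals per group; with other group
sizes they remain absolute (and configurable) rather than proportions.

Pairwise categorization (generic / specific / absent) uses the presence
call; the six-way scheme uses the stricter enrichment call throughout, the
more conservative reading of "sex-specific across strains". Patterns that
match no named category — including enrichment in two of three strains of
one sex, or in no group at all — are `uncategorized`. Every compound gets
exactly one category, so category counts always sum to the table size.

Concentration indices average over *all* samples of a group, counting
non-detections as zeros (the literal reading of "among all 10 samples
within a group"); compounds with zero means in both groups are excluded
(logged) so CI is always defined and in [-1, 1] with
CI(g1, g2) = -CI(g2, g1).

Quantile normalization replaces each sample's sorted values with the
across-sample rank means; tied values receive the mean of the reference
values at their tied rank positions, making the transform idempotent.
All-zero samples are left untouched (logged). Hierarchical clustering of
sample profiles runs on log10(x + 1)-transformed, quantile-normalized
abundances with Euclidean distance and average linkage (the +1 pseudo-count
handles exact zeros); defaults chosen as the most common choices for
log-intensity MS data. The agreement score at a k = 6 cut is the fraction of
samples whose cluster's majority group matches their own group.

## Statistics

Histograms use half-open bins of width 0.05 on [-1, 1] (last bin closed);
the width is configurable and must divide the interval evenly. Gaussian fits
minimize unweighted least squares of the curve against bin counts — matching
curve-overlay fitting of histograms and keeping the pipeline deterministic —
with multi-start initialization at the largest local maxima and bounded
parameters (sigma >= bin_width / 4). Model order (1 vs 2 components) can be
selected automatically: the selection score is a Pearson chi-square BIC
(chi-square of counts against the fitted curve with Poisson variances, plus
`k ln n`), because a raw-RSS BIC is miscalibrated for count data. Two
components are accepted only when their BIC improves on one component by
>= 6 *and* the fitted means are separated by at least the larger component
sigma — two concentric components merely reshape one peak's tails and are
not evidence of bimodality. Non-convergence of every start raises an error;
there are no silent fallback parameters.

Box statistics use linear interpolation between order statistics for all
percentiles (quartile box, 10th/90th-percentile whiskers); outliers are
values beyond 1.5 IQR from the box edges. The paired/two-sample test
wrappers (Wilcoxon signed-rank, Mann–Whitney U, unpaired t,
two-sample KS) are two-sided with significance at p < 0.05 and no
multiple-testing correction (tests are reported per panel). All-zero paired
differences make the signed-rank test undefined; this is reported as such,
never silently converted.

## Synthetic data

### Traces

The generator emulates the population structure the analysis assumes. Class
fractions default to nonresponsive 0.08, K_only 0.567, specialist_A/B 0.068
each, generalist 0.217 — chosen so that ~38% of K⁺-sensitive neurons are
urine-responsive and ~61% of those are generalists, the composition reported
for large VSN populations. Transients are unit-peak difference-of-
exponentials `(1 − e^(−t/rise)) e^(−t/decay)` with rise 2 s and decay 8 s
(plausible somatic Ca²⁺-indicator kinetics; the shape is not otherwise
constrained by data). K⁺ amplitudes are truncated-normal (mean 1.0, sd 0.15,
floor 0.6 ΔF/F); stimulus amplitudes are expressed K⁺-normalized
(mean 0.5, sd 0.15, floor 0.2) so the intended normalized amplitude is exact
in the noise-free limit. Generalist preference draws an intended RI from
N(0, 0.2) clipped to ±0.6 and splits the overall amplitude as
`m(1 ± RI)`. Presentation-to-presentation variability is a multiplicative
factor N(1, 0.05) (clipped at 0), giving the narrow near-zero ReI
distributions seen in reliable recordings; additive Gaussian noise defaults
to sd 0.02 ΔF/F. Because all events start on sample ticks, the sampled
kernel peak is identical across events and K⁺ normalization recovers
intended amplitudes to < 1e-6 without noise.

What this does *not* model: photobleaching, drift, spontaneous transients,
motion artifacts, or correlated noise. Passing recovery tests therefore
shows the classification rules are implemented correctly and are robust at
realistic SNR — not that they are robust to every artifact of real
recordings.

### Compound tables

Six groups (male/female x C57BL/6, BALB/c, wild), 10 samples per group.
Each compound is planted with a category that fixes its presence pattern;
`uncategorized` compounds get a two-strains-of-one-sex pattern that matches
no category by construction. Default planted counts (48 generic, 8 per
sex-specific, 4 per strain-specific, 6 per combination-exclusive, 12
uncategorized; 124 compounds) keep all categories populated at roughly the
generic-heavy proportions seen in real urine profiling. Present samples draw
`1 + NB(mean x bias, dispersion)` with a per-compound base mean that is
log-normally spread (0.3 dex) around 100 and dispersion 1; the +1 offset
guarantees a truly present sample is detectable (so zero-dropout recovery is
exact by construction) and is negligible against the NB mean. Detection
dropout (default 0.1) zeroes present samples independently. Absent groups
are exact zeros by default; an optional low-rate contamination models
sporadic MS carryover. Per-group concentration bias factors multiply the NB
mean; the end-to-end pipeline's default design applies a 1.5x bias to
protein-class compounds in male groups, emulating the higher protein content
of male urine. The lipocalin-like design (3 generic + 4 exclusive markers
per group = 27 proteins) exercises sample clustering at the scale of the
urinary lipocalin repertoire.

## Problem sizes and determinism

Validation runs use 500 neurons at noise sd 0.02 for classification
recovery, 124-compound tables for category recovery, 100 seeded 10,000-draw
histograms for Gaussian-fit recovery, and a 27 x 60 marker table for
clustering — sizes at which the measured properties are stable across seeds
while the whole suite runs in well under a minute. Every generator takes an
explicit seed; one RNG stream is used per simulated object, and identical
seed + configuration yields bit-identical outputs, which the end-to-end
pipeline verifies by hashing complete output trees. The run manifest stores
the package version, seed and a SHA-256 hash of the canonical configuration.

## Known limitations

* Detection assumes ROI-resolved ΔF/F input; only a minimal
  `(F − F0)/F0` conversion is provided, no segmentation, motion or
  bleaching correction.
* The stimulus protocol assumes the inter-stimulus interval is measured
  offset-to-next-onset (configurable); repeats beyond two presentations are
  supported by the detector but ReI uses the first two.
* Six-way categorization is deliberately strict: partial patterns are
  uncategorized rather than fractionally assigned.
* Gaussian fitting targets histogram curves, not maximum-likelihood mixture
  estimation; for heavily overlapping mixtures a likelihood-based EM fit
  would discriminate better.
* sPLS-DA, Random-Forest feature ranking and power-law global error
  modelling of differential abundance are out of scope.
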