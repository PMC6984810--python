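# Methods

This note records the models implemented by `meawell`, their
assumptions, the defaults that matter, and the design choices made
where more than one reasonable construction existed.

## Spike events and the interchange format

A spike event is a threshold crossing with a fixed-length waveform
vector. The retained window is 1 ms before and 2 ms after the
crossing; with the crossing sample always kept, the sample count is
`floor(pre·rate/1000) + floor(post·rate/1000) + 1`, which gives 38
samples at 12.5 kHz with the crossing at 0-based index 12. Units are
fixed: seconds, µV, Hz; timestamps are recording-relative; electrodes
are 1-based within a well; wells are row-letter + column-number.
Tables round-trip through a tab-separated text format (timestamps to
1 µs, voltages to 0.001 µV) with an optional Parquet container
carrying the identical schema.

## QC and firing-rate metrics

High-noise exclusion drops events whose crossing threshold exceeds
the mean + 3 SD of all crossing thresholds, computed **per
recording** (the noise regime is recording-specific; pooling across
recordings is available behind a flag). The mean firing rate of an
array is MFR = n/s over all its electrodes; the log transform uses
(n + 1)/s so silent arrays remain finite. Active-array selection
keeps arrays within 2 SD (sample SD over all arrays, ddof = 1) below
the median log₁₀ MFR.

For synthetic raw traces, spikes are detected where |v| exceeds
5.5 × the background RMS over a centered 10 ms moving window. The
background estimator is the windowed *median* of squared samples,
rescaled by the median of χ²₁ (≈0.4549) so it is unbiased for
Gaussian noise: a plain windowed mean square is inflated by any spike
inside the window, which can raise the local threshold above the
spike's own trough. Detection is two-sided (templates are biphasic)
with a 1 ms refractory suppression of follow-on crossings.

## Design: assignment, follow-up correlation, power

**Minimum-F assignment.** Candidate assignments are drawn by
shuffling the pool and slicing into the requested group sizes
(uniform among ordered partitions; unbalanced designs supported).
Each candidate is scored by the one-way ANOVA F of baseline log₁₀ Hz
on group; ties keep the first candidate. With zero within-group
spread and zero between-group spread F is defined as 0. The search is
vectorized in batches of 2000 candidates.

**Correlated follow-up.** B = ρA + A⊥√(1 − ρ²), where A⊥ is the
residual of regressing an independent standard-normal draw on A
(hence exactly orthogonal to A in sample, zero mean), rescaled to
SD(A). The rescaling step is what makes the *sample* correlation
equal ρ exactly rather than in expectation. If the auxiliary draw is
numerically collinear with A (possible when caller seeds collide) it
is redrawn.

**ANCOVA power.** Each simulated experiment draws n control and n
treatment arrays' paired (t₀, t₁) log rates from a baseline
population and its correlated follow-up (ρ = 0.8 by default),
subtracts the effect from treated t₁ values, fits the group × time
model with interaction — which for this saturated design reduces to
the four cell means with a pooled error variance — and applies Tukey
HSD over the four cells, extracting the control-vs-treatment
comparison at t₁. Power is the fraction of iterations with adjusted
p < α. Because the Tukey correction spans all six cell comparisons,
the type-I rate of the *single* extracted comparison is conservative
(≈0.01 at α = 0.05), and the power surface inherits this; tests
check the null cell against α as an upper bound, not as a target.
Within a sample size the same index draws are reused across effect
sizes, so power monotonicity in effect is not masked by sampling
noise. The default grid (n = 3..16 × effects 0.1..2.0 step 0.1 ×
5000 iterations) enumerates 1.4 × 10⁶ simulated treatments and runs
in well under a minute because the studentized-range critical value
is computed once per sample size.

**Duration-correlation curve.** For accumulating intervals [0, k·step]
the per-well log₁₀((n + 1)/t) is computed in two recordings of the
same plate and correlated across wells; an OLS fit of ρ on
ln(minutes) summarizes how reliability grows with recording length.
The log scale is used because rates span decades and the rest of the
package operates on log₁₀ Hz.

## Spike sorting

Six shape features per waveform: peak, valley, amplitude
(peak − valley), peak–valley interval (ms), signed trapezoidal AUC
(µV·ms), and non-linear energy Ψ(xₙ) = xₙ² − xₙ₋₁xₙ₊₁ summarized by
its maximum over interior samples (the "sharpness" of the extrema; a
mean-Ψ summary is available via `nle_profile`).

Features are transformed x → ln(|x| + 10⁻⁶) — magnitudes, because
valley, AUC, and NLE can be non-positive; the natural log, because
that is the convention of the statistical environment the procedure
is modelled on, and the mean-shift bandwidth below is calibrated to
natural-log PC scores (log₁₀ would compress all separations by
ln 10 ≈ 2.3 and leave realistic template differences inside one
bandwidth). Columns are mean-centered (no unit-variance scaling,
matching the default of the standard PCA routine; scaling is exposed
as a flag) and scores on the first two principal components are kept.

Mean-shift clustering uses a Gaussian kernel exp(−‖d‖²/2h²) with
h = 1.5, tolerance 10⁻⁶, at most 300 iterations, and a mode-merge
radius of h/10. Each electrode's events are pooled across **all**
recordings before clustering, making cluster identity independent of
how spikes were split into sessions; within an electrode events are
processed in timestamp order so the result does not depend on
recording labels. Electrodes with fewer than 3 events form a single
flagged cluster. Each cluster's representative waveform is the member
nearest (Euclidean) its PC-space mode, ties to the lowest index.

Longitudinal patterns over chronological recordings: persistent (all
active), lost (active first, silent through the end), recovering
(active, an interior silent run, active again), emergent (silent
first, active later). Patterns such as (silent, active, silent) are
classified emergent — the first-recording state decides between the
lost/recovering family and emergent, and later silence does not
re-classify. "Active" means ≥ 1 attributed spike.

## Functional networks

STTC uses tiling fraction T_X (union of ±Δt windows, overlaps
merged, clipped to the recording, divided by duration) and proportion
P_X (fraction of X's spikes within ±Δt of any spike of the other
train), Δt = 100 ms. A term whose denominator 1 − P·T vanishes
contributes 0 (occurs when one train tiles the whole recording). The
implementation is O(n log n) via sorted searches and is checked in
tests against a brute-force discretization oracle.

The null distribution for a pair draws uniform-random spike times
with the observed counts (homogeneous-Poisson-like surrogates;
an inter-spike-interval shuffle preserving each train's interval
structure is available behind a flag). Edges are observed STTC values
outside the empirical 0.5% / 99.5% quantiles of 1000 permutations —
a two-sided 1% test; negative (out-of-phase) coupling also counts as
an edge, and the signed STTC is retained on the edge record. C̄ is
the average local clustering coefficient with nodes of degree < 2
contributing zero (the interpretation under which the isolates rule
has any effect), computed with networkx.

## Condition-level models

**Gamma GLM.** Cluster firing frequencies are positive and
right-skewed; they are modelled as Gamma with the inverse
(canonical) link on treatment × recording with interaction. Fitted
cell means are reported on the Hz scale with delta-method SEs; in
this saturated design they equal the cell sample means, an algebraic
identity used as the fitting oracle in tests. Zero-frequency clusters
are excluded (Gamma support is positive); an optional
(n + 1)/duration offset mode retains them — the choice is the
caller's and is surfaced prominently because zero inflation of
cluster rates is common (a quarter to nearly half of clusters can be
silent in a 30-min recording).

**Mixed models.** log₁₀ amplitude: treatment × recording fixed
effects, nested random intercepts experiment / electrode / cluster
(labels are made unique within their parent before fitting), REML.
If the innermost variance component is singular the model refits
without it and flags the drop. Input should first pass
`persistent_amplitude_filter`: clusters active in every modelled
recording with pre-treatment amplitude ≥ 30 µV — amplitude is a
frequency-independent phenotype, measurable only where the cluster
fired, and the floor leaves dynamic range for a decrease. Array
log₁₀ rate: random experiment intercept only; with a single
experiment the model falls back to OLS with a warning. Reported
per-treatment changes are post-minus-pre contrasts of the fixed
effects with Wald SEs; no small-sample df correction is applied.

**Contrasts.** Single-step adjustment references each |z| against
the distribution of max |Z| over all contrasts under the joint
normal with correlation from the fit covariance (seeded Monte-Carlo,
10⁵ draws; exact for a single contrast; Bonferroni available).
Adjusted p is floored at raw p.

## The simulator

What it emulates: log-normal array rates (latent log₁₀ Hz ~ Normal;
default mean −0.8, SD 0.55 — calibration choices giving a plausible
quiet-to-busy spread, as no distributional parameters for a reference
population are available); neuron rate shares within a well from
Gamma(shape 1) weights; 1–3 neurons per electrode; biphasic templates
(Gaussian trough at the crossing, later rebound) whose amplitudes come
from the linear source approximation
V_e = I/(4πσΔs) · ln|(√(h²+r²) − h)/(√(l²+r²) − l)|, l = h + Δs, with
currents 5–30 nA, radial distances 20–100 µm, Δs = 50 µm, σ =
0.3 S/m — yielding tens-of-µV amplitudes independent of firing rate;
Poisson trains with a configurable fraction of within-well pairs
sharing a jittered parent process (defaults: 15% of pairs, share 0.7,
jitter 5 ms); day-to-day latent-rate correlation ρ = 0.8 via the
correlated-follow-up construction on centred latents (preserving the
marginal mean); per-group treatment multipliers on rates and template
amplitudes in post phases; Gaussian waveform noise (SD 3 µV) and a
crossing threshold of 5.5 × noise SD, with an optional fraction of
high-noise electrodes for exercising the QC filter.

What it does not emulate: bursting and network oscillations,
electrode drift, overlapping-spike superposition on one electrode,
non-stationary rates within a recording, and electrode impedance
variation. Passing tests therefore demonstrate correctness of the
pipeline's statistics under the stated generative assumptions, not
robustness to every property of real recordings.

Randomness flows from a single seed through documented substreams
(per well, per recording), so partial regeneration is stable and runs
are reproducible end to end. Coupled pairs are drawn once per well
and shared by all recordings. Event-level generation (spike times +
waveforms) is the default; raw-trace synthesis exists only to
exercise threshold detection and is capped at 60 s.

## Problem sizes in the test suite

Tests run the full machinery at desk scale: 8–24-well plates,
10–30-min recordings, hundreds of permutations, and reduced power
grids (e.g. 3 × 4 cells × 500 iterations) — sizes chosen so the
whole suite completes in well under a minute per module while keeping
every statistical check at ≥ 3-SE resolution. The default simulator
configuration remains the full 96-well, 8-electrode, 30-min
geometry.

## Known limitations

* Mean-shift is O(n²) per electrode per iteration; electrodes with
  tens of thousands of pooled events would need subsampling or a
  binned kernel estimate.
* The bandwidth h = 1.5 is a fixed default, not adaptively chosen;
  its suitability depends on the feature log scale documented above.
* Cluster identity rests on waveform-shape stability; templates that
  drift between recordings will split into lost + emergent cluster
  pairs, and no drift correction is attempted.
* STTC edges are undirected and say nothing about physical synapses.
* The Gamma GLM's exclusion of silent clusters conditions the
  estimand on activity; the offset mode changes the estimand
  slightly instead. Neither is a hurdle/zero-inflated model.
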