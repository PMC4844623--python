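# Methods

This note documents the models, conventions and defaults behind `neuroloop`,
and what the synthetic data do and do not establish.

## Block design

A run is an obligatory opening REST block followed by `n_per_condition`
blocks each of UP, DOWN and REST, all 12 TR long (30.48 s at TR = 2.54 s).
Two constraints define validity: consecutive blocks always differ in
condition, and each of the six ordered transition types occurs exactly
`n/2` times — which forces `n` to be even and, by a degree-counting argument
(REST occurs `n+1` times but has only `n` out-transitions), forces every
valid run to end on REST. The sampler is a complete backtracking search over
condition sequences with per-transition budgets and uniformly shuffled
candidate order; it is deterministic per seed and cannot silently return an
unbalanced sequence.

Schedules are represented in regulation space (UP/DOWN/REST). The
counterbalanced direction mapping — whether the left-pointing cue means UP-
or DOWN-regulation — is modeled as a pure display-side sign: flipping it
negates every displayed value but leaves the underlying regulation labels,
the raw data, and therefore the UP−DOWN analysis contrast untouched. That is
exactly what makes the mapping an internal control: any feedback-independent
left/right bias cancels in the group UP−DOWN contrast. Mapping assignment
alternates deterministically with enrollment index, so even cohorts split
exactly in half.

End-of-block feedback (EoBF) runs append a 2-TR display window after every
block, including the initial REST. This reproduces the run lengths implied by
the protocol: 25 × 12 TR × 2.54 s = 762 s (12:42) for continuous feedback
and 25 × 14 TR × 2.54 s = 889 s (14:49) for EoBF. Whether the display TRs
were appended to or carved out of the 12-TR blocks is not decidable from the
protocol text alone; appending is the only reading consistent with both run
lengths, so it is adopted.

## Real-time feedback chain

Echo combination uses fixed, BOLD-sensitivity weights
`w_n = TE_n·exp(−TE_n/T2*)`, max-normalized, with T2* = 30 ms for the
amygdala; for echo times 8.6–57 ms these round to 0.59, 0.90, 1, 0.97, 0.88,
0.77. Combination is a weighted *average* (divide by Σw), which makes the
combined signal scale-free; a weighted sum would differ only by a constant
factor and cancel in the baseline scaling anyway.

The run baseline is the mean and sample SD (ddof = 1) of the combined ROI
signal over volumes 6–15, 1-based inclusive. Two caveats are deliberate:

* With 12-TR blocks, volumes 13–15 of that window fall inside the *second*
  block, not the opening rest block. The protocol nonetheless specifies
  volumes 6–15, and the hemodynamic delay means those early volumes still
  carry essentially rest-level signal, so the window is kept as specified.
* A constant window (SD = 0) makes scaling undefined and raises.

Display scaling maps the baseline mean to screen center and ±4 SD to the
edges, clipping beyond ±1 (the protocol only promises dots stay on screen).
Scaling is invariant to affine gain/offset changes of the raw signal. Frames
before volume 15 carry raw values but no display position (the scaling does
not exist yet); the dot history holds the 12 most recent displayed values;
all state resets at run boundaries, so no frame depends on a previous run.

## GLM and percent signal change

The canonical HRF is the double-gamma difference (response delay 6 s,
undershoot delay 16 s, unit dispersions, undershoot ratio 1/6, 32 s support),
sampled on a microtime grid of 16 bins per TR and normalized to unit peak.
Condition boxcars (UP, DOWN; REST implicit; FEEDBACK_DISPLAY over the 2-TR
windows in EoBF runs) are convolved on the fine grid and sampled at volume
onsets. Nuisance terms are six motion parameters when a motion table is
supplied, a high-pass set, and a constant.

The high-pass set is a centered linear trend plus the discrete-cosine basis
with frequencies below 1/128 Hz (`floor(2·N·TR/128)` components; 11 for a
300-volume run). The explicit linear column is a deliberate addition to the
usual cosine-only basis: a finite cosine set absorbs a linear scanner drift
only approximately (leaving percent-level leakage into condition betas),
whereas with the linear column any drift inside the nuisance span is removed
to machine precision. Fitting is ordinary least squares; rank-deficient
designs raise an error naming the collinear columns (pivoted QR).

Betas convert to percent signal change by
`PSC = β · max(single event ⊗ HRF) · 100 / β_constant`, where the "single
event" is a one-TR boxcar convolved with the HRF on the fine grid. With REST
implicit, the three contrasts satisfy `UP−DOWN = psc_up − psc_down`,
`UP−REST = psc_up`, `REST−DOWN = −psc_down` identically.

## Synthetic data and its ground truth

Echo `n` of a simulated run fluctuates around `s0·exp(−TE_n/T2*)`
(mono-exponential decay; default `s0` = 1000 a.u., resting T2* = 30 ms). The
BOLD effect multiplies the decayed baseline identically across echoes, i.e.
it is modeled as a TE-independent *fractional modulation* rather than a T2*
perturbation — a simplification that makes the ground truth exact and is the
quantity the PSC pipeline estimates. Per-echo white noise (default SD 4 a.u.,
about 0.5% of the combined ROI baseline after weighted averaging — a
realistic ROI-mean noise level) and a centered linear drift (default
0.02 a.u./volume) are added per echo.

Effect amplitudes are expressed in single-event-peak units: the generator's
ideal response divides the convolved boxcar by `max(single event ⊗ HRF)`, so
an amplitude `a` corresponds to exactly `100·a` percent signal change under
the PSC formula above. At zero noise the round trip is exact; this is the
package's own normalization convention and is what makes "effect 0.01 →
psc = 1.0%" an identity rather than an approximation.

Cohorts draw per-subject UP−DOWN effects from N(mean, SD) in percent, split
symmetrically between up- and down-regulation, so the true Cohen's d is
mean/SD; the defaults (0.43, 1.0) reproduce a moderate transfer-run effect
with realistic between-subject spread (subject-level PSC effects of a few
tenths of a percent). Volume mode places the effect inside a 2-voxel-radius
spherical "amygdala" on a 12×12×8 grid, a desk-scale stand-in for an
anatomically parcellated mask.

Physiology: respiration is an amplitude-modulated sinusoid (default period
4 s, i.e. 15 breaths/min) with optional condition-locked amplitude factors;
pulse is a raised-cosine-power spike train (default 1.1 Hz = 66 bpm); both
are sampled at 50 Hz (a recorder-typical rate) with small additive noise.
Motion tables are zeros by default — motion correction is out of scope — with
sinusoidal columns available for regression tests.

**What passing tests do not show.** The generator has no spikes, field-drift
nonlinearity, motion-by-susceptibility interaction, T2*-mediated BOLD,
cardiac/respiratory aliasing into the ROI signal, or spatial autocorrelation;
parameter-recovery results therefore validate the *estimator chain*, not its
robustness to real-scanner artifacts.

## Physiological time courses

Peaks are detected on a lightly smoothed (0.1 s moving average,
edge-preserving), SD-normalized trace via prominence threshold 0.3 (in SD
units) with a second pass enforcing a minimum spacing of 0.5 median periods;
normalization makes detection exactly amplitude-invariant. Heart rate is
60/inter-beat-interval placed at beat midpoints and interpolated to TR-bin
centers. RVT is per-breath depth (peak minus the deepest trough before the
next peak) divided by the peak-to-peak period, interpolated likewise; for a
pure sinusoid of amplitude A and period T it equals 2A/T. QC flags traces
with runs of identical samples longer than 2 s covering more than 10% of the
trace ("excessive signal plateaus") or |signal| below 1% of the range for
more than 5 s ("loss of signal"); all thresholds are module constants.
Condition summaries average the per-TR series within UP/DOWN/REST blocks
(display TRs belong to no condition) with a configurable onset lag that
defaults to 0 for physiological series, and report
`(mean_UP − mean_DOWN)/mean_REST` — normalization by the REST mean, one of
two plausible readings of "relative difference", chosen and fixed here.

## Group statistics

One-sample t-tests use the upper-tail alternative for the directional
hypotheses. Cohen's d is mean over sample SD (ddof = 1 throughout); its 95%
CI is a percentile bootstrap over 1000 resamples of subjects (percentile
rather than BCa — the simplest estimator consistent with "bootstrapping with
1000 draws"), seeded and deterministic. The 3×2×2 repeated-measures ANOVA is
computed as within-subject contrast tests: unit-norm polynomial contrasts
(linear, quadratic) over the three training days crossed with difference
contrasts over feedback type and direction; each effect is F(1, n−1) = t² of
the per-subject scores. Contrast tests need no sphericity correction, and a
two-level collapse reproduces the paired t-test exactly (F = t²). Missing
data are handled by listwise deletion per analysis with correspondingly
reduced degrees of freedom. Bonferroni adjustment is α/m; per-subject
learning slopes are OLS slopes against session index 1..3.

## Numerical and scale choices

* Microtime resolution 16 bins/TR; regressors sampled at volume onsets.
* Baseline SD and all group SDs are sample SDs (ddof = 1).
* Bootstrap resamples that happen to have zero variance are dropped from the
  percentile computation (vanishingly rare beyond tiny n).
* Monte-Carlo problem sizes: the acceptance checks use 200 cohorts (effect
  recovery/CI coverage) and 500 cohorts (type-I error) of 32 subjects with
  full per-subject simulation and GLM analysis (300-volume transfer runs,
  ROI mode); these sizes give binomial/sampling error comfortably inside the
  asserted bands while keeping the whole run around a minute.
* Seeds: every stochastic stage derives an independent stream from an
  explicit integer seed via `numpy` seed sequences; identical seeds give
  byte-identical outputs, including TSV artifacts.

## Known limitations

* The feedback engine processes volumes; scanner/export latency, motion
  correction and distortion correction are out of scope (motion parameters
  are inputs).
* Slice-time correction is not modeled; synthetic data are generated at
  volume resolution.
* RVT from a respiration belt is semi-quantitative; the per-breath
  definition here is one of several in use, and condition means of RVT
  should be compared within, not across, recording setups.
* The RM-ANOVA reports contrast tests only (no omnibus multi-df TD test);
  this matches the intended use — directional, single-df questions about
  training-day trends and factor effects.
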