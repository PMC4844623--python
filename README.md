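# neuroloop

Closed-loop fMRI neurofeedback at desk scale: block-design generation, the
real-time multi-echo feedback signal chain, offline GLM / percent-signal-change
analysis, heart-rate and respiration-volume-per-time physiology, and group
statistics — all testable end to end against a synthetic-data generator with
known ground truth.

## Who this is for

Real-time fMRI neurofeedback experiments train subjects to regulate the BOLD
signal of a target region (here: the bilateral amygdala, a dropout-prone
region scanned with six-echo EPI) by showing them a display derived from the
ROI signal every TR. The subject-level scans from such studies are rarely
public, which makes the analysis chain hard to validate. `neuroloop`
re-implements that chain as a tested library: every stage consumes standard
formats (NIfTI, TSV, plain-text waveforms), and a generator produces
multi-echo runs, motion tables and physiological traces whose ground truth
the pipeline must recover.

## The model in brief

* **Design.** A run is an opening REST block followed by `n` blocks each of
  UP, DOWN and REST regulation (12 TR = 30.48 s at TR = 2.54 s), ordered so
  conditions always change and each of the 6 ordered transition types occurs
  `n/2` times. Which screen direction cues UP is a counterbalanced,
  display-only sign (the internal control of the design).
* **Real-time chain.** Echoes are combined with fixed weights
  `w_n ∝ TE_n·exp(−TE_n/T2*)` (T2* = 30 ms → 0.59, 0.90, 1, 0.97, 0.88,
  0.77); the ROI mean of volumes 6–15 defines the run baseline; the display
  maps the baseline mean to screen center and ±4 SD to the edges, shows the
  last 12 samples, and resets per run.
* **Offline analysis.** OLS GLM with canonical double-gamma HRF regressors
  for UP and DOWN (REST implicit), an EoBF display regressor where needed,
  motion parameters, and a high-pass set below 1/128 Hz. Betas convert to
  percent signal change via
  `PSC = β · max(single event ⊗ HRF) · 100 / β_constant`.
* **Group level.** One-tailed one-sample t-tests on the UP−DOWN PSC
  contrast, Cohen's `d = mean/SD` with a 1000-draw percentile-bootstrap 95%
  CI, a 3×2×2 repeated-measures ANOVA via within-subject contrasts,
  correlations, and Bonferroni adjustment.

## Worked example

Simulate a 32-subject cohort whose true UP−DOWN PSC effects are drawn from
N(0.43 %, 1.0 %) — a true Cohen's d of 0.43 — and run each subject's
transfer run through the echo-combination → GLM → PSC → group-statistics
chain:

```python
from neuroloop.io import StudyConfig
from neuroloop.pipeline import run_pipeline

report = run_pipeline(StudyConfig(n_subjects=32, seed=7))
print(f"t({report.df}) = {report.t:.3f}, p = {report.p:.4f}")
print(f"d = {report.d:.3f} (95% CI {report.ci_low:.3f} to {report.ci_high:.3f})")
```

prints

```
t(31) = 2.327, p = 0.0133
d = 0.411 (95% CI 0.074 to 0.793)
```

i.e. this cohort's estimated effect size is 0.411 — close to the generative
truth of 0.43 and significant in the one-tailed group test — and the
bootstrap CI covers the truth. `report.per_subject` holds the per-subject
table (`true_up_down_psc` vs the recovered `up_down`, plus the
`psc_up`/`psc_down`/`up_rest`/`rest_down` contrasts).

The same stages are scriptable from the shell:

```bash
neuroloop design --n-per-condition 8 --mode cf --seed 4 --out sched.tsv
neuroloop simulate --schedule sched.tsv --seed 4 --outdir run/
neuroloop feedback --echoes run/echo_1.nii.gz,...,run/echo_6.nii.gz \
    --mask run/mask.nii.gz --schedule sched.tsv --out frames.tsv
neuroloop glm --echoes run/echo_1.nii.gz,...,run/echo_6.nii.gz \
    --mask run/mask.nii.gz --schedule sched.tsv --out psc.tsv
```

## Layout

| module | contents |
|---|---|
| `neuroloop.design` | block schedules, balance validation, direction mapping, run timing |
| `neuroloop.simulate` | multi-echo / physio / cohort generators with ground truth |
| `neuroloop.realtime` | echo weights, baseline scaling, streaming feedback engine |
| `neuroloop.glm` | HRF, design matrix, OLS, PSC conversion, ROI aggregation |
| `neuroloop.physio` | peak detection, HR, RVT, waveform QC, condition summaries |
| `neuroloop.stats` | t-tests, Cohen's d + bootstrap CI, RM-ANOVA, correlations |
| `neuroloop.io` / `.pipeline` / `.cli` | formats, config, end-to-end cohort pipeline, CLI |

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
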