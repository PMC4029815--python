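# affectloop

Closed-loop real-time fMRI neurofeedback, simulated and analyzed end to end.

`affectloop` re-creates a complete brain–computer-interface experiment on
the desk: participants alternate blocks of *tenderness/affection* and
*pride* autobiographical imagery while a two-class linear support vector
machine (SVM), trained on the previous run's multivoxel activation
patterns, classifies each incoming brain volume and feeds the result back
as a ring whose distortion encodes the decoder's confidence. A
neurofeedback (NFB) group sees contingent rings; a control (CTR) group
sees random ones. The package provides every stage as a tested library:

- **design** — the block protocol (4 tenderness + 4 pride blocks of 22
  volumes interleaved with 8 neutral blocks of 15 volumes; TR = 2 s;
  296 volumes per run) and per-volume usability labels (the first two
  volumes of every block are excluded for hemodynamic stabilization).
- **simulate** — a closed-loop synthetic subject: HRF-convolved
  condition patterns inside a feature mask, slow drift, AR(1) noise, and
  a latent learning rule that couples displayed feedback back to the
  tenderness pattern amplitude — only for NFB subjects.
- **preproc** — incremental volume-by-volume processing: optional
  translation realignment, 6 mm FWHM Gaussian smoothing, and subtraction
  of the mean of the most recent completed neutral block.
- **decoder** — soft-margin linear SVM; decision value `d = xᵀw + b`
  (positive = tenderness); per-session retraining on the previous run;
  discriminant maps from the top 2% of `|w|` and across-subject
  consistency maps.
- **feedback** — the decision value quantized to 20 ring-distortion
  levels: level 1 (most distorted) iff misclassified, levels 2–20
  monotone in the toward-target distance, saturating at `d_max`.
- **stats** — percent of usable tenderness volumes classified as
  tenderness per session, last-minus-first session changes, one-sample
  and pooled two-sample t tests, and exact binomial tests of per-subject
  accuracy against chance (the 60%-of-80-volumes criterion).
- **glm** — offline univariate analysis: double-gamma HRF block
  regressors, DCT high-pass (448 s) plus linear trend, OLS,
  tenderness − pride contrasts, second-level covariate regression, and
  max-statistic permutation small-volume FWE correction within an
  a-priori ROI.

## Worked example

Simulate the default cohort (12 NFB + 12 CTR subjects, 4 runs each, on a
24×24×12 desk-scale grid) and summarize the decoding outcomes:

```python
import affectloop as al

records = al.simulate_cohort(n_per_group=12, seed=1)
report = al.cohort_report([r.outcome for r in records])
print(report.summary_text())
```

prints

```
NFB (n=12): delta last-first = 19.3% +/- 8.3%, t(11) = 8.04, p = 0.000
  last session = 90.6% +/- 12.7% vs 50%, t(11) = 11.07, p = 0.000
CTR (n=12): delta last-first = -6.1% +/- 14.5%, t(11) = -1.47, p = 0.170
  last session = 66.6% +/- 13.2% vs 50%, t(11) = 4.35, p = 0.001
CTR - NFB delta: t(22) = -5.27, p = 0.000
reliable subjects (>60% last-session accuracy, exact binomial p < .05): 19/24
```

Reading the numbers: each subject's *delta last-first* is the change in
the percentage of usable tenderness-condition volumes classified as
tenderness between the first and last classification session. Only the
NFB group — whose rings are driven by the decoder — improves; the CTR
group, receiving random rings, does not, and the pooled two-sample t
confirms the group × session dissociation. The last line counts subjects
whose final-session accuracy exceeds 60% of 80 usable volumes with an
exact binomial p < .05 against chance.

The same pipeline runs from the shell:

```
affectloop simulate --out cohort/ --seed 1
affectloop analyze cohort/manifest.yaml
```

which additionally writes per-subject tables, discriminant-consistency
maps, and the permutation small-volume-correction report for the
covariate GLM (second-level regression of each subject's
tenderness − pride contrast on their session-3 minus session-1
classification change).

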