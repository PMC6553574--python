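# wavepac

Cycle-by-cycle waveform-shape and phase–amplitude-coupling (PAC) analysis
of resting sensorimotor EEG, with a synthetic-data generator for paired
two-state cohorts.

## The problem

Beta-band (13–30 Hz) activity over sensorimotor cortex is excessively
synchronized in Parkinson's disease, and two noninvasive markers track the
medication state: the *shape* of the beta oscillation and beta-phase /
broadband-gamma-amplitude coupling.  Oscillation shape is quantified cycle
by cycle on the **raw** signal:

- **peak/trough sharpness** — mean voltage drop from an extremum to the
  samples ±3 points (≈5.9 ms at 512 Hz) around it;
- **rise/decay steepness** — the largest one-sample slope between
  consecutive extrema.

Channel-level ratios are natural logs of mean-feature quotients:

```
PTR = ln( mean peak sharpness / mean trough sharpness )   peak-to-trough ratio
RTF = ln( mean rise steepness / mean decay steepness )    rise-to-fall ratio
sharpness ratio = |PTR|,   steepness ratio = |RTF|
```

The sign pair (PTR, RTF) places a channel in one of four shape quadrants;
Q4 (sharper peaks, steeper decays) is the canonical sensorimotor shape and
can be used as an inclusion criterion that concentrates the medication
effect.  PAC is the normalized (Kullback–Leibler) modulation index of the
gamma (50–150 Hz) amplitude binned over 18 beta-phase bins,
`MI = KL(P‖uniform)/ln 18 ∈ [0,1]`.

The package implements the full chain — preprocessing (demean, common
average or bipolar reference, zero-phase 0.5 Hz FIR high-pass, artifact
intervals), Welch-PSD oscillation screening, cycle features, PAC, and the
group layer (Wilcoxon signed-rank/rank-sum, Spearman, Benjamini–Hochberg
FDR, Cohen's *d*, Q4 retention, topographic statistic maps) — plus a
generator of non-sinusoidal oscillations with tunable rise–decay asymmetry,
extremum sharpness, 1/f background, phase-locked gamma, artifact bursts,
and paired off/on cohorts, so every stage is testable without patient data.

## Worked example

```python
import wavepac as wp

# a 15-subject paired cohort: rise fraction 0.42 off vs 0.48 on medication
spec = wp.CohortSpec(
    n_subjects=15,
    state_params={"off": wp.SynthParams(rdsym=0.42, gamma_amp=0.0),
                  "on":  wp.SynthParams(rdsym=0.48, gamma_amp=0.0)},
    seed=11)
cohort = wp.simulate_cohort(spec)
table = wp.analyze_cohort(cohort, include_pac=False)
for c in wp.compare_cohort(table):
    print(f"{c.metric:16s} W={c.statistic:5.1f}  p={c.p_raw:.2e} "
          f"p_fdr={c.p_fdr:.2e}  d={c.cohens_d:.2f}")
```

prints

```
sharpness_ratio  W=  0.0  p=6.10e-05 p_fdr=6.10e-05  d=3.65
steepness_ratio  W=  0.0  p=6.10e-05 p_fdr=6.10e-05  d=3.39
```

`W` is the smaller signed-rank sum (0 = every subject changed in the same
direction), `p_fdr` the Benjamini–Hochberg-adjusted p-value, and `d` the
pooled-SD Cohen's *d*: both shape ratios are larger in the asymmetric
"off" state, as expected from the injected rise-fraction difference.

The same pipeline runs from the shell:

```bash
wavepac simulate --config cohort.yaml --out cohort/
wavepac group cohort/ --out results.csv
wavepac all --config cohort.yaml --out results.csv   # both steps at once
```

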