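# statecoupler

Dynamic network-state inference and state-specific spectral coupling
analysis for multichannel electrophysiology (cortical channels plus a
local-field-potential channel), exercised end to end on a synthetic
generator with known ground truth.

The pipeline:

1. **synthgen** — paired ("off"/"on") synthetic cohorts: Markov
   state-switching, state-gated band-limited oscillators, state-dependent
   LFP–cortex coupling, and a per-state beta-amplitude "medication" effect.
2. **preprocess** — zero-phase band-pass/notch filtering, anti-aliased
   resampling, standardization, and GESD-based bad-segment detection on
   2-s window standard deviations.
3. **tdehmm** — time-delay embedding (±7 lags), PCA reduction, zero-mean
   full-covariance Gaussian HMM trained by EM (Baum–Welch), canonical-state
   inference with fixed observation models, fractional occupancy, state
   matching.
4. **specest** — state-weighted multitaper cross-spectra (2-s windows,
   seven Slepian tapers, 2 Hz smoothing), magnitude and imaginary
   coherence, time-averaged baselines, band power, percentile network
   thresholding.
5. **bursts** — beta-band (13–30 Hz) amplitude-envelope burst detection
   (75th percentile, ≥100 ms) and burst/state overlap quantification.
6. **permstats** — within-subject GLM contrasts, cluster-based sign-flip
   permutation tests over frequency, max-t permutation across states,
   Bonferroni thresholds, GESD outlier test, group contrasts with
   covariates.
7. **pipeline** — config-driven orchestration with deterministic seeding
   and a JSON + CSV report bundle.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the headline criteria (analytic values,
oracle equivalences, error-rate simulations, and a 20-replicate
end-to-end state-specificity check); the remaining files are per-module
unit and property tests.

## CLI

```bash
# write a synthetic paired cohort as TSV + JSON sidecars
statecoupler simulate --config config.yaml --seed 1 --out cohort/

# run the full analysis and write the report bundle
statecoupler run-all --config config.yaml --seed 1 --out results/run1/

# repeat across HMM state counts
statecoupler sweep --config config.yaml --seed 1 --k 8 --k 10 --k 12 --out sweep/
```

The config file is YAML with the fields of
`statecoupler.pipeline.PipelineConfig` (all optional; defaults give a
4-state scaled-down cohort).

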