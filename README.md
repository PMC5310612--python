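# eggdiscrim

Colour-threshold analysis of egg-rejection decisions: from eggshell
reflectance spectra, through a receptor-noise-limited (RNL) visual model
in just-noticeable-difference (JND) units, to psychometric threshold
estimation, AICc multimodel inference, and slope-resampling comparisons
of discrimination ability between host populations.

The package tests whether hosts reject foreign eggs by a *single
directional* colour threshold (position along the natural blue-green to
brown eggshell gradient) or by *multiple* thresholds on the absolute
perceived colour distance from their own eggs.

## What's inside

| module | role |
| --- | --- |
| `eggdiscrim.spectral_core` | read/validate/regrid reflectance spectra (CSV, `wl` + one column per sample; canonical grid 300–700 nm @ 1 nm) |
| `eggdiscrim.visual_model` | quantum catches, Weber-fraction noise, RNL chromatic/achromatic contrast, isometric JND chromaticity embedding, signed gradient-axis predictors |
| `eggdiscrim.psychometrics` | binomial GLMs (logit / probit / cloglog) via IRLS, Nagelkerke R², AICc, VIF, p=0.50 threshold location with case-resampling bootstrap (median + IQR) |
| `eggdiscrim.model_selection` | exhaustive subset enumeration, Akaike weights and evidence ratios, the 1/8 relative-likelihood candidate set, zero-method model averaging with adjusted SEs and relative importance |
| `eggdiscrim.resampling_stats` | 90 % subsample slope resampling, Monte-Carlo (Lilliefors-style) KS normality test, Wilcoxon rank-sum with rank-biserial correlation |
| `eggdiscrim.synthetic_data` | synthetic eggshell spectra along natural (blue-green→brown) and artificial (green→purple) gradients, a UVS-passerine visual-system preset, and simulated experiments under either decision rule |
| `eggdiscrim.cli_pipeline` | YAML-configured end-to-end pipeline and the `eggdiscrim` CLI |

## CLI

```sh
# simulate an experiment (spectra + trials + params)
eggdiscrim simulate --rule single --n 82 --seed 42 -o simdir/

# spectra -> JND colour predictors
eggdiscrim jnd --spectra simdir/spectra.csv -o predictors.csv

# full analysis from a config
eggdiscrim analyze --config cfg.yaml
```

A minimal `cfg.yaml`:

```yaml
trials: simdir/trials.csv      # one row per nest
# trials_b: other_host.csv     # optional second population for slope comparison
links: [logit, probit, cloglog]
bootstrap_B: 10000
resample_B: 10000
resample_fraction: 0.9
seed: 1
outdir: results
```

Outputs: `table1.csv` (scenario GLMs per link, with two-model Akaike
weights and the single-vs-multiple evidence ratio), `thresholds.json`
(p = 0.50 threshold point, bootstrap median and IQR per predictor),
`table2.csv` (zero-method averaged model with adjusted SEs and relative
importance), `slopes.csv` + `comparison.json` (KS normality and
Wilcoxon/rank-biserial slope comparison), and `run.log`. Reruns with the
same config and seed are byte-identical.

## Notes and caveats

- The default visual system (Gaussian sensitivities peaking at
  370/445/505/565 nm, flat illuminant, densities 1:2:2:4, Weber fraction
  0.1) is a conventional UVS-passerine stand-in, not measured data; every
  piece is overridable via CSV/YAML.
- The sign conventions are: browner = positive on the blue-green→brown
  axis, greener = positive on the green↔purple axis, more UV = positive
  on the third axis.
- Bootstrap thresholds use case resampling; replicates that fail to
  converge (separation) are dropped and counted, and estimates with more
  than 50 % failures are flagged unreliable.
- Wald confidence limits are reported throughout (not profile
  likelihood).
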