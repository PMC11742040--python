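# devocoevol

Quantitative comparison of developmental trajectories of **serial organs**
(upper/lower molars, fore/hindlimbs) **across species**, from staged-embryo
collections and bulk RNA-seq time courses.

Serial organs are built by largely shared developmental programs, so the
question of how much of their developmental evolution is *concerted*
(changes shared by both organs within a species) versus *organ-specific* is
central to understanding developmental system drift. This package provides
the statistical machinery to answer it on real or simulated data:

- **chronology** — calibrate embryo weight (mg) to developmental age (days
  post-coitum) with a monotone smoother on Box-Cox-transformed weight, and
  map ages onto a species-homologous relative timeline (0–10) anchored on
  two morphological milestones (e.g. mouse 14.6 dpc → 0, 18.0 dpc → 10).
- **staging** — infer the durations of ordered, irreversible morphological
  stages (e.g. the PEK → 1-SEK → … → crest cusp-patterning sequence) from
  cross-sectional (age, stage) embryo data. Each stage is an Erlang phase
  (m consecutive exponential substates with rate λ), the whole sequence a
  continuous-time Markov chain; stage durations are m/λ, and nested
  rate-class structures are compared by likelihood-ratio tests.
- **profiles** — per-gene negative-binomial B-spline models of expression
  over the relative timeline for 2 species × 2 organs. Four nested mean
  models (`simple` one shared curve, `species` one per species, `tooth` one
  per organ, `complex` one per series) are compared by four LRTs (t1–t4,
  BH-adjusted across genes) and a decision tree assigns each gene a class.
  The **coevolution index** is `species / (species + tooth + complex)` among
  informative genes — the fraction of temporal changes shared by both
  organs. Per-organ divergence, windowed curve distances (100 points, 10
  windows, per-point RMS) and a PCA-based variance decomposition round out
  the module.
- **deconvolution** — select tissue marker genes by NB Wald tests
  (BH-adjusted p < 0.05, |log2FC| > threshold), build a signature matrix of
  mean normalized marker expression, and estimate compartment proportions of
  bulk samples by simplex-constrained least squares
  (min ‖b − S·p‖₂ s.t. p ≥ 0, Σp = 1), with 1000× marker-list bootstrap
  intervals.
- **synthetic** — seeded generators for every input (staged cohorts, NB
  count time courses under each model class, two-tissue mixtures, weight/age
  pairs), each returning its ground truth, so the whole pipeline is testable
  without any download.

## Worked example

```python
import numpy as np
from devocoevol.synthetic import ProfilesSimConfig, simulate_profiles
from devocoevol.profiles import select_profile_model, coevolution_index

cfg = ProfilesSimConfig(n_per_class={"simple": 100, "species": 300,
                                     "tooth": 100, "complex": 100},
                        effect_size=2.0)
sim = simulate_profiles(cfg, seed=7)          # 600 genes x 32 samples + truth
sel = select_profile_model(sim.dataset)       # 4 nested NB-spline fits/gene
print(sel.class_counts.to_dict())
print(round(coevolution_index(sel), 4))
```

prints

```
{'species': 290, 'complex': 130, 'simple': 90, 'tooth': 88}
0.5709
```

With 300/100/100 truly species/tooth/complex genes the selection recovers
the class sizes closely, and the coevolution index (290 / (290+88+130) =
0.57) matches the generating fraction of 0.60 within binomial error — the
interpretation being that 57% of the genes with any informative temporal
signal changed *in the same way in both organs* between the species.

The staging module works the same way:

```python
from devocoevol.synthetic import rodent_preset, simulate_staging_cohort
from devocoevol.staging import fit_stage_model

cfg = rodent_preset(0).staging                # 9-stage cusp sequence
cohort = simulate_staging_cohort(cfg.plan, cfg.rates, 400, cfg.window, seed=42)
fit = fit_stage_model(cfg.plan, (cohort.t, cohort.stage), seed=0)
print(np.round(fit.relative_durations, 3))
print(np.round(cohort.true_relative_durations, 3))
```

```
[0.194 0.108 0.063 0.117 0.11  0.103 0.134 0.171]
[0.195 0.085 0.061 0.11  0.146 0.098 0.134 0.171]
```

(estimated above, truth below) — i.e. from 400 embryos, each contributing
only its age and its observed stage, the relative durations of the eight
non-terminal stages are recovered within ±0.04.

## Command line

```bash
devocoevol simulate profiles --seed 1 --genes-per-class 100 --out data/
devocoevol profiles select --counts data/counts.tsv --metadata data/samples.tsv --out sel.tsv
devocoevol staging fit --config cfg.yaml --obs obs.tsv --out durations.tsv
devocoevol deconv run --tissue-a epi.tsv --tissue-b mes.tsv --bulk bulk.tsv --out props.tsv
devocoevol run --config cfg.yaml --seed 1 --out results/
```

`devocoevol run` executes the full synthetic preset pipeline
(chronology → staging → profiles → deconvolution) and writes deterministic
TSV/JSON outputs plus a `manifest.json` with seeds and SHA-256 checksums;
reruns with the same config and seed are byte-identical.

## Documentation

The model assumptions, parameter defaults, numerical choices and known
limitations are described in `docs/methods.md`.
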