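# vococoord

Speech-motor coordination analysis of non-verbal vocalizations via
time-delay-embedded correlation structure.

## The problem

Non- or minimally-speaking individuals communicate largely through
non-verbal vocalizations (squeals, moans, babbles) that caregivers can
interpret but outsiders cannot. One way to characterize how these
vocalization categories differ — self-talk, delight, dysregulation,
frustration, request — is through the *coordination* of the speech
production subsystems that generate them: articulatory (formants,
MFCCs), laryngeal (F0, HNR, CPP) and respiratory (amplitude envelope).

`vococoord` implements that analysis as a reusable pipeline:

1. **Feature extraction** — acoustic trajectories from WAV segments:
   F0 at 1000 Hz with a voiced mask; MFCCs at 200 Hz; HNR, CPP,
   amplitude envelope and LPC formants F1–F3 at 100 Hz.
2. **Correlation structure** — for a combination of *n* channels, each
   channel is paired with *D* = 15 delayed copies of itself at 10 ms
   steps; the (15·n)×(15·n) matrix of Pearson correlations between all
   delayed copies is built with pairwise deletion over valid frames
   (laryngeal combinations restricted to voiced regions), and its
   eigenvalues λ₁ ≥ … ≥ λ₁₅ₙ are extracted. The signed eigenvalue sum
   always equals 15·n. A spectrum concentrated in few leading
   eigenvalues ⇒ tightly coupled, low-complexity movement; a flat
   spectrum ⇒ many independent degrees of freedom.
3. **Effect-size patterns** — per-recording spectra are averaged within
   each (subject, category) cell, then Cohen's d (pooled SD, category 2
   subtracted from category 1) is computed at every eigenvalue rank
   across subjects. A positive-to-negative pattern of d across ranks
   labels category 1 *lower* complexity; negative-to-positive labels it
   *higher*; the rule compares the mean d over the front and back
   thirds of ranks against a small-effect floor θ = 0.2.
4. **Synthetic validation** — a first-class generator produces (a)
   latent-factor feature bundles whose effective degrees of freedom are
   planted exactly, and (b) source-filter vocalization waveforms with
   controllable F0 modulation, jitter, formants and envelope/F0
   coupling, organized into labelled multi-subject cohorts, so every
   stage is testable end-to-end without external data.

## Worked example

```python
import numpy as np
from vococoord import (
    CategoryParams, ComboSpec, CoordinationModel, SyntheticCohortSpec,
    make_cohort,
)
from vococoord.model import compute_spectra

# a cohort with a planted contrast: "request" recordings are driven by a
# single latent factor (tightly coupled channels), "delight" by four
# independent ones
spec = SyntheticCohortSpec(
    n_subjects=7,
    categories={
        "request": CategoryParams(kind="bundle", n_latents=1,
                                  recordings_per_category=10),
        "delight": CategoryParams(kind="bundle", n_latents=4,
                                  recordings_per_category=10),
    },
    seed=7,
)
items, labels = make_cohort(spec)

combo = ComboSpec("bundle4", ("c1", "c2", "c3", "c4"), mask_policy="none")
model = CoordinationModel.from_recordings(items, combos=[combo])
results = model.fit()
print(results.summary())
```

prints

```
Vocalization coordination-complexity comparison
========================================================================
category pairs: 1   combinations: 1   theta: 0.2
------------------------------------------------------------------------
category_1 category_2   combo  n_ranks  front_mean  back_mean                  label
   delight    request bundle4       60      -0.448      1.562 higher_complexity_in_1
------------------------------------------------------------------------
label semantics: lower_complexity_in_1 = category 1 concentrates
variance in fewer leading eigenvalues (positive-to-negative d).
```

Read: with delight as category 1, the effect-size pattern runs
negative-to-positive across the 60 eigenvalue ranks (front-third mean
−0.45, back-third mean +1.56), so delight is classified as the
*higher*-complexity category — equivalently, the single-latent
"request" category is recovered as the lower-complexity one, which is
exactly the planted structure. `results.plot_pattern("delight",
"request", "bundle4")` draws the group pattern with per-subject traces.

The same model runs on real audio: `run_analysis(AnalysisConfig(),
waveforms, labels, out_dir=...)` filters segments shorter than 2.5 s,
extracts all channels, builds spectra for the default registry of 18
feature combinations, and writes `spectra.csv`, `patterns.csv`,
`summary.json` and `run.log`. The CLI mirrors the stages:

```sh
vococoord simulate --spec cohort.yaml --out data/ --seed 1
vococoord extract  --audio data/ --labels data/labels.csv --out feats/
vococoord corr     --features feats/ --labels data/labels.csv --out spectra.csv
vococoord compare  --spectra spectra.csv --out results/
vococoord run      --audio data/ --labels data/labels.csv --out results/
```

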