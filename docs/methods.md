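# Methods

This note documents the models, algorithms, defaults and design
decisions behind `vococoord`, in the spirit of a statistical package's
methods appendix. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## The coordination-complexity construct

The analysis treats a set of acoustic feature trajectories as the
observable output of a dynamical motor system and asks how many
effective degrees of freedom that system has. The instrument is
time-delay embedding: each of the *n* channels in a feature combination
is paired with *D* = 15 delayed copies of itself at τ = 10 ms steps,
and the (D·n)×(D·n) matrix of Pearson correlations between all delayed
copies is formed. Diagonal blocks sample each channel's autocorrelation
function; off-diagonal blocks sample cross-correlation functions. Since
every diagonal entry is a zero-lag self-correlation (= 1), the trace —
and hence the signed eigenvalue sum — is exactly D·n.

Ranked eigenvalues summarize coupling: if channels (and their lagged
copies) are strongly interdependent, variance concentrates in a few
leading eigenvalues (low complexity); independent channels spread
variance evenly (high complexity). Two categories are compared by
Cohen's d at each rank, computed across per-subject mean spectra;
subjects are first averaged over their recordings so heavily-recorded
subjects do not dominate. Averaging is rank-aligned and spectra are not
re-sorted afterwards.

**Direction convention.** A positive-to-negative d pattern across ranks
(category 1 larger at leading ranks, smaller at trailing ranks) is
classified as *lower complexity in category 1*: category 1 concentrates
more variance in fewer modes. The mirrored shape is higher complexity;
everything else is "unclear". This follows the convention used by the
method's published applications when reading group patterns off ranked
eigenvalue plots.

**Classification rule.** The qualitative "positive-to-negative" reading
is made operational as: with N ranks and k = ⌈N/3⌉, compute the mean d
over the first k and last k ranks; require front ≥ +θ and back ≤ −θ
(θ = 0.2, the conventional small-effect floor) for a label. The
front/back-third rule is this package's own formalization of what is
otherwise a visual judgement; θ and the thirds are configurable.
Missing ranks (undefined d from zero pooled variance) are excluded from
the means; classification requires at least 6 non-missing ranks.

**Cohen's d.** Unpaired, pooled-SD form:
d = (m₁ − m₂) / s_p, s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2),
with n−1 variance denominators, even though the same subjects may
appear in both categories — the comparison is defined group-vs-group,
not paired.

## Correlation-matrix construction

* All channels are resampled to a common 100 Hz analysis grid by
  mask-aware linear interpolation: a grid frame is valid only if every
  native frame that actually contributes to the interpolated value is
  valid. At 100 Hz, τ = 10 ms is exactly one frame, so delays are
  integral.
* Entries use **pairwise deletion**: the correlation at lag ℓ is the
  Pearson correlation over exactly the index pairs (t, t+ℓ) where both
  samples are valid. This preserves true lag relationships across
  unvoiced gaps, unlike concatenating voiced segments. Entries with
  fewer than 25 valid pairs raise an error; recordings with fewer than
  100 jointly valid grid frames (1 s) are excluded for that
  combination.
* When a combination contains a laryngeal channel (F0, HNR, CPP,
  creak), the joint voiced mask is applied to **all** channels of the
  combination, so laryngeal and non-laryngeal channels are correlated
  over the same voiced regions.
* Pairwise deletion can make the matrix slightly indefinite. Policy:
  eigenvalues in (−10⁻⁶, 0) are clipped to zero; more negative values
  are kept (so the signed sum still equals the trace) and logged with
  their magnitude. On realistic masked recordings magnitudes of order
  10⁻² occur; they are a property of pairwise deletion, not a bug.
* Entries where a paired slice has zero variance raise an undefined-
  correlation error and exclude the recording for that combination
  (zero-filling would silently distort spectra).
* `spectrum_flatness` is the normalized Shannon entropy of λ/Σλ
  (negative eigenvalues treated as zero mass): 1 for a uniform
  spectrum, 0 for a point mass. It is a diagnostic scalar used by the
  synthetic validation, not part of the published analysis.

## Feature extraction

All parameters below are keyword arguments with the stated defaults;
the source material for this analysis style does not specify frame
lengths, windows, pitch bounds or voicing parameters, so they are
declared configuration.

* **F0** (1000 Hz): normalized autocorrelation per 25 ms frame,
  unbiased lag normalization (dividing out the (N−ℓ)/N taper so a
  periodic signal scores ≈ 1), search band 60–1000 Hz, parabolic
  interpolation around the integer-lag peak. Candidate local maxima are
  scored with a 0.03-per-octave penalty on lag so the true period beats
  its subharmonics. A frame is voiced if the peak is ≥ 0.45 and frame
  RMS exceeds 1% of the global RMS. The track is smoothed by a 15 ms
  running median; an optional longer deviation-gated stage
  (`deglitch_s`) can mark residual octave-error runs unvoiced, but is
  off by default because any repair strong enough to bridge octave runs
  also suppresses genuine fast modulation.
* **HNR** (100 Hz, dB): 10·log₁₀(r/(1−r)) with r the normalized
  autocorrelation at the detected period, clipped to ±40 dB.
* **CPP** (100 Hz, dB): real cepstrum of a 40 ms Hann frame (two
  periods at the 60 Hz pitch floor), peak in the quefrency band
  [1/f_max, 1/f_min] minus the least-squares regression line over that
  band, evaluated at the peak quefrency.
* **Formants F1–F3** (100 Hz): audio resampled to 10 kHz, 0.97
  pre-emphasis, 25 ms Hann frames, LPC order 2 + f_s/1000 via
  Levinson recursion; polynomial roots with bandwidth < 400 Hz and
  frequency in (90 Hz, Nyquist) become candidates, sorted ascending.
  Frames with fewer than three candidates (e.g. silence) are invalid.
* **MFCC 1–5** (200 Hz): 26 triangular mel filters, log energies,
  orthonormal DCT-II, c0 excluded — the retained coefficients are
  exactly invariant to waveform gain.
* **Envelope** (100 Hz, linear): magnitude of the analytic signal,
  4th-order Butterworth low-pass at 20 Hz (≤ 30 Hz bounds enforced),
  sampled on the grid; always fully valid.
* `extract_all` attaches the F0-derived voiced mask to HNR and CPP
  (aligned 1000 Hz → 100 Hz frames), so the three laryngeal channels
  share one voicing decision. A failing extractor masks its channel and
  logs; it never aborts the recording.

Articulatory tract variables and the creak channel are not extracted
(each would require an externally trained model or an unpublished
algorithm); the channel registry accepts externally supplied `TV*` /
`CREAK` trajectories, which then flow through the correlation machinery
unchanged.

## Pipeline

Segments shorter than 2.5 s are eliminated before analysis; the 2.5 s
boundary itself is kept. The default registry holds 18 feature
combinations, each with 15 delays at 10 ms: six single-channel or
single-family combinations (F0, HNR, CPP, ENV, formants, MFCCs), and
twelve within/across-subsystem interactions, including all seven
combinations the analysis design names explicitly (F0; CPP; formants;
F0×HNR×CPP; ENV×formants; F0×HNR×CPP×ENV; formants×F0×ENV). The
remaining eleven fill out the within/across-subsystem design and are
fully overridable in configuration — the original enumeration beyond
the named seven is not public, so the registry is a stand-in satisfying
the count and the named subset.

The model layer (`CoordinationModel` / `CoordinationResults`) wraps the
effects stage the way statistical packages wrap estimators: built from
labelled spectra (or straight from recordings), `fit()` returns results
holding per-pair/per-combination patterns, labels, diagnostics, a
`summary()` table, per-subject patterns and plotting.

## Synthetic data: what it emulates, and what it does not

The generator plants known structure so that recovery is a meaningful
test:

* **Latent-factor bundles.** Each channel is a random full-column-rank
  mixture of K latent signals, unit-normalized, plus `noise_sd` times
  white Gaussian noise (so `noise_sd` is a noise-to-signal ratio;
  default 0.7). With zero noise the channel matrix has rank exactly K.
  Latents are sinusoid mixtures with seeded random frequencies spread
  over a broad band (0.3 Hz to ~96% of the trajectory Nyquist) and
  amplitudes decaying as exp(−f/120 Hz). The tilt matters: narrowband
  latents occupy ~2 embedding ranks regardless of K, and perfectly flat
  broadband latents produce cliff-shaped embedded spectra pinned by the
  delay window; the tilted regime yields a smooth geometric-like decay
  in which spectral flatness tracks K and category contrasts produce
  the canonical positive-to-negative patterns.
* **Vocalization waveforms.** Classic source-filter synthesis: an
  impulse train at the instantaneous F0 (cumulative-phase integration)
  excites a cascade of second-order resonators at the formant
  frequencies; the output's intrinsic envelope is flattened (divided by
  its own 25 Hz-smoothed analytic magnitude) before the target envelope
  contour is imposed, so the requested contour *is* the waveform's
  envelope — without flattening, source-filter interaction makes output
  energy vary non-monotonically with F0-harmonic/formant alignment.
  `coupling` ∈ [0, 1] blends the requested envelope with an affine
  function of the F0 contour; `coupling = 1` makes them exactly affine.
  Jitter is a low-pass-filtered multiplicative perturbation of the
  instantaneous F0; broadband noise enters at `noise_floor` relative to
  unit signal RMS; output is peak-normalized.
* **Cohorts.** `make_cohort` emits per-subject, per-category recordings
  with a labels table, bit-reproducible from (spec, seed) via
  per-recording seed sequences. Subjects carry seeded multipliers
  (modulation ±15%, noise/jitter ±40%, base F0 ±10%) applied
  consistently across their categories, so the between-subject variance
  entering group-level effect sizes is non-degenerate — the analogue of
  real inter-individual variability, and the reason per-subject
  averaging is worth testing.
* **Category presets** are illustrative regimes, not empirical claims
  (no quantitative generative model of real vocalization categories
  exists). The two waveform presets differ in F0-modulation complexity
  and were designed around a measured property of the pitch tracker:
  its response is faithful for modulation below roughly 8 Hz at
  realistic depths, while faster modulation surfaces as broadband
  tracking noise. "Frustration-like" places deep smooth modulation in
  0.3–5 Hz with minimal jitter (steep embedded spectrum);
  "dysregulation-like" combines modest 0.3–8 Hz modulation with strong
  pitch jitter whose extraction artifacts — themselves part of an
  erratic-pitch phenotype — flatten the spectrum. The bundle presets
  (request-like, self-talk-like, delight-like) differ only in latent
  count (1, 3, 4).

Passing tests on these cohorts demonstrate that the pipeline recovers
*planted statistical structure* of the kind the method assumes. They do
not demonstrate perceptual realism of the audio, robustness to
real-world recording noise, reverberation or overlapping speakers, or
anything about actual clinical populations.

## Problem sizes used in validation

Latent-bundle experiments use 4 channels, 5 s at 100 Hz, 20 seeds for
flatness curves; cohort classification uses 7 subjects × 20 recordings
per category × 50 seeded cohorts. The direction experiment uses 7
subjects × 12 three-second vocalizations per category over a handful of
cohorts. These sizes give stable statistics (classification margins are
several times the θ floor) while keeping the full validation battery in
the minutes range on one CPU.

## Known limitations

* The formant tracker is frame-wise LPC root-picking, not a Kalman
  smoother; it is accurate on synthetic resonator cascades but will be
  noisier on real child vocalizations.
* The pitch tracker's faithful modulation band (~0–8 Hz) means very
  fast genuine F0 modulation is partly rendered as broadband noise;
  complexity comparisons remain valid as relative statements but the
  embedded spectrum of an extracted F0 track is not that of the true
  contour.
* No significance testing or multiple-comparison correction is
  performed anywhere: the analysis reports effect sizes only, by
  design.
* Creak and articulatory tract variables are accepted as external
  channels but never computed.
* The 18-combination registry beyond the seven named combinations is a
  design-complete stand-in, not a reconstruction.
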