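"""Synthetic signals with known coupling structure.

Two generators make every downstream stage testable without external
audio:

* :func:`make_latent_bundle` emits a bundle of feature trajectories
  driven by a controllable number of shared latent signals — the number
  of latents is the planted "degrees of freedom" that the eigenvalue
  analysis is supposed to recover.
* :func:`make_vocalization` synthesizes a source-filter vocalization
  waveform (impulse-train glottal source, cascaded formant resonators,
  amplitude envelope) with controllable F0 modulation, jitter and
  envelope/F0 coupling, so the acoustic feature extractors can be
  validated against known ground truth.

:func:`make_cohort` organizes either kind of recording into a labelled
multi-subject, multi-category cohort. Category presets in
:data:`PRESETS` sketch qualitative regimes (e.g. high versus low
F0-modulation complexity); they are illustrative configuration, not
claims about real vocalizations.

Latent signals are mixtures of many sinusoids with seeded random
frequencies and phases spread over a broad modulation band, with
component amplitudes decaying exponentially in frequency (a spectral
tilt). Both properties are essential for the planted degrees of freedom
to be recoverable by time-delay embedding: a narrowband latent occupies
~2 ranks of the embedding no matter how many latents exist, while a
perfectly flat broadband latent produces a cliff-shaped embedded
spectrum whose rank count is pinned by the delay window rather than by
the latent count. The tilt yields a smooth, geometric-like decay of the
embedded eigenvalues, the regime in which spectral flatness tracks
``n_latents`` and category contrasts produce the canonical
positive-to-negative effect-size patterns.

Cohorts add between-subject heterogeneity (per-subject multipliers on
modulation rate, noise level and base F0) so that between-subject
variance — the denominator of the group-level Cohen's d — is realistic
rather than degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidSpecError
from .types import FeatureTrajectory, RecordingFeatures, Waveform

__all__ = [
    "ContourSpec",
    "CategoryParams",
    "SyntheticCohortSpec",
    "make_latent_bundle",
    "make_vocalization",
    "make_cohort",
    "PRESETS",
    "preset",
]


# --------------------------------------------------------------------------
# latent-factor feature bundles
# --------------------------------------------------------------------------

def _latent_signals(
    n_latents: int,
    t: np.ndarray,
    modulation_rate_hz: float,
    rng: np.random.Generator,
    n_components: int = 48,
    band_rel: tuple[float, float] = (0.03, 5.0),
    spectral_decay_hz: float | None = 120.0,
    nyquist_hz: float | None = None,
) -> np.ndarray:
    """Tilted sinusoid-mixture latents, unit variance, shape (K, T).

    Component frequencies are uniform over ``band_rel`` times the
    modulation rate (clipped just below Nyquist); amplitudes decay as
    ``exp(-f / spectral_decay_hz)``, giving a smooth geometric-like
    embedded eigenvalue profile.
    """
    lo = band_rel[0] * modulation_rate_hz
    hi = band_rel[1] * modulation_rate_hz
    if nyquist_hz is not None:
        hi = min(hi, 0.96 * nyquist_hz)
    lo = min(lo, 0.5 * hi)
    out = np.empty((n_latents, t.size))
    for k in range(n_latents):
        freqs = rng.uniform(lo, hi, size=n_components)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_components)
        amps = (
            np.exp(-freqs / spectral_decay_hz)
            if spectral_decay_hz
            else np.ones(n_components)
        )
        s = amps[:, None] * np.sin(
            2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
        )
        s = s.sum(axis=0)
        sd = s.std()
        out[k] = s / sd if sd > 0 else s
    return out


def make_latent_bundle(
    n_channels: int,
    n_latents: int,
    noise_sd: float,
    duration_s: float,
    rate_hz: float = 100.0,
    seed: int | np.random.Generator = 0,
    modulation_rate_hz: float = 10.0,
    n_components: int = 48,
    band_rel: tuple[float, float] = (0.03, 5.0),
    spectral_decay_hz: float | None = 120.0,
    channel_names: list[str] | None = None,
) -> dict[str, FeatureTrajectory]:
    """Generate ``n_channels`` trajectories driven by ``n_latents`` factors.

    Each channel is a fixed random mixture of the latent signals,
    normalized to unit variance, plus ``noise_sd`` times i.i.d. standard
    Gaussian noise (so ``noise_sd`` is a noise-to-signal ratio). With
    ``noise_sd=0`` the channel matrix has rank exactly ``n_latents``.

    All frames are valid (mask all-True).
    """
    if n_latents < 1 or n_latents > n_channels:
        raise InvalidSpecError(
            f"n_latents must be in [1, n_channels]; got {n_latents} latents "
            f"for {n_channels} channels"
        )
    if noise_sd < 0:
        raise InvalidSpecError(f"noise_sd must be >= 0, got {noise_sd}")
    n_frames = int(round(duration_s * rate_hz))
    if n_frames < 2:
        raise InvalidSpecError(
            f"duration_s * rate_hz must give >= 2 frames, got {n_frames}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if channel_names is None:
        channel_names = [f"c{i + 1}" for i in range(n_channels)]
    if len(channel_names) != n_channels:
        raise InvalidSpecError("channel_names length must equal n_channels")

    t = np.arange(n_frames) / rate_hz
    latents = _latent_signals(
        n_latents, t, modulation_rate_hz, rng,
        n_components=n_components, band_rel=band_rel,
        spectral_decay_hz=spectral_decay_hz, nyquist_hz=rate_hz / 2.0,
    )
    # full-column-rank mixing matrix; Gaussian is a.s. full rank but guard
    for _ in range(8):
        mixing = rng.normal(size=(n_channels, n_latents))
        if np.linalg.matrix_rank(mixing, tol=1e-8) == n_latents:
            break
    else:  # pragma: no cover - probability ~0
        raise InvalidSpecError("could not draw a full-rank mixing matrix")

    mixed = mixing @ latents
    sd = mixed.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    mixed = mixed / sd
    if noise_sd > 0:
        mixed = mixed + noise_sd * rng.standard_normal(mixed.shape)

    return {
        name: FeatureTrajectory(name=name, values=mixed[i], rate_hz=rate_hz)
        for i, name in enumerate(channel_names)
    }


# --------------------------------------------------------------------------
# source-filter vocalization synthesis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContourSpec:
    """Spec for a slowly varying control contour (F0 or envelope).

    The contour is ``base * (1 + mod_depth * m(t))`` where ``m`` is a
    unit-variance sinusoid mixture whose component frequencies are drawn
    uniformly from ``band_rel`` times ``mod_rate_hz``; component
    amplitudes optionally decay as ``exp(-f / f_decay_hz)`` (spectral
    tilt), which controls the steepness of the contour's delay-embedded
    eigenvalue profile.
    """

    base: float
    mod_rate_hz: float = 3.0
    mod_depth: float = 0.1
    band_rel: tuple[float, float] = (0.5, 1.5)
    n_components: int = 6
    f_decay_hz: float | None = None

    def realize(self, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.mod_depth == 0 or self.n_components == 0:
            return np.full(t.size, float(self.base))
        freqs = rng.uniform(
            self.band_rel[0] * self.mod_rate_hz,
            self.band_rel[1] * self.mod_rate_hz,
            size=self.n_components,
        )
        phases = rng.uniform(0, 2 * np.pi, size=self.n_components)
        amps = (
            np.exp(-freqs / self.f_decay_hz)
            if self.f_decay_hz
            else np.ones(self.n_components)
        )
        m = (
            amps[:, None]
            * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
        ).sum(axis=0)
        sd = m.std()
        if sd > 0:
            m = m / sd
        contour = self.base * (1.0 + self.mod_depth * m)
        return np.clip(contour, 0.05 * self.base, None)


def _as_contour(
    spec: "float | np.ndarray | ContourSpec",
    t: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    if isinstance(spec, ContourSpec):
        return spec.realize(t, rng)
    arr = np.atleast_1d(np.asarray(spec, dtype=np.float64))
    if arr.size == 1:
        return np.full(t.size, float(arr[0]))
    # array given at arbitrary uniform rate: stretch over the duration
    src_t = np.linspace(t[0], t[-1], arr.size)
    return np.interp(t, src_t, arr)


def make_vocalization(
    duration_s: float,
    f0_contour: "float | np.ndarray | ContourSpec" = 220.0,
    envelope_contour: "float | np.ndarray | ContourSpec" = 1.0,
    formant_freqs: tuple[float, ...] = (500.0, 1500.0, 2500.0),
    coupling: float = 0.0,
    jitter_sd: float = 0.0,
    noise_floor: float = 0.0,
    rate_hz: float = 16000.0,
    seed: int | np.random.Generator = 0,
    formant_bandwidths: tuple[float, ...] | None = None,
    recording_id: str = "",
    subject_id: str = "",
    category: str = "",
) -> Waveform:
    """Synthesize a vocalization via the classic source-filter model.

    An impulse train at the instantaneous F0 (with optional relative
    jitter ``jitter_sd`` applied as low-pass-filtered multiplicative
    noise) excites a cascade of second-order resonators at
    ``formant_freqs``; the output is multiplied by the amplitude
    envelope and peak-normalized. ``coupling`` in [0, 1] blends the
    requested envelope with an affine function of the F0 contour;
    ``coupling=1`` makes the envelope exactly affine in F0.
    """
    if duration_s <= 0:
        raise InvalidSpecError(f"duration_s must be positive, got {duration_s}")
    nyq = rate_hz / 2.0
    freqs = tuple(float(f) for f in formant_freqs)
    if any(b <= a for a, b in zip(freqs, freqs[1:])):
        raise InvalidSpecError(f"formant_freqs must be strictly increasing: {freqs}")
    if any(f >= nyq for f in freqs):
        raise InvalidSpecError(
            f"formant at or above Nyquist ({nyq} Hz): {freqs}"
        )
    if not 0.0 <= coupling <= 1.0:
        raise InvalidSpecError(f"coupling must be in [0, 1], got {coupling}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz

    f0 = _as_contour(f0_contour, t, rng)
    if jitter_sd > 0:
        # smooth multiplicative perturbation of the instantaneous F0
        noise = rng.standard_normal(n)
        sos = sps.butter(2, min(50.0, 0.4 * nyq), fs=rate_hz, output="sos")
        noise = sps.sosfiltfilt(sos, noise)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
        f0 = f0 * (1.0 + jitter_sd * noise)
    f0 = np.clip(f0, 1.0, 0.45 * rate_hz)

    # impulse train: one impulse per glottal cycle
    phase = np.cumsum(f0) / rate_hz
    source = np.zeros(n)
    source[np.diff(np.floor(phase), prepend=np.floor(phase[0])) > 0] = 1.0

    if formant_bandwidths is None:
        formant_bandwidths = tuple(80.0 + 40.0 * i for i in range(len(freqs)))
    out = source
    for f, bw in zip(freqs, formant_bandwidths):
        r = np.exp(-np.pi * bw / rate_hz)
        theta = 2 * np.pi * f / rate_hz
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        b = [1.0 - r]  # keep gain bounded
        out = sps.lfilter(b, a, out)
    rms = float(np.sqrt(np.mean(out**2)))
    if rms > 0:
        out = out / rms  # noise_floor is relative to unit signal RMS

    # flatten the intrinsic envelope of the filtered source (source-filter
    # interaction makes raw output energy vary with F0-harmonic/formant
    # alignment) so the requested contour IS the waveform's envelope
    n_fft = int(2 ** np.ceil(np.log2(max(n, 2))))
    mag = np.abs(sps.hilbert(out, N=n_fft)[:n])
    sos_env = sps.butter(2, min(25.0, 0.4 * nyq), fs=rate_hz, output="sos")
    mag = sps.sosfiltfilt(sos_env, mag)
    floor = 0.1 * np.median(mag) if np.median(mag) > 0 else 1e-12
    out = out / np.maximum(mag, floor)

    env = _as_contour(envelope_contour, t, rng)
    if coupling > 0:
        lo, ptp = f0.min(), np.ptp(f0)
        f0_env = 0.3 + 0.7 * (f0 - lo) / (ptp if ptp > 0 else 1.0)
        f0_env = f0_env * (env.mean() / f0_env.mean() if f0_env.mean() > 0 else 1.0)
        env = (1.0 - coupling) * env + coupling * f0_env
    out = out * env

    if noise_floor > 0:
        out = out + noise_floor * rng.standard_normal(n)

    peak = np.abs(out).max()
    if peak > 0:
        out = 0.95 * out / peak
    return Waveform(
        samples=out, rate_hz=rate_hz,
        recording_id=recording_id, subject_id=subject_id, category=category,
    )


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryParams:
    """Generative parameters for one vocalization category.

    ``kind="bundle"`` emits latent-factor feature bundles (fast; used
    for parameter-recovery experiments on the correlation machinery).
    ``kind="waveform"`` synthesizes audio via :func:`make_vocalization`
    (used to exercise the full extraction pipeline).
    """

    kind: str = "bundle"
    recordings_per_category: int = 20
    duration_s: float = 5.0
    # bundle parameters
    n_channels: int = 4
    n_latents: int = 2
    noise_sd: float = 0.7
    modulation_rate_hz: float = 10.0
    spectral_decay_hz: float | None = 120.0
    channel_names: tuple[str, ...] | None = None
    # waveform parameters
    f0: ContourSpec = field(default_factory=lambda: ContourSpec(base=250.0))
    envelope: ContourSpec = field(default_factory=lambda: ContourSpec(base=1.0, mod_rate_hz=2.0, mod_depth=0.2))
    formant_freqs: tuple[float, ...] = (600.0, 1400.0, 2600.0)
    coupling: float = 0.0
    jitter_sd: float = 0.0
    noise_floor: float = 0.005
    audio_rate_hz: float = 16000.0

    def __post_init__(self) -> None:
        if self.kind not in ("bundle", "waveform"):
            raise InvalidSpecError(f"unknown category kind {self.kind!r}")
        if self.recordings_per_category < 1:
            raise InvalidSpecError("recordings_per_category must be >= 1")
        if self.duration_s <= 0:
            raise InvalidSpecError("duration_s must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort-level generative spec: who, what, and how much.

    ``categories`` maps category label to its :class:`CategoryParams`.
    Identical spec + seed reproduce the cohort bit-for-bit. The default
    recording duration (5 s) exceeds the 2.5 s analysis threshold so
    generated cohorts survive the duration filter.

    Subjects are heterogeneous: each subject carries seeded multipliers
    (uniform in 1 +- the jitter below), applied consistently across
    that subject's categories, so the between-subject variance that
    enters group-level effect sizes is non-degenerate. The noise
    multiplier scales bundle noise and waveform pitch jitter; the
    modulation and F0 multipliers scale the waveform F0 contour's
    modulation rate and base.
    """

    n_subjects: int = 7
    categories: dict[str, CategoryParams] = field(
        default_factory=lambda: {"A": CategoryParams()}
    )
    rate_hz: float = 100.0
    seed: int = 0
    subject_modulation_jitter: float = 0.15
    subject_noise_jitter: float = 0.4
    subject_f0_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidSpecError("n_subjects must be >= 1")
        if not self.categories:
            raise InvalidSpecError("at least one category is required")


def _recording_rng(seed: int, subj: int, cat: int, rec: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, subj, cat, rec]))


def make_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list, pd.DataFrame]:
    """Generate a labelled multi-subject cohort.

    Returns ``(items, labels)`` where ``items`` holds one
    :class:`RecordingFeatures` (bundle categories) or :class:`Waveform`
    (waveform categories) per recording, and ``labels`` is a DataFrame
    with columns ``recording_id, subject_id, category, duration_s``.
    """
    items: list = []
    rows: list[dict] = []
    for s in range(spec.n_subjects):
        subject_id = f"S{s + 1:02d}"
        srng = np.random.default_rng(np.random.SeedSequence([spec.seed, s, 0x5AB]))
        mod_mult = srng.uniform(
            1 - spec.subject_modulation_jitter, 1 + spec.subject_modulation_jitter
        )
        noise_mult = srng.uniform(
            1 - spec.subject_noise_jitter, 1 + spec.subject_noise_jitter
        )
        f0_mult = srng.uniform(1 - spec.subject_f0_jitter, 1 + spec.subject_f0_jitter)
        for c, (cat_name, p) in enumerate(spec.categories.items()):
            for r in range(p.recordings_per_category):
                rng = _recording_rng(spec.seed, s, c, r)
                rec_id = f"{subject_id}_{cat_name}_{r:03d}"
                if p.kind == "bundle":
                    channels = make_latent_bundle(
                        n_channels=p.n_channels,
                        n_latents=p.n_latents,
                        noise_sd=p.noise_sd * noise_mult,
                        duration_s=p.duration_s,
                        rate_hz=spec.rate_hz,
                        seed=rng,
                        modulation_rate_hz=p.modulation_rate_hz,
                        spectral_decay_hz=p.spectral_decay_hz,
                        channel_names=(
                            list(p.channel_names) if p.channel_names else None
                        ),
                    )
                    items.append(
                        RecordingFeatures(
                            recording_id=rec_id,
                            subject_id=subject_id,
                            category=cat_name,
                            duration_s=p.duration_s,
                            channels=channels,
                        )
                    )
                else:
                    f0_spec = replace(
                        p.f0,
                        base=p.f0.base * f0_mult,
                        mod_rate_hz=p.f0.mod_rate_hz * mod_mult,
                    )
                    items.append(
                        make_vocalization(
                            duration_s=p.duration_s,
                            f0_contour=f0_spec,
                            envelope_contour=p.envelope,
                            formant_freqs=p.formant_freqs,
                            coupling=p.coupling,
                            jitter_sd=p.jitter_sd * noise_mult,
                            noise_floor=p.noise_floor,
                            rate_hz=p.audio_rate_hz,
                            seed=rng,
                            recording_id=rec_id,
                            subject_id=subject_id,
                            category=cat_name,
                        )
                    )
                rows.append(
                    {
                        "recording_id": rec_id,
                        "subject_id": subject_id,
                        "category": cat_name,
                        "duration_s": p.duration_s,
                    }
                )
    return items, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# category presets (illustrative regimes, not empirical claims)
# --------------------------------------------------------------------------

#: Qualitative category regimes. The waveform presets differ mainly in
#: F0-modulation complexity (dysregulation-like: broadband, deeply
#: modulated, jittery pitch; frustration-like: narrowband, shallow,
#: steady pitch); the bundle presets differ in cross-channel latent
#: dimension (request-like: one shared latent; delight-like: independent
#: channels).
PRESETS: dict[str, CategoryParams] = {
    # Both waveform presets use broadband, spectrally tilted F0
    # modulation; they differ in tilt steepness (how fast modulation
    # power decays with frequency) and depth. The frustration-like
    # regime concentrates F0 movement at low modulation frequencies
    # (smooth, steady pitch -> steep embedded spectrum, low complexity);
    # the dysregulation-like regime spreads it broadly (rough, erratic
    # pitch -> flat embedded spectrum, high complexity).
    "frustration-like": CategoryParams(
        kind="waveform",
        duration_s=3.0,
        f0=ContourSpec(base=300.0, mod_rate_hz=10.0, mod_depth=0.25,
                       band_rel=(0.03, 0.5), n_components=20, f_decay_hz=None),
        envelope=ContourSpec(base=1.0, mod_rate_hz=2.0, mod_depth=0.12),
        jitter_sd=0.003,
        coupling=0.3,
        noise_floor=0.003,
    ),
    "dysregulation-like": CategoryParams(
        kind="waveform",
        duration_s=3.0,
        f0=ContourSpec(base=320.0, mod_rate_hz=10.0, mod_depth=0.15,
                       band_rel=(0.03, 0.8), n_components=20, f_decay_hz=None),
        envelope=ContourSpec(base=1.0, mod_rate_hz=2.0, mod_depth=0.25),
        jitter_sd=0.12,
        coupling=0.3,
        noise_floor=0.03,
    ),
    "request-like": CategoryParams(kind="bundle", n_channels=4, n_latents=1),
    "self-talk-like": CategoryParams(kind="bundle", n_channels=4, n_latents=3),
    "delight-like": CategoryParams(kind="bundle", n_channels=4, n_latents=4),
}


def preset(name: str, **overrides) -> CategoryParams:
    """Fetch a category preset, optionally overriding fields."""
    if name not in PRESETS:
        raise InvalidSpecError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    p = PRESETS[name]
    return replace(p, **overrides) if overrides else p
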