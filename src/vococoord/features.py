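"""Low-level acoustic feature extraction.

Extracts the nine-channel feature set that represents the three speech
production subsystems: F0, HNR and CPP for the laryngeal subsystem
(voiced regions only), the amplitude envelope for the respiratory
subsystem, and formants F1-F3 plus MFCCs for the articulatory
subsystem. Registry output rates: F0 at 1000 Hz, MFCCs at 200 Hz,
everything else at 100 Hz.

Algorithm choices (all parameters configurable):

* F0 / voicing: per-frame normalized autocorrelation peak within the
  pitch band, with unbiased lag normalization and parabolic peak
  interpolation; frames whose peak falls below the voicing threshold
  (default 0.45), or whose energy is negligible, are masked invalid.
* HNR: ``10*log10(r / (1 - r))`` with ``r`` the normalized
  autocorrelation at the detected pitch period, clipped to +-40 dB.
* CPP: real-cepstrum peak in the pitch quefrency band minus the value
  of a least-squares regression line fit over that band, in dB.
* Formants: frame-wise LPC (autocorrelation method, audio resampled to
  10 kHz), polynomial roots with bandwidth < 400 Hz mapped to F1-F3.
* MFCC: mel filterbank log-energies + orthonormal DCT-II, coefficients
  1..k (c0 excluded, so the coefficients are gain-invariant).
* Envelope: magnitude of the analytic signal, low-pass filtered at
  20 Hz, sampled on the 100 Hz grid.

Articulatory tract variables and the creak channel are not extracted
(both need externally trained models/algorithms); the correlation
machinery accepts externally supplied ``TV*``/``CREAK`` channels.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import fft as sfft
from scipy import linalg as sla
from scipy import signal as sps

from .errors import InvalidInputError
from .types import FeatureTrajectory, RecordingFeatures, Waveform, registry_rate

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_f0",
    "estimate_hnr",
    "estimate_cpp",
    "estimate_formants",
    "estimate_mfcc",
    "estimate_envelope",
    "extract_all",
    "cpp_from_cepstrum",
]

#: Default voicing threshold on the normalized autocorrelation peak.
VOICING_THRESHOLD = 0.45
#: Frames with RMS below this fraction of the global RMS are silent.
SILENCE_REL_RMS = 0.01

_FRAME_BLOCK = 2048  # frames per FFT batch, bounds memory
_OCTAVE_COST = 0.03  # per-octave penalty in the pitch candidate score


def _check_waveform(w: Waveform) -> None:
    if w.samples.size == 0:
        raise InvalidInputError("empty audio")


def _frame_indices(n_samples: int, fs: float, out_rate: float, frame_len: int):
    """Centered frame index matrix and per-frame in-bounds weights."""
    n_frames = int(round(n_samples / fs * out_rate))
    centers = np.round(np.arange(n_frames) / out_rate * fs).astype(np.int64)
    offs = np.arange(frame_len) - frame_len // 2
    return n_frames, centers, offs


def _gather_frames(x: np.ndarray, centers: np.ndarray, offs: np.ndarray):
    idx = centers[:, None] + offs[None, :]
    inb = (idx >= 0) & (idx < x.size)
    frames = np.where(inb, x[np.clip(idx, 0, x.size - 1)], 0.0)
    return frames


def _autocorr_track(
    w: Waveform,
    out_rate: float,
    fmin: float,
    fmax: float,
    frame_s: float,
    voicing_threshold: float,
):
    """Shared autocorrelation pitch machinery.

    Returns ``(f0, r_peak, voiced)`` arrays at ``out_rate``. ``r_peak``
    is the unbiased-normalized autocorrelation at the (parabolically
    interpolated) pitch period.
    """
    _check_waveform(w)
    fs = w.rate_hz
    if not (0 < fmin < fmax < fs / 2):
        raise InvalidInputError(
            f"need 0 < fmin < fmax < Nyquist; got fmin={fmin}, fmax={fmax}, fs={fs}"
        )
    frame_len = int(round(frame_s * fs))
    frame_len = max(frame_len, 16)
    n_frames, centers, offs = _frame_indices(w.samples.size, fs, out_rate, frame_len)

    lag_min = max(2, int(np.ceil(fs / fmax)))
    lag_max = min(int(np.floor(fs / fmin)), frame_len - 2)
    if lag_max <= lag_min:
        raise InvalidInputError(
            f"frame of {frame_s * 1e3:.0f} ms too short for fmin={fmin} Hz at {fs} Hz"
        )
    nfft = sfft.next_fast_len(2 * frame_len)
    glob_rms = float(np.sqrt(np.mean(w.samples**2)))
    # unbiased normalization: divide out the (N - lag)/N taper of the
    # raw autocorrelation estimate so a periodic signal scores ~1
    lags = np.arange(frame_len)
    unbias = frame_len / np.maximum(frame_len - lags, 1)

    f0 = np.zeros(n_frames)
    r_peak = np.zeros(n_frames)
    voiced = np.zeros(n_frames, dtype=bool)

    for start in range(0, n_frames, _FRAME_BLOCK):
        sl = slice(start, min(start + _FRAME_BLOCK, n_frames))
        frames = _gather_frames(w.samples, centers[sl], offs)
        frames = frames - frames.mean(axis=1, keepdims=True)
        rms = np.sqrt(np.mean(frames**2, axis=1))
        spec = sfft.rfft(frames, n=nfft, axis=1)
        r = sfft.irfft(np.abs(spec) ** 2, n=nfft, axis=1)[:, :frame_len]
        r0 = r[:, 0].copy()
        r0[r0 <= 0] = np.inf
        rn = (r / r0[:, None]) * unbias[None, :]

        band = rn[:, lag_min : lag_max + 1]
        # a periodic signal peaks at every multiple of its period, and
        # the unbiased normalization slightly favours long lags; score
        # candidate local maxima with a small octave cost so the true
        # (shortest) period wins over its subharmonics
        interior = np.zeros_like(band, dtype=bool)
        interior[:, 1:-1] = (band[:, 1:-1] >= band[:, :-2]) & (
            band[:, 1:-1] >= band[:, 2:]
        )
        lag_axis = np.arange(lag_min, lag_max + 1)
        cost = _OCTAVE_COST * np.log2(lag_axis / lag_min)
        score = np.where(interior, band - cost[None, :], -np.inf)
        no_peak = ~interior.any(axis=1)
        k = np.argmax(score, axis=1)
        k[no_peak] = np.argmax(band[no_peak], axis=1)
        k = k + lag_min
        rows = np.arange(rn.shape[0])
        # parabolic interpolation around the integer peak
        km = np.clip(k - 1, 0, frame_len - 1)
        kp = np.clip(k + 1, 0, frame_len - 1)
        y0, y1, y2 = rn[rows, km], rn[rows, k], rn[rows, kp]
        denom = y0 - 2 * y1 + y2
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        delta = np.clip(delta, -0.5, 0.5)
        lag_star = k + delta
        peak = y1 - 0.25 * (y0 - y2) * delta

        f0[sl] = fs / np.maximum(lag_star, 1e-9)
        r_peak[sl] = peak
        voiced[sl] = (
            (peak >= voicing_threshold)
            & (peak <= 1.5)
            & (rms > SILENCE_REL_RMS * max(glob_rms, 1e-12))
        )
    return f0, r_peak, voiced


def _running_median(values: np.ndarray, mask: np.ndarray, k: int) -> np.ndarray:
    """Mask-aware running median of a trajectory."""
    if k % 2 == 0:
        k += 1
    half = k // 2
    x = np.where(mask, values, np.nan)
    pad = np.pad(x, half, constant_values=np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(pad, k)
    with np.errstate(all="ignore"):
        return np.nanmedian(windows, axis=1)


def _median_deglitch(
    values: np.ndarray,
    mask: np.ndarray,
    k_smooth: int,
    k_gate: int,
    rel_tol: float = 0.45,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage pitch-track cleanup; returns ``(values, voiced)``.

    A short plain running median (``k_smooth`` frames) suppresses
    estimation noise and brief octave flips. Frames that still deviate
    from a longer local median (``k_gate`` frames) by more than
    ``rel_tol`` — chosen between genuine modulation excursions and the
    smallest octave error (a halving is a 50% deviation) — are residual
    octave-error runs; they are marked UNVOICED rather than repaired,
    so surviving frames carry undistorted pitch values and downstream
    pairwise deletion absorbs the gaps.
    """
    out = values
    voiced = mask
    if k_smooth >= 3 and values.size >= k_smooth:
        med = _running_median(out, voiced, k_smooth)
        out = np.where(voiced & np.isfinite(med), med, out)
    if k_gate >= 3 and values.size >= k_gate:
        med = _running_median(out, voiced, k_gate)
        with np.errstate(invalid="ignore"):
            bad = voiced & np.isfinite(med) & (
                np.abs(out - med) > rel_tol * np.abs(med)
            )
        voiced = voiced & ~bad
    return out, voiced


def estimate_f0(
    w: Waveform,
    fmin: float = 60.0,
    fmax: float = 1000.0,
    frame_s: float = 0.025,
    out_rate: float = 1000.0,
    voicing_threshold: float = VOICING_THRESHOLD,
    median_s: float = 0.015,
    deglitch_s: float = 0.0,
) -> FeatureTrajectory:
    """Fundamental frequency trajectory at 1000 Hz with a voiced mask.

    The raw track is cleaned by a short running median (``median_s``,
    default 15 ms); frames still deviating octave-like from a longer
    local median (``deglitch_s``, default 45 ms) are marked unvoiced.
    Set both to 0 to disable post-processing.
    """
    f0, _, voiced = _autocorr_track(w, out_rate, fmin, fmax, frame_s, voicing_threshold)
    if median_s > 0 or deglitch_s > 0:
        f0, voiced = _median_deglitch(
            f0, voiced,
            int(round(median_s * out_rate)),
            int(round(deglitch_s * out_rate)),
        )
    return FeatureTrajectory(name="F0", values=f0, rate_hz=out_rate, mask=voiced, units="Hz")


def estimate_hnr(
    w: Waveform,
    fmin: float = 60.0,
    fmax: float = 1000.0,
    frame_s: float = 0.025,
    voicing_threshold: float = VOICING_THRESHOLD,
    max_db: float = 40.0,
    mask_unvoiced: bool = True,
) -> FeatureTrajectory:
    """Harmonic-to-noise ratio (dB) at 100 Hz, masked to voiced frames."""
    _, r, voiced = _autocorr_track(w, 100.0, fmin, fmax, frame_s, voicing_threshold)
    r_max = 1.0 / (1.0 + 10 ** (-max_db / 10.0))
    rc = np.clip(r, 1.0 - r_max, r_max)
    hnr = 10.0 * np.log10(rc / (1.0 - rc))
    mask = voiced if mask_unvoiced else None
    return FeatureTrajectory(name="HNR", values=hnr, rate_hz=100.0, mask=mask, units="dB")


def cpp_from_cepstrum(
    cepstrum: np.ndarray, quefrency_s: np.ndarray, band: tuple[float, float]
) -> float:
    """Cepstral peak prominence of one cepstrum slice.

    Peak value within the quefrency ``band`` (seconds) minus the value,
    at the peak quefrency, of a least-squares line fit to the cepstrum
    over that band. Zero if the cepstrum equals its own regression line.
    """
    sel = (quefrency_s >= band[0]) & (quefrency_s <= band[1])
    q = quefrency_s[sel]
    c = np.asarray(cepstrum, float)[sel]
    if q.size < 3:
        raise InvalidInputError("quefrency band too narrow for CPP")
    A = np.column_stack([q, np.ones_like(q)])
    coef, *_ = np.linalg.lstsq(A, c, rcond=None)
    i = int(np.argmax(c))
    return float(c[i] - (coef[0] * q[i] + coef[1]))


def estimate_cpp(
    w: Waveform,
    fmin: float = 60.0,
    fmax: float = 1000.0,
    frame_s: float = 0.040,
    voicing_threshold: float = VOICING_THRESHOLD,
    mask_unvoiced: bool = True,
) -> FeatureTrajectory:
    """Cepstral peak prominence (dB) at 100 Hz, masked to voiced frames.

    A 40 ms frame is used so at least two pitch periods fit at the
    default ``fmin`` of 60 Hz, the minimum for a stable cepstral peak.
    """
    _check_waveform(w)
    fs = w.rate_hz
    frame_len = max(int(round(frame_s * fs)), 32)
    n_frames, centers, offs = _frame_indices(w.samples.size, fs, 100.0, frame_len)
    nfft = sfft.next_fast_len(2 * frame_len)
    window = np.hanning(frame_len)
    quef = np.arange(nfft) / fs
    band = (1.0 / fmax, 1.0 / fmin)
    sel = (quef >= band[0]) & (quef <= band[1])
    q = quef[sel]
    if q.size < 3:
        raise InvalidInputError("frame too short to resolve the pitch quefrency band")
    A = np.column_stack([q, np.ones_like(q)])
    proj = np.linalg.pinv(A)  # (2, B): per-frame regression in one matmul

    cpp = np.zeros(n_frames)
    for start in range(0, n_frames, _FRAME_BLOCK):
        sl = slice(start, min(start + _FRAME_BLOCK, n_frames))
        frames = _gather_frames(w.samples, centers[sl], offs) * window[None, :]
        spec_db = 20.0 * np.log10(np.abs(sfft.rfft(frames, n=nfft, axis=1)) + 1e-12)
        ceps = sfft.irfft(spec_db, n=nfft, axis=1)
        cb = ceps[:, sel]
        coef = cb @ proj.T  # (F, 2): slope, intercept
        i = np.argmax(cb, axis=1)
        rows = np.arange(cb.shape[0])
        cpp[sl] = cb[rows, i] - (coef[:, 0] * q[i] + coef[:, 1])

    mask = None
    if mask_unvoiced:
        _, _, voiced = _autocorr_track(w, 100.0, fmin, fmax, 0.025, voicing_threshold)
        mask = voiced[:n_frames]
    return FeatureTrajectory(name="CPP", values=cpp, rate_hz=100.0, mask=mask, units="dB")


def _resample_for_lpc(w: Waveform, target_fs: float = 10000.0) -> tuple[np.ndarray, float]:
    if w.rate_hz <= 11025.0:
        return w.samples, w.rate_hz
    from fractions import Fraction

    frac = Fraction(int(round(target_fs)), int(round(w.rate_hz))).limit_denominator(1000)
    x = sps.resample_poly(w.samples, frac.numerator, frac.denominator)
    return x, w.rate_hz * frac.numerator / frac.denominator


def estimate_formants(
    w: Waveform,
    n_formants: int = 3,
    lpc_order: int | None = None,
    frame_s: float = 0.025,
    max_bandwidth_hz: float = 400.0,
    pre_emphasis: float = 0.97,
) -> dict[str, FeatureTrajectory]:
    """First ``n_formants`` formant trajectories (Hz) at 100 Hz.

    Frame-wise LPC via the autocorrelation method; roots of the LPC
    polynomial with bandwidth under ``max_bandwidth_hz`` and frequency
    inside (90 Hz, Nyquist) become formant candidates, sorted ascending.
    Frames with fewer than ``n_formants`` candidates are masked invalid.
    """
    _check_waveform(w)
    x, fs = _resample_for_lpc(w)
    if lpc_order is None:
        lpc_order = 2 + int(round(fs / 1000.0))
    x = np.append(x[0], x[1:] - pre_emphasis * x[:-1])
    frame_len = max(int(round(frame_s * fs)), 2 * lpc_order + 2)
    n_frames, centers, offs = _frame_indices(x.size, fs, 100.0, frame_len)
    window = np.hanning(frame_len)
    nfft = sfft.next_fast_len(2 * frame_len)
    glob_rms = float(np.sqrt(np.mean(x**2)))

    values = np.full((n_formants, n_frames), np.nan)
    mask = np.zeros(n_frames, dtype=bool)
    p = lpc_order
    for start in range(0, n_frames, _FRAME_BLOCK):
        sl = slice(start, min(start + _FRAME_BLOCK, n_frames))
        frames = _gather_frames(x, centers[sl], offs) * window[None, :]
        rms = np.sqrt(np.mean(frames**2, axis=1))
        spec = sfft.rfft(frames, n=nfft, axis=1)
        r = sfft.irfft(np.abs(spec) ** 2, n=nfft, axis=1)[:, : p + 1]
        for fi in range(frames.shape[0]):
            gi = start + fi
            if rms[fi] <= SILENCE_REL_RMS * max(glob_rms, 1e-12):
                continue
            rr = r[fi].copy()
            if rr[0] <= 0:
                continue
            rr[0] *= 1.0 + 1e-9  # mild regularization
            try:
                a = sla.solve_toeplitz((rr[:p], rr[:p]), rr[1 : p + 1])
            except np.linalg.LinAlgError:
                continue
            roots = np.roots(np.concatenate(([1.0], -a)))
            roots = roots[np.imag(roots) > 0]
            mag = np.abs(roots)
            mag[mag == 0] = 1e-12
            freq = np.angle(roots) * fs / (2 * np.pi)
            bw = -np.log(mag) * fs / np.pi
            ok = (bw < max_bandwidth_hz) & (freq > 90.0) & (freq < fs / 2.0)
            cand = np.sort(freq[ok])
            if cand.size >= n_formants:
                values[:, gi] = cand[:n_formants]
                mask[gi] = True

    return {
        f"F{i + 1}": FeatureTrajectory(
            name=f"F{i + 1}", values=values[i], rate_hz=100.0, mask=mask, units="Hz"
        )
        for i in range(n_formants)
    }


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)


def _mel_filterbank(n_mels: int, nfft: int, fs: float) -> np.ndarray:
    edges = _mel_inv(np.linspace(_mel(0.0), _mel(fs / 2.0), n_mels + 2))
    bins = np.fft.rfftfreq(nfft, d=1.0 / fs)
    fb = np.zeros((n_mels, bins.size))
    for m in range(n_mels):
        lo, mid, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (bins - lo) / max(mid - lo, 1e-9)
        down = (hi - bins) / max(hi - mid, 1e-9)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def estimate_mfcc(
    w: Waveform,
    n_coeffs: int = 5,
    n_mels: int = 26,
    frame_s: float = 0.025,
    out_rate: float = 200.0,
) -> dict[str, FeatureTrajectory]:
    """MFCC coefficients 1..``n_coeffs`` at 200 Hz (5 ms hop).

    c0 is excluded, so a positive rescaling of the waveform (a pure
    gain) leaves all returned coefficients unchanged.
    """
    _check_waveform(w)
    fs = w.rate_hz
    frame_len = max(int(round(frame_s * fs)), 16)
    n_frames, centers, offs = _frame_indices(w.samples.size, fs, out_rate, frame_len)
    nfft = sfft.next_fast_len(frame_len)
    window = np.hanning(frame_len)
    fb = _mel_filterbank(n_mels, nfft, fs)

    coeffs = np.zeros((n_coeffs, n_frames))
    for start in range(0, n_frames, _FRAME_BLOCK):
        sl = slice(start, min(start + _FRAME_BLOCK, n_frames))
        frames = _gather_frames(w.samples, centers[sl], offs) * window[None, :]
        power = np.abs(sfft.rfft(frames, n=nfft, axis=1)) ** 2
        energy = np.log(np.maximum(power @ fb.T, 1e-30))
        cc = sfft.dct(energy, type=2, axis=1, norm="ortho")
        coeffs[:, sl] = cc[:, 1 : n_coeffs + 1].T

    return {
        f"MFCC{i + 1}": FeatureTrajectory(
            name=f"MFCC{i + 1}", values=coeffs[i], rate_hz=out_rate, units=""
        )
        for i in range(n_coeffs)
    }


def estimate_envelope(
    w: Waveform, cutoff_hz: float = 20.0, out_rate: float = 100.0
) -> FeatureTrajectory:
    """Amplitude envelope (linear) at 100 Hz; all frames valid.

    Magnitude of the analytic signal, low-pass filtered at
    ``cutoff_hz`` (must be <= 30 Hz to isolate the slow respiratory
    modulation) and sampled on the output grid.
    """
    _check_waveform(w)
    if not 0 < cutoff_hz <= 30.0:
        raise InvalidInputError(f"envelope cutoff must be in (0, 30] Hz, got {cutoff_hz}")
    fs = w.rate_hz
    n = w.samples.size
    nfft = sfft.next_fast_len(n)
    analytic = sps.hilbert(w.samples, N=nfft)[:n]
    env = np.abs(analytic)
    sos = sps.butter(4, cutoff_hz, fs=fs, output="sos")
    env = sps.sosfiltfilt(sos, env)
    env = np.clip(env, 0.0, None)
    n_out = int(round(n / fs * out_rate))
    t_out = np.arange(n_out) / out_rate
    t_in = np.arange(n) / fs
    vals = np.interp(t_out, t_in, env)
    return FeatureTrajectory(name="ENV", values=vals, rate_hz=out_rate, units="amplitude")


def extract_all(
    w: Waveform,
    n_mfcc: int = 5,
    fmin: float = 60.0,
    fmax: float = 1000.0,
    voicing_threshold: float = VOICING_THRESHOLD,
    channels: list[str] | None = None,
) -> RecordingFeatures:
    """Run all extractors on one waveform.

    The F0-derived voiced mask is attached to the F0, HNR and CPP
    channels (downsampled from 1000 Hz to 100 Hz by frame alignment),
    so the three laryngeal channels share one voicing decision. A
    failing extractor masks its channel (logged) without aborting the
    recording.
    """
    _check_waveform(w)
    out: dict[str, FeatureTrajectory] = {}
    wanted = set(channels) if channels else None

    def want(name: str) -> bool:
        if wanted is None:
            return True
        if name.startswith("MFCC"):
            return any(c.startswith("MFCC") or c == "MFCC" for c in wanted)
        if name in ("F1", "F2", "F3"):
            return bool(wanted & {"F1", "F2", "F3", "FORMANTS"})
        return name in wanted

    def attempt(name: str, fn):
        try:
            res = fn()
        except Exception:  # noqa: BLE001 - per-channel failures are logged
            logger.warning("channel %s failed for %r; masking", name, w.recording_id,
                           exc_info=True)
            rate = registry_rate(name)
            n = int(round(w.duration_s * rate))
            res = FeatureTrajectory(
                name=name, values=np.full(n, np.nan), rate_hz=rate,
                mask=np.zeros(n, dtype=bool),
            )
        if isinstance(res, dict):
            out.update(res)
        else:
            out[res.name] = res

    f0 = None
    if want("F0") or want("HNR") or want("CPP"):
        attempt("F0", lambda: estimate_f0(
            w, fmin=fmin, fmax=fmax, voicing_threshold=voicing_threshold))
        f0 = out.get("F0")
    if want("HNR"):
        attempt("HNR", lambda: estimate_hnr(
            w, fmin=fmin, fmax=fmax, mask_unvoiced=False))
    if want("CPP"):
        attempt("CPP", lambda: estimate_cpp(
            w, fmin=fmin, fmax=fmax, mask_unvoiced=False))
    if want("ENV"):
        attempt("ENV", lambda: estimate_envelope(w))
    if want("F1"):
        attempt("F1", lambda: estimate_formants(w))
    if want("MFCC1"):
        attempt("MFCC1", lambda: estimate_mfcc(w, n_coeffs=n_mfcc))

    # unify the laryngeal voicing decision on the F0 mask
    if f0 is not None:
        for name in ("HNR", "CPP"):
            if name in out:
                tr = out[name]
                idx = np.minimum(
                    (np.arange(tr.n_frames) * 10).astype(int), f0.n_frames - 1
                )
                shared = f0.mask[idx] if f0.n_frames else np.zeros(tr.n_frames, bool)
                out[name] = FeatureTrajectory(
                    name=name, values=np.where(shared, tr.values, np.nan),
                    rate_hz=tr.rate_hz, mask=shared, units=tr.units,
                )

    return RecordingFeatures(
        recording_id=w.recording_id,
        subject_id=w.subject_id,
        category=w.category,
        duration_s=w.duration_s,
        channels=out,
    )
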