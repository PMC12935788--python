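"""Time-delay-embedded correlation matrices and their eigenspectra.

For a combination of ``n`` feature channels, each channel is paired
with ``D`` delayed copies of itself (default ``D=15`` delays at 10 ms
steps). The resulting ``(D*n) x (D*n)`` matrix holds Pearson
correlations between every pair of delayed channel copies: diagonal
blocks sample each channel's autocorrelation function, off-diagonal
blocks sample cross-correlation functions. The ranked eigenvalues of
this matrix summarize the effective degrees of freedom of the channel
set — a spectrum concentrated in few leading eigenvalues indicates
tightly coupled (low-complexity) movement, a flat spectrum many
independent degrees of freedom (high complexity). The signed eigenvalue
sum always equals the matrix size ``D*n`` (the trace).

All channels are resampled to a common analysis grid (default 100 Hz,
so one delay step is exactly one frame) with mask-aware linear
interpolation. Correlations use pairwise deletion over valid frames;
when a combination involves laryngeal channels (F0, HNR, CPP, creak)
the joint voiced mask is applied to every channel in the combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    InsufficientOverlapError,
    InvalidMatrixError,
    InvalidSpecError,
    MissingChannelError,
    UndefinedCorrelationError,
    UndefinedSpectrumError,
)
from .types import LARYNGEAL_CHANNELS, FeatureTrajectory, RecordingFeatures

logger = logging.getLogger(__name__)

__all__ = [
    "ComboSpec",
    "CorrelationMatrix",
    "EigenSpectrum",
    "cross_correlation",
    "resample_to_grid",
    "build_delay_matrix",
    "eigenspectrum",
    "spectrum_flatness",
]

#: Default minimum number of valid sample pairs for any single entry.
MIN_VALID_PAIRS = 25
#: Default minimum number of jointly valid frames for a recording/combo.
MIN_VALID_FRAMES = 100


@dataclass(frozen=True)
class ComboSpec:
    """One feature combination and its embedding geometry.

    ``n_delays`` delayed copies at ``delay_step_ms`` spacing on a
    ``grid_rate_hz`` analysis grid; the delay step must be a whole
    number of grid frames. ``mask_policy`` is ``"voiced-if-laryngeal"``
    (apply the joint voiced mask to all channels whenever the combo
    contains a laryngeal channel) or ``"none"``.
    """

    name: str
    channels: tuple[str, ...]
    n_delays: int = 15
    delay_step_ms: float = 10.0
    grid_rate_hz: float = 100.0
    mask_policy: str = "voiced-if-laryngeal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        if len(self.channels) < 1:
            raise InvalidSpecError("combo needs at least one channel")
        if self.n_delays < 1:
            raise InvalidSpecError("n_delays must be >= 1")
        step = self.delay_step_ms * self.grid_rate_hz / 1000.0
        if abs(step - round(step)) > 1e-9 or round(step) < 1:
            raise InvalidSpecError(
                f"delay step {self.delay_step_ms} ms is not a positive whole "
                f"number of frames at {self.grid_rate_hz} Hz"
            )
        if self.mask_policy not in ("voiced-if-laryngeal", "none"):
            raise InvalidSpecError(f"unknown mask_policy {self.mask_policy!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def delay_frames(self) -> int:
        """Delay step in grid frames (1 for 10 ms at 100 Hz)."""
        return int(round(self.delay_step_ms * self.grid_rate_hz / 1000.0))

    @property
    def size(self) -> int:
        """Side length of the correlation matrix, ``D * n``."""
        return self.n_delays * self.n_channels

    def involves_laryngeal(self) -> bool:
        return any(c in LARYNGEAL_CHANNELS for c in self.channels)


@dataclass
class CorrelationMatrix:
    """The delay-embedded correlation matrix of one recording/combo."""

    combo: ComboSpec
    matrix: np.ndarray
    n_valid_pairs: int
    recording_id: str = ""
    subject_id: str = ""
    category: str = ""


@dataclass
class EigenSpectrum:
    """Ranked (descending) eigenvalues of one correlation matrix."""

    eigenvalues: np.ndarray
    combo: ComboSpec
    recording_id: str = ""
    subject_id: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)

    def __len__(self) -> int:
        return self.eigenvalues.size


def cross_correlation(
    a: np.ndarray,
    b: np.ndarray,
    lag: int = 0,
    mask_a: np.ndarray | None = None,
    mask_b: np.ndarray | None = None,
    min_valid_pairs: int = MIN_VALID_PAIRS,
) -> float:
    """Pearson correlation of ``a(t)`` with ``b(t + lag)``.

    Uses pairwise deletion: only index pairs ``(t, t+lag)`` where both
    samples are valid contribute. Raises
    :class:`InsufficientOverlapError` if fewer than ``min_valid_pairs``
    pairs remain and :class:`UndefinedCorrelationError` if either paired
    slice has zero variance.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if mask_a is None:
        mask_a = np.isfinite(a)
    if mask_b is None:
        mask_b = np.isfinite(b)

    if lag >= 0:
        x = a[: a.size - lag] if lag else a
        y = b[lag:]
        mx = mask_a[: a.size - lag] if lag else mask_a
        my = mask_b[lag:]
    else:
        x = a[-lag:]
        y = b[: b.size + lag]
        mx = mask_a[-lag:]
        my = mask_b[: b.size + lag]
    m = min(x.size, y.size)
    x, y, mx, my = x[:m], y[:m], mx[:m], my[:m]
    valid = mx & my
    n = int(valid.sum())
    if n < min_valid_pairs:
        raise InsufficientOverlapError(
            f"only {n} valid (t, t+{lag}) pairs; need {min_valid_pairs}"
        )
    xv = x[valid]
    yv = y[valid]
    xv = xv - xv.mean()
    yv = yv - yv.mean()
    sx = np.sqrt(xv @ xv)
    sy = np.sqrt(yv @ yv)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError(
            f"zero variance in paired slice at lag {lag}"
        )
    return float((xv @ yv) / (sx * sy))


def resample_to_grid(
    traj: FeatureTrajectory, grid_rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mask-aware linear interpolation onto the analysis grid.

    Returns ``(values, mask)``. A grid frame is valid only if both
    native frames bracketing it are valid (logical AND over contributing
    frames); invalid grid frames carry NaN.
    """
    n_out = int(round(traj.duration_s * grid_rate_hz))
    if n_out < 1 or traj.n_frames < 2:
        return np.full(max(n_out, 0), np.nan), np.zeros(max(n_out, 0), dtype=bool)
    pos = np.arange(n_out) * (traj.rate_hz / grid_rate_hz)
    i0 = np.clip(np.floor(pos).astype(int), 0, traj.n_frames - 1)
    i1 = np.clip(i0 + 1, 0, traj.n_frames - 1)
    w = np.clip(pos - i0, 0.0, 1.0)
    upper_contributes = w > 1e-12
    with np.errstate(invalid="ignore"):
        interp = (1.0 - w) * traj.values[i0] + w * traj.values[i1]
    vals = np.where(upper_contributes, interp, traj.values[i0])
    mask = traj.mask[i0] & (traj.mask[i1] | ~upper_contributes)
    vals = np.where(mask, vals, np.nan)
    return vals, mask


def build_delay_matrix(
    features: RecordingFeatures,
    combo: ComboSpec,
    min_valid_pairs: int = MIN_VALID_PAIRS,
    min_valid_frames: int = MIN_VALID_FRAMES,
) -> CorrelationMatrix:
    """Build the ``(D*n) x (D*n)`` channel-delay correlation matrix.

    Entry at block ``(i, j)``, delay offsets ``(a, b)`` equals the
    Pearson correlation of channel ``i`` with channel ``j`` lagged by
    ``(b - a)`` delay steps. The matrix is symmetrized as
    ``(M + M.T) / 2`` (it is symmetric by construction up to float
    round-off, since pairwise deletion uses identical index pairs for
    the two orderings).
    """
    missing = [c for c in combo.channels if c not in features.channels]
    if missing:
        raise MissingChannelError(
            f"recording {features.recording_id!r} lacks channels {missing}"
        )

    series: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for name in combo.channels:
        v, m = resample_to_grid(features.channels[name], combo.grid_rate_hz)
        series.append(v)
        masks.append(m)
    n_frames = min(v.size for v in series)
    series = [v[:n_frames] for v in series]
    masks = [m[:n_frames] for m in masks]

    if combo.mask_policy == "voiced-if-laryngeal" and combo.involves_laryngeal():
        joint = np.ones(n_frames, dtype=bool)
        for name, m in zip(combo.channels, masks):
            if name in LARYNGEAL_CHANNELS:
                joint &= m
        masks = [m & joint for m in masks]
        series = [np.where(m, v, np.nan) for v, m in zip(series, masks)]

    jointly_valid = np.ones(n_frames, dtype=bool)
    for m in masks:
        jointly_valid &= m
    if int(jointly_valid.sum()) < min_valid_frames:
        raise InsufficientOverlapError(
            f"recording {features.recording_id!r}: {int(jointly_valid.sum())} "
            f"jointly valid frames < {min_valid_frames} for combo {combo.name!r}"
        )

    D = combo.n_delays
    n = combo.n_channels
    step = combo.delay_frames
    size = combo.size

    # correlation table for channel pairs i <= j at every needed lag;
    # corr(x_j(t), x_i(t+lag)) equals corr(x_i(t), x_j(t-lag)) exactly
    # under pairwise deletion (identical index-pair set), so i > j and,
    # for i == j, negative lags are looked up by symmetry.
    table: dict[tuple[int, int, int], float] = {}
    n_pairs_min = n_frames
    for i in range(n):
        for j in range(i, n):
            for lag in range(-(D - 1) * step, (D - 1) * step + 1, step):
                if i == j and lag < 0:
                    continue
                table[(i, j, lag)] = cross_correlation(
                    series[i], series[j], lag,
                    mask_a=masks[i], mask_b=masks[j],
                    min_valid_pairs=min_valid_pairs,
                )
                k = abs(lag)
                mi = masks[i][: n_frames - k] if k else masks[i]
                mj = masks[j][k:] if k else masks[j]
                n_pairs_min = min(n_pairs_min, int((mi & mj).sum()))

    def corr(i: int, j: int, lag: int) -> float:
        if i > j:
            i, j, lag = j, i, -lag
        if i == j:
            lag = abs(lag)
        return table[(i, j, lag)]

    M = np.empty((size, size))
    offsets = np.arange(D) * step
    for i in range(n):
        for j in range(n):
            for ai, a in enumerate(offsets):
                for bi, b in enumerate(offsets):
                    M[i * D + ai, j * D + bi] = corr(i, j, int(b - a))
    M = 0.5 * (M + M.T)

    return CorrelationMatrix(
        combo=combo,
        matrix=M,
        n_valid_pairs=n_pairs_min,
        recording_id=features.recording_id,
        subject_id=features.subject_id,
        category=features.category,
    )


def eigenspectrum(
    M: CorrelationMatrix, clip_tol: float = 1e-6
) -> EigenSpectrum:
    """Ranked eigenvalues of the symmetrized correlation matrix.

    Pairwise deletion can make the matrix slightly indefinite:
    eigenvalues in ``(-clip_tol, 0)`` are clipped to zero; anything more
    negative is kept and logged as a warning with its magnitude.
    """
    A = np.asarray(M.matrix, dtype=np.float64)
    if not np.all(np.isfinite(A)):
        raise InvalidMatrixError(
            f"correlation matrix for {M.recording_id!r} contains NaN/inf"
        )
    A = 0.5 * (A + A.T)
    vals = np.linalg.eigvalsh(A)
    below = vals[vals <= -clip_tol]
    if below.size:
        logger.warning(
            "recording %r combo %r: %d eigenvalue(s) below -%g (most negative %.3e)",
            M.recording_id, M.combo.name, below.size, clip_tol, below.min(),
        )
    vals = np.where((vals > -clip_tol) & (vals < 0.0), 0.0, vals)
    vals = np.sort(vals)[::-1]
    return EigenSpectrum(
        eigenvalues=vals,
        combo=M.combo,
        recording_id=M.recording_id,
        subject_id=M.subject_id,
        category=M.category,
    )


def spectrum_flatness(s: "EigenSpectrum | np.ndarray") -> float:
    """Normalized Shannon entropy of the eigenvalue distribution, in [0, 1].

    1.0 for a perfectly uniform spectrum (maximal complexity), 0.0 when
    all variance sits in a single eigenvalue. Negative eigenvalues are
    treated as zero mass.
    """
    vals = s.eigenvalues if isinstance(s, EigenSpectrum) else np.asarray(s, float)
    vals = np.clip(vals, 0.0, None)
    total = vals.sum()
    if vals.size < 2 or total <= 0:
        raise UndefinedSpectrumError("flatness undefined for all-zero spectrum")
    p = vals / total
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return h / float(np.log(vals.size))
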