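"""Reading and writing the package's on-disk formats.

* audio: 16-bit PCM WAV (stereo is downmixed to mono, samples scaled
  to [-1, 1]);
* labels: CSV with header ``recording_id,subject_id,category,duration_s``;
* features: one long-format CSV per recording,
  ``channel,frame_index,time_s,value,valid``;
* spectra: long-format CSV
  ``recording_id,subject_id,category,combo,rank,eigenvalue``;
* patterns: long-format CSV ``category_1,category_2,combo,rank,d`` plus
  a JSON summary per (pair, combo) with label and diagnostics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .corrstruct import ComboSpec, EigenSpectrum
from .effects import EffectSizePattern
from .errors import InvalidInputError, InvalidLabelsError
from .types import FeatureTrajectory, RecordingFeatures, Waveform, registry_rate

__all__ = [
    "read_wav",
    "write_wav",
    "read_labels",
    "write_labels",
    "write_features_csv",
    "read_features_csv",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_patterns",
    "write_cohort",
]

LABEL_COLUMNS = ["recording_id", "subject_id", "category", "duration_s"]


def read_wav(path, recording_id: str = "", subject_id: str = "", category: str = "") -> Waveform:
    """Load a WAV file as a mono, [-1, 1]-scaled :class:`Waveform`."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:  # stereo: downmix
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if not recording_id:
        recording_id = Path(path).stem
    return Waveform(samples=data, rate_hz=float(rate), recording_id=recording_id,
                    subject_id=subject_id, category=category)


def write_wav(path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM."""
    peak = np.abs(w.samples).max() if w.samples.size else 0.0
    x = w.samples / peak if peak > 1.0 else w.samples
    wavfile.write(path, int(round(w.rate_hz)), (x * 32767).astype(np.int16))


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidLabelsError(f"labels file {path} missing columns {missing}")
    return df


def write_labels(path, labels: pd.DataFrame) -> None:
    labels.to_csv(path, index=False, columns=LABEL_COLUMNS)


def write_features_csv(path, rec: RecordingFeatures) -> None:
    rows = []
    for name in sorted(rec.channels):
        tr = rec.channels[name]
        t = tr.times()
        for k in range(tr.n_frames):
            rows.append(
                (name, k, t[k], tr.values[k] if tr.mask[k] else np.nan, int(tr.mask[k]))
            )
    pd.DataFrame(
        rows, columns=["channel", "frame_index", "time_s", "value", "valid"]
    ).to_csv(path, index=False)


def read_features_csv(
    path, recording_id: str = "", subject_id: str = "", category: str = ""
) -> RecordingFeatures:
    df = pd.read_csv(path)
    need = {"channel", "frame_index", "value", "valid"}
    if not need.issubset(df.columns):
        raise InvalidInputError(f"feature CSV {path} missing columns {need - set(df.columns)}")
    channels = {}
    duration = 0.0
    for name, g in df.groupby("channel"):
        g = g.sort_values("frame_index")
        rate = registry_rate(str(name))
        if "time_s" in g.columns and len(g) > 1:
            dt = np.median(np.diff(g["time_s"].to_numpy()))
            if dt > 0:
                rate = 1.0 / dt
        channels[str(name)] = FeatureTrajectory(
            name=str(name),
            values=g["value"].to_numpy(dtype=float),
            rate_hz=rate,
            mask=g["valid"].to_numpy().astype(bool),
        )
        duration = max(duration, len(g) / rate)
    if not recording_id:
        recording_id = Path(path).stem
    return RecordingFeatures(
        recording_id=recording_id, subject_id=subject_id, category=category,
        duration_s=duration, channels=channels,
    )


def write_spectra_csv(path, spectra: list[EigenSpectrum]) -> None:
    frames = []
    for s in spectra:
        frames.append(
            pd.DataFrame(
                {
                    "recording_id": s.recording_id,
                    "subject_id": s.subject_id,
                    "category": s.category,
                    "combo": s.combo.name,
                    "rank": np.arange(1, len(s) + 1),
                    "eigenvalue": s.eigenvalues,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["recording_id", "subject_id", "category", "combo", "rank", "eigenvalue"]
        )
    )
    df.to_csv(path, index=False)


def read_spectra_csv(path, combos: "list[ComboSpec] | None" = None) -> list[EigenSpectrum]:
    """Rebuild :class:`EigenSpectrum` objects from a spectra CSV.

    ``combos`` supplies the full ComboSpec per combo name; unknown
    combos get a reconstructed single-block spec sized to the data.
    """
    df = pd.read_csv(path)
    by_name = {c.name: c for c in combos} if combos else {}
    out = []
    for (rec, subj, cat, combo_name), g in df.groupby(
        ["recording_id", "subject_id", "category", "combo"], sort=False, dropna=False
    ):
        g = g.sort_values("rank")
        vals = g["eigenvalue"].to_numpy(dtype=float)
        combo = by_name.get(combo_name)
        if combo is None:
            size = vals.size
            n_delays = 15 if size % 15 == 0 else size
            combo = ComboSpec(
                name=str(combo_name),
                channels=tuple(f"x{i}" for i in range(size // n_delays)),
                n_delays=n_delays,
            )
            by_name[combo_name] = combo
        out.append(
            EigenSpectrum(
                eigenvalues=vals, combo=combo,
                recording_id=str(rec), subject_id=str(subj), category=str(cat),
            )
        )
    return out


def write_patterns(csv_path, json_path, patterns: list[EffectSizePattern]) -> None:
    rows = []
    summary = []
    for p in patterns:
        for r, d in enumerate(p.d, start=1):
            rows.append((p.category_1, p.category_2, p.combo.name, r, d))
        summary.append(
            {
                "category_1": p.category_1,
                "category_2": p.category_2,
                "combo": p.combo.name,
                "label": p.label,
                "front_mean": p.front_mean,
                "back_mean": p.back_mean,
                "n_subjects_1": p.n_subjects_1,
                "n_subjects_2": p.n_subjects_2,
            }
        )
    pd.DataFrame(
        rows, columns=["category_1", "category_2", "combo", "rank", "d"]
    ).to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2)


def write_cohort(out_dir, items: list, labels: pd.DataFrame) -> None:
    """Write a synthetic cohort: WAVs or per-recording bundle CSVs + labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for item in items:
        if isinstance(item, Waveform):
            write_wav(out / f"{item.recording_id}.wav", item)
        else:
            write_features_csv(out / f"{item.recording_id}.csv", item)
    write_labels(out / "labels.csv", labels)
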