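"""End-to-end orchestration: filter, extract, correlate, compare.

``run_analysis`` takes a labelled corpus (audio waveforms, extracted
recordings, or synthetic feature bundles), applies the duration filter
(segments shorter than 2.5 s are eliminated; the 2.5 s boundary itself
is kept), extracts features where needed, builds per-recording
delay-embedded eigenspectra for every combination in the registry, and
fits the coordination model. Outputs are deterministic given the
configuration seed and inputs.

The default registry holds exactly 18 feature combinations, every one
with 15 delays at 10 ms steps, including the seven named combinations
of the underlying analysis design (F0; CPP; formants; F0 x HNR x CPP;
envelope x formants; F0 x HNR x CPP x envelope; formants x F0 x
envelope); the remaining eleven fill out the within/across-subsystem
design and are fully overridable in configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .corrstruct import ComboSpec
from .errors import ConfigurationError, InvalidLabelsError
from .features import extract_all
from .model import CoordinationModel, CoordinationResults
from .types import RecordingFeatures, Waveform

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "filter_segments",
    "default_combo_registry",
    "run_analysis",
    "AnalysisOutputs",
]

MIN_DURATION_S = 2.5

_FORMANTS = ("F1", "F2", "F3")
_MFCC = ("MFCC1", "MFCC2", "MFCC3", "MFCC4", "MFCC5")


def default_combo_registry() -> list[ComboSpec]:
    """The default registry of 18 feature combinations.

    Single channels first (within-subsystem autostructure), then
    within-subsystem and cross-subsystem interactions.
    """
    defs: list[tuple[str, tuple[str, ...]]] = [
        ("F0", ("F0",)),
        ("HNR", ("HNR",)),
        ("CPP", ("CPP",)),
        ("ENV", ("ENV",)),
        ("FORMANTS", _FORMANTS),
        ("MFCC", _MFCC),
        ("F0xHNR", ("F0", "HNR")),
        ("F0xCPP", ("F0", "CPP")),
        ("HNRxCPP", ("HNR", "CPP")),
        ("F0xENV", ("F0", "ENV")),
        ("F0xHNRxCPP", ("F0", "HNR", "CPP")),
        ("F0xHNRxCPPxENV", ("F0", "HNR", "CPP", "ENV")),
        ("ENVxFORMANTS", ("ENV",) + _FORMANTS),
        ("ENVxMFCC", ("ENV",) + _MFCC),
        ("FORMANTSxF0xENV", _FORMANTS + ("F0", "ENV")),
        ("FORMANTSxMFCC", _FORMANTS + _MFCC),
        ("MFCCxF0", _MFCC + ("F0",)),
        ("FORMANTSxF0", _FORMANTS + ("F0",)),
    ]
    return [ComboSpec(name=name, channels=channels) for name, channels in defs]


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run."""

    min_duration_s: float = MIN_DURATION_S
    combos: list[ComboSpec] = field(default_factory=default_combo_registry)
    category_pairs: list[tuple[str, str]] | None = None
    theta: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_duration_s <= 0:
            raise ConfigurationError("min_duration_s must be positive")

    @classmethod
    def from_dict(cls, cfg: dict) -> "AnalysisConfig":
        combos = cfg.get("combos")
        combo_specs = (
            [
                ComboSpec(
                    name=c["name"],
                    channels=tuple(c["channels"]),
                    n_delays=int(c.get("n_delays", 15)),
                    delay_step_ms=float(c.get("delay_step_ms", 10.0)),
                    grid_rate_hz=float(c.get("grid_rate_hz", 100.0)),
                    mask_policy=c.get("mask_policy", "voiced-if-laryngeal"),
                )
                for c in combos
            ]
            if combos
            else default_combo_registry()
        )
        pairs = cfg.get("category_pairs")
        return cls(
            min_duration_s=float(cfg.get("min_duration_s", MIN_DURATION_S)),
            combos=combo_specs,
            category_pairs=[tuple(p) for p in pairs] if pairs else None,
            theta=float(cfg.get("theta", 0.2)),
            seed=int(cfg.get("seed", 0)),
        )


def filter_segments(
    labels: pd.DataFrame, min_duration_s: float = MIN_DURATION_S
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the duration filter: keep segments with duration >= threshold.

    The boundary is inclusive (a 2.5 s segment survives the default
    2.5 s threshold; only segments strictly shorter are eliminated).
    Returns ``(kept, excluded)``; ``excluded`` carries a reason column.
    """
    if "duration_s" not in labels.columns:
        raise InvalidLabelsError("labels table has no 'duration_s' column")
    dur = pd.to_numeric(labels["duration_s"], errors="coerce")
    if (dur < 0).any() or dur.isna().any():
        raise InvalidLabelsError("duration_s must be non-negative numbers")
    keep = dur >= min_duration_s
    excluded = labels.loc[~keep].copy()
    excluded["reason"] = f"duration < {min_duration_s} s"
    return labels.loc[keep].copy(), excluded


@dataclass
class AnalysisOutputs:
    """Everything a run produces, plus the accounting of exclusions."""

    results: CoordinationResults
    spectra: list
    labels_used: pd.DataFrame
    duration_excluded: pd.DataFrame
    combo_exclusions: list[dict]

    def accounting(self) -> dict:
        """Per-combo identity: in = duration-excluded + combo-excluded + contributing."""
        n_in = len(self.labels_used) + len(self.duration_excluded)
        per_combo = {}
        contributing: dict[str, int] = {}
        for s in self.spectra:
            contributing[s.combo.name] = contributing.get(s.combo.name, 0) + 1
        excluded: dict[str, int] = {}
        for e in self.combo_exclusions:
            excluded[e["combo"]] = excluded.get(e["combo"], 0) + 1
        for combo in set(contributing) | set(excluded):
            per_combo[combo] = {
                "recordings_in": n_in,
                "excluded_by_duration": len(self.duration_excluded),
                "excluded_for_combo": excluded.get(combo, 0),
                "contributing": contributing.get(combo, 0),
            }
        return per_combo


def _to_recording(item, label_row: pd.Series) -> RecordingFeatures:
    if isinstance(item, RecordingFeatures):
        item.subject_id = item.subject_id or str(label_row["subject_id"])
        item.category = item.category or str(label_row["category"])
        return item
    if isinstance(item, Waveform):
        item.subject_id = item.subject_id or str(label_row["subject_id"])
        item.category = item.category or str(label_row["category"])
        return extract_all(item)
    raise ConfigurationError(f"unsupported corpus item type {type(item)!r}")


def run_analysis(
    config: AnalysisConfig,
    items: list,
    labels: pd.DataFrame,
    out_dir=None,
) -> AnalysisOutputs:
    """Run the full pipeline over a labelled corpus.

    ``items`` holds one :class:`Waveform` or :class:`RecordingFeatures`
    per labels row (matched on ``recording_id``). If ``out_dir`` is
    given, writes ``spectra.csv``, ``patterns.csv``, ``summary.json``
    and ``run.log`` there. Per-recording failures are logged and
    excluded; an empty post-filter corpus is fatal.
    """
    missing = [c for c in vio.LABEL_COLUMNS if c not in labels.columns]
    if missing:
        raise InvalidLabelsError(f"labels table missing columns {missing}")
    np.random.seed(config.seed % (2**32))  # extractors are deterministic; belt & braces

    kept, dur_excluded = filter_segments(labels, config.min_duration_s)
    if kept.empty:
        raise ConfigurationError(
            f"no recordings remain after the {config.min_duration_s} s duration "
            f"filter ({len(labels)} supplied)"
        )
    by_id = {getattr(i, "recording_id", None): i for i in items}
    recordings: list[RecordingFeatures] = []
    for _, row in kept.iterrows():
        item = by_id.get(row["recording_id"])
        if item is None:
            logger.warning("no corpus item for %r; skipping", row["recording_id"])
            continue
        recordings.append(_to_recording(item, row))
    if not recordings:
        raise ConfigurationError("no corpus items matched the filtered labels")

    model = CoordinationModel.from_recordings(
        recordings,
        combos=config.combos,
        category_pairs=config.category_pairs,
        theta=config.theta,
    )
    results = model.fit()
    outputs = AnalysisOutputs(
        results=results,
        spectra=model.spectra,
        labels_used=kept,
        duration_excluded=dur_excluded,
        combo_exclusions=model.exclusions,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vio.write_spectra_csv(out / "spectra.csv", model.spectra)
        vio.write_patterns(out / "patterns.csv", out / "summary.json", results.patterns)
        summary = {
            "config": {
                "min_duration_s": config.min_duration_s,
                "theta": config.theta,
                "seed": config.seed,
                "n_combos": len(config.combos),
            },
            "patterns": json.loads((out / "summary.json").read_text()),
            "accounting": outputs.accounting(),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        log_lines = [
            f"recordings supplied: {len(labels)}",
            f"excluded by duration filter (<{config.min_duration_s} s): "
            f"{len(dur_excluded)}",
        ]
        for e in model.exclusions:
            log_lines.append(
                f"excluded {e['recording_id']} for {e['combo']}: {e['reason']}"
            )
        for f in results.failures:
            log_lines.append(
                f"no pattern for ({f['category_1']}, {f['category_2']}, "
                f"{f['combo']}): {f['reason']}"
            )
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return outputs
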