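"""Domain types shared across the pipeline.

The data model is organised around a single bolus administration
(:class:`BolusTrial`): a participant swallows one mouthful of a test
stimulus while a dual-axis neck accelerometer records vibrations
(:class:`Recording`) and a simultaneous videofluoroscopy rating
(:class:`VfssRating`) supplies the clinical reference judgement.
A :class:`CohortDataset` collects the trials of a study cohort and is the
unit consumed by the label-derivation and evaluation layers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

__all__ = [
    "Consistency",
    "Recording",
    "VfssRating",
    "BolusTrial",
    "CohortDataset",
    "PipelineConfig",
    "PROTOCOL_BOLUSES",
    "DataError",
    "ConfigError",
]


class DataError(ValueError):
    """Malformed or inconsistent domain data."""


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class Consistency(enum.IntEnum):
    """Stimulus thickness level, ordered from thinnest to thickest."""

    thin = 0
    mildly_thick = 1
    moderately_thick = 2
    extremely_thick = 3

    @classmethod
    def from_string(cls, s: str) -> "Consistency":
        key = s.strip().lower().replace(" ", "_").replace("-", "_")
        aliases = {
            "thin": cls.thin,
            "mild": cls.mildly_thick,
            "mildly_thick": cls.mildly_thick,
            "moderate": cls.moderately_thick,
            "moderately_thick": cls.moderately_thick,
            "extreme": cls.extremely_thick,
            "extremely_thick": cls.extremely_thick,
        }
        try:
            return aliases[key]
        except KeyError:
            raise DataError(f"unknown consistency label: {s!r}") from None


#: Number of boluses per consistency in the administration protocol.
PROTOCOL_BOLUSES = {
    Consistency.thin: 6,
    Consistency.mildly_thick: 3,
    Consistency.moderately_thick: 3,
    Consistency.extremely_thick: 3,
}


@dataclass
class Recording:
    """One two-channel acceleration time series for a single bolus trial.

    Parameters
    ----------
    si_axis, ap_axis:
        Calibrated acceleration samples for the superior-inferior and
        anterior-posterior axes.  Units are deliberately unspecified; the
        pipeline is amplitude-scale aware only where it has to be.
    fs:
        Sampling rate in Hz.
    bit_depth:
        A/D converter resolution, kept as metadata only.
    """

    si_axis: np.ndarray
    ap_axis: np.ndarray
    fs: float = 10_000.0
    bit_depth: int = 12
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.si_axis = np.asarray(self.si_axis, dtype=np.float64)
        self.ap_axis = np.asarray(self.ap_axis, dtype=np.float64)
        if self.si_axis.ndim != 1 or self.ap_axis.ndim != 1:
            raise DataError("recording channels must be one-dimensional")
        if len(self.si_axis) != len(self.ap_axis):
            raise DataError(
                f"channel length mismatch: si={len(self.si_axis)} ap={len(self.ap_axis)}"
            )
        if len(self.si_axis) == 0:
            raise DataError("recording has zero samples")
        if not np.isfinite(self.si_axis).all() or not np.isfinite(self.ap_axis).all():
            raise DataError("recording contains non-finite samples")
        if not self.fs > 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.si_axis)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            np.array_equal(self.si_axis, other.si_axis)
            and np.array_equal(self.ap_axis, other.ap_axis)
            and self.fs == other.fs
            and self.bit_depth == other.bit_depth
            and self.trial_id == other.trial_id
        )


@dataclass(frozen=True)
class VfssRating:
    """Videofluoroscopy rating of one bolus.

    ``None`` marks a not-rateable feature (obscured anatomy on the video):
    the corresponding derived label becomes a missing data point.
    """

    pas: Optional[int] = None
    vallecular_fill: Optional[float] = None
    pyriform_fill: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pas is not None and self.pas not in range(1, 9):
            raise DataError(f"PAS must be an integer in 1..8, got {self.pas}")
        for name in ("vallecular_fill", "pyriform_fill"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise DataError(f"{name} must be in [0, 100], got {v}")


@dataclass
class BolusTrial:
    """One bolus administration with its rating and (optional) recording."""

    participant_id: str
    consistency: Consistency
    bolus_index: int  # 1-based order within the consistency series
    rating: VfssRating = field(default_factory=VfssRating)
    recording: Optional[Recording] = None
    group: str = ""

    def __post_init__(self) -> None:
        if self.bolus_index < 1:
            raise DataError(f"bolus_index must be >= 1, got {self.bolus_index}")
        self.consistency = Consistency(self.consistency)

    @property
    def safety_label(self) -> Optional[int]:
        """Binary unsafe-swallow label, or ``None`` if PAS is not rateable."""
        from .vfss import map_pas_to_safety

        return map_pas_to_safety(self.rating.pas)

    @property
    def efficiency_label(self) -> Optional[int]:
        """Binary inefficient-swallow label, or ``None`` if undeterminable."""
        from .vfss import map_residue_to_efficiency

        return map_residue_to_efficiency(
            self.rating.vallecular_fill, self.rating.pyriform_fill
        )

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.consistency, self.bolus_index)


class CohortDataset:
    """Participants x trials, with uniqueness and referential integrity."""

    def __init__(self, trials=(), participants=None):
        self.trials: list[BolusTrial] = list(trials)
        if participants is None:
            participants = {t.participant_id: {} for t in self.trials}
        self.participants: dict[str, dict] = dict(participants)
        self.validate()

    def validate(self) -> None:
        seen = set()
        for t in self.trials:
            if t.key in seen:
                raise DataError(f"duplicate trial {t.key}")
            seen.add(t.key)
            if t.participant_id not in self.participants:
                raise DataError(
                    f"trial references unknown participant {t.participant_id!r}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortDataset):
            return NotImplemented
        key = lambda t: t.key  # noqa: E731
        a, b = sorted(self.trials, key=key), sorted(other.trials, key=key)
        if len(a) != len(b):
            return False
        for ta, tb in zip(a, b):
            if ta.key != tb.key or ta.rating != tb.rating or ta.group != tb.group:
                return False
            if (ta.recording is None) != (tb.recording is None):
                return False
            if ta.recording is not None and ta.recording != tb.recording:
                return False
        return set(self.participants) == set(other.participants)

    def select(self, consistency: Optional[Consistency] = None) -> list[BolusTrial]:
        """Trials of one consistency, in (participant, bolus order)."""
        ts = [
            t
            for t in self.trials
            if consistency is None or t.consistency == consistency
        ]
        return sorted(ts, key=lambda t: t.key)

    def by_participant(self, consistency: Consistency) -> dict[str, list[BolusTrial]]:
        out: dict[str, list[BolusTrial]] = {}
        for t in self.select(consistency):
            out.setdefault(t.participant_id, []).append(t)
        return out


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis chain.

    Defaults follow the published acquisition/validation protocol where one
    is stated (filter corners and orders, split fraction, iteration count,
    per-consistency bolus caps); segmentation and feature constants are
    artifact choices exposed here.
    """

    # preprocessing
    hp_corner_hz: float = 0.1
    hp_order: int = 2
    lp_corner_hz: float = 1000.0
    lp_order: int = 4
    decimate_to_hz: Optional[float] = None

    # segmentation
    envelope_window_ms: float = 50.0
    seg_detection_hp_hz: Optional[float] = 30.0
    seg_enter_mads: float = 40.0
    seg_exit_mads: float = 10.0
    seg_min_duration_s: float = 0.2
    seg_merge_gap_s: float = 0.3

    # features
    feature_set: str = "default"
    wavelet_levels: int = 5
    aggregate: str = "mean"  # per-trial aggregation over segments

    # classifier
    shrinkage: Optional[float] = None  # None -> analytic selection
    priors: Optional[tuple] = None  # None -> training frequencies

    # evaluation
    n_iterations: int = 10_000
    validation_fraction: float = 0.2
    bolus_cap_thin: int = 4
    bolus_cap_other: int = 3
    specificity_target: float = 0.6

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ConfigError(
                f"validation_fraction must be in (0, 1), got {self.validation_fraction}"
            )
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if self.hp_corner_hz <= 0 or self.lp_corner_hz <= 0:
            raise ConfigError("filter corner frequencies must be positive")
        if self.shrinkage is not None and not (0.0 <= self.shrinkage <= 1.0):
            raise ConfigError(f"shrinkage must be in [0, 1], got {self.shrinkage}")
        if self.envelope_window_ms <= 0:
            raise ConfigError("envelope_window_ms must be positive")

    def bolus_cap(self, consistency: Consistency) -> int:
        return self.bolus_cap_thin if consistency == Consistency.thin else self.bolus_cap_other

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Read a ``key = value`` declarative config file; kwargs override."""
        values: dict = {}
        valid = {f.name: f for f in fields(cls)}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in valid:
                    raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = _coerce(val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _coerce(s: str):
    low = s.lower()
    if low in ("none", ""):
        return None
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s
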