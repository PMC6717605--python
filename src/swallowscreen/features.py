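"""Fixed-length feature vectors for segmented swallow events.

Default set, per axis: duration-normalized energy, variance, skewness,
kurtosis, zero-crossing rate, spectral centroid, spectral bandwidth, peak
frequency, spectral entropy and five relative wavelet detail-subband
energies (Haar, 5 levels); plus cross-axis correlation and segment
duration.  2 x 14 + 2 = 30 features.

Degenerate-segment conventions: constant signals get zero for moments,
spectral descriptors and correlation, so every vector is finite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps, stats

from .core import CohortDataset, Consistency, DataError, PipelineConfig, Recording
from .signals import Segment, preprocess, segment_swallows

__all__ = ["FeatureVector", "extract_features", "feature_names", "build_feature_table"]

log = logging.getLogger(__name__)

_AXIS_FEATURES = [
    "energy",
    "variance",
    "skewness",
    "kurtosis",
    "zcr",
    "spectral_centroid",
    "spectral_bandwidth",
    "peak_frequency",
    "spectral_entropy",
    "wavelet_d1",
    "wavelet_d2",
    "wavelet_d3",
    "wavelet_d4",
    "wavelet_d5",
]


def feature_names(config: PipelineConfig | None = None) -> list[str]:
    """Stable, ordered feature names for the configured feature set."""
    levels = config.wavelet_levels if config is not None else 5
    axis = [n for n in _AXIS_FEATURES if not n.startswith("wavelet")]
    axis += [f"wavelet_d{i}" for i in range(1, levels + 1)]
    return (
        [f"si_{n}" for n in axis]
        + [f"ap_{n}" for n in axis]
        + ["cross_correlation", "duration_s"]
    )


@dataclass(frozen=True)
class FeatureVector:
    values: tuple
    names: tuple
    trial_id: str = ""
    segment_index: int = 0

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise DataError("feature values/names length mismatch")
        if not np.isfinite(self.values).all():
            raise DataError("non-finite feature values")

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def _haar_relative_energies(x: np.ndarray, levels: int) -> list[float]:
    """Relative energy in Haar detail subbands d1..dL (finest to coarsest)."""
    total = float(np.sum(x**2))
    if total == 0.0:
        return [0.0] * levels
    a = x.astype(np.float64)
    energies = []
    for _ in range(levels):
        if len(a) < 2:
            energies.append(0.0)
            continue
        if len(a) % 2:
            a = a[:-1]
        d = (a[0::2] - a[1::2]) / np.sqrt(2.0)
        a = (a[0::2] + a[1::2]) / np.sqrt(2.0)
        energies.append(float(np.sum(d**2)) / total)
    return energies


def _spectral_descriptors(x: np.ndarray, fs: float) -> tuple[float, float, float, float]:
    f, pxx = sps.periodogram(x, fs=fs, detrend="constant")
    power = float(pxx.sum())
    if power <= 0.0:
        return 0.0, 0.0, 0.0, 0.0
    p = pxx / power
    centroid = float(np.sum(f * p))
    bandwidth = float(np.sqrt(np.sum(((f - centroid) ** 2) * p)))
    peak = float(f[int(np.argmax(pxx))])
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return centroid, bandwidth, peak, entropy


def _axis_features(x: np.ndarray, fs: float, levels: int) -> list[float]:
    duration = len(x) / fs
    energy = float(np.sum(x**2)) / duration
    var = float(np.var(x))
    if var > 0.0:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))
    else:
        skew = kurt = 0.0
    centered = x - x.mean()
    crossings = int(np.sum(np.abs(np.diff(np.signbit(centered)))))
    zcr = crossings / duration
    centroid, bandwidth, peak, entropy = _spectral_descriptors(x, fs)
    return [energy, var, skew, kurt, zcr, centroid, bandwidth, peak, entropy] + (
        _haar_relative_energies(x, levels)
    )


def extract_features(
    recording: Recording, segment: Segment, config: PipelineConfig
) -> FeatureVector:
    """Feature vector for one segment of a preprocessed recording."""
    if segment.end > len(recording):
        raise DataError(
            f"segment [{segment.start}, {segment.end}) outside recording of "
            f"length {len(recording)}"
        )
    si = recording.si_axis[segment.start : segment.end]
    ap = recording.ap_axis[segment.start : segment.end]
    levels = config.wavelet_levels
    vals = _axis_features(si, recording.fs, levels)
    vals += _axis_features(ap, recording.fs, levels)
    if si.std() > 0 and ap.std() > 0:
        corr = float(np.corrcoef(si, ap)[0, 1])
    else:
        corr = 0.0
    vals += [corr, segment.duration_s(recording.fs)]
    return FeatureVector(
        values=tuple(vals),
        names=tuple(feature_names(config)),
        trial_id=recording.trial_id,
        segment_index=0,
    )


def build_feature_table(
    cohort: CohortDataset,
    config: PipelineConfig,
    consistency: Consistency | None = None,
    preprocessed: bool = False,
) -> pd.DataFrame:
    """Assemble per-bolus feature rows for trials carrying recordings.

    One row per trial; features of multiple segments within a trial are
    aggregated element-wise (default: mean).  Trials without a recording or
    without any detected segment are dropped with a warning.  Returned
    columns: participant_id, consistency, bolus_index, safety_label,
    efficiency_label, n_segments, then the feature columns.
    """
    names = feature_names(config)
    rows = []
    n_dropped = 0
    for t in cohort.select(consistency):
        if t.recording is None:
            continue
        rec = t.recording if preprocessed else preprocess(t.recording, config)
        segments = segment_swallows(rec, config)
        if not segments:
            n_dropped += 1
            log.warning(
                "trial %s/%s/%d: no segments detected, row dropped",
                t.participant_id,
                t.consistency.name,
                t.bolus_index,
            )
            continue
        vectors = np.array(
            [extract_features(rec, s, config).values for s in segments]
        )
        if config.aggregate == "mean":
            agg = vectors.mean(axis=0)
        elif config.aggregate == "first":
            agg = vectors[0]
        else:
            raise DataError(f"unknown aggregation {config.aggregate!r}")
        row = {
            "participant_id": t.participant_id,
            "consistency": t.consistency.name,
            "bolus_index": t.bolus_index,
            "safety_label": t.safety_label,
            "efficiency_label": t.efficiency_label,
            "n_segments": len(segments),
        }
        row.update(dict(zip(names, agg)))
        rows.append(row)
    if n_dropped:
        warnings.warn(f"{n_dropped} trial(s) dropped with no detected segments")
    columns = [
        "participant_id",
        "consistency",
        "bolus_index",
        "safety_label",
        "efficiency_label",
        "n_segments",
    ] + names
    return pd.DataFrame(rows, columns=columns)
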