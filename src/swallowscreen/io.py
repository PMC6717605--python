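"""Readers and writers for the on-disk cohort and recording dialects.

Cohort dialect: one CSV row per bolus with columns
``participant_id, group, consistency, bolus_index, pas, vallecular_fill,
pyriform_fill, recording_path``; the token ``NR`` marks a not-rateable
feature.  ``recording_path`` is resolved relative to the cohort file and
points to a sidecar recording file (empty when no signal was stored).

Recording dialect: plain-text, two comma-separated columns ``si, ap``
preceded by ``# key=value`` header lines carrying ``fs_hz``, ``bit_depth``
and ``trial_id``.  Samples are stored as shortest round-tripping float64
literals, so a write/read cycle is bit-exact.  Files ending in ``.h5`` /
``.hdf5`` use an HDF5 container with the same keys instead (requires h5py).
"""

from __future__ import annotations

import csv
import os
from typing import Optional

import numpy as np

from .core import (
    BolusTrial,
    CohortDataset,
    Consistency,
    DataError,
    Recording,
    VfssRating,
)

__all__ = ["read_cohort", "write_cohort", "read_recording", "write_recording"]

COHORT_COLUMNS = [
    "participant_id",
    "group",
    "consistency",
    "bolus_index",
    "pas",
    "vallecular_fill",
    "pyriform_fill",
    "recording_path",
]

NR = "NR"


def _parse_cell(value: str, cast, row_no: int, col: str):
    value = value.strip()
    if value == "" or value.upper() == NR:
        return None
    try:
        return cast(value)
    except ValueError:
        raise DataError(f"row {row_no}: cannot parse {col}={value!r}") from None


def read_cohort(path) -> CohortDataset:
    """Read a cohort table, loading sidecar recordings when referenced.

    Raises :class:`DataError` naming the offending row for malformed cells
    and on duplicate (participant, consistency, bolus_index) keys.
    """
    base = os.path.dirname(os.path.abspath(path))
    trials: list[BolusTrial] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataError(f"{path}: empty file, header row required") from None
        header = [h.strip() for h in header]
        if header != COHORT_COLUMNS:
            raise DataError(
                f"{path}: bad header {header!r}, expected {COHORT_COLUMNS!r}"
            )
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(COHORT_COLUMNS):
                raise DataError(
                    f"row {row_no}: expected {len(COHORT_COLUMNS)} columns, got {len(row)}"
                )
            rec = dict(zip(COHORT_COLUMNS, (c.strip() for c in row)))
            pas = _parse_cell(rec["pas"], int, row_no, "pas")
            vall = _parse_cell(rec["vallecular_fill"], float, row_no, "vallecular_fill")
            pyr = _parse_cell(rec["pyriform_fill"], float, row_no, "pyriform_fill")
            idx = _parse_cell(rec["bolus_index"], int, row_no, "bolus_index")
            if idx is None:
                raise DataError(f"row {row_no}: bolus_index is mandatory")
            try:
                rating = VfssRating(pas=pas, vallecular_fill=vall, pyriform_fill=pyr)
                consistency = Consistency.from_string(rec["consistency"])
            except DataError as exc:
                raise DataError(f"row {row_no}: {exc}") from None
            recording = None
            if rec["recording_path"]:
                rec_path = os.path.join(base, rec["recording_path"])
                if not os.path.exists(rec_path):
                    raise DataError(f"row {row_no}: missing recording file {rec_path}")
                recording = read_recording(rec_path)
            try:
                trials.append(
                    BolusTrial(
                        participant_id=rec["participant_id"],
                        consistency=consistency,
                        bolus_index=idx,
                        rating=rating,
                        recording=recording,
                        group=rec["group"],
                    )
                )
            except DataError as exc:
                raise DataError(f"row {row_no}: {exc}") from None
    return CohortDataset(trials)


def write_cohort(cohort: CohortDataset, path, signals_dir: Optional[str] = None) -> str:
    """Write a cohort table; recordings go to per-trial sidecar files.

    ``signals_dir`` defaults to ``<path stem>_signals`` next to the table and
    is only created when at least one trial carries a recording.
    """
    base = os.path.dirname(os.path.abspath(path))
    if signals_dir is None:
        stem = os.path.splitext(os.path.basename(path))[0]
        signals_dir = stem + "_signals"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for t in sorted(cohort.trials, key=lambda t: t.key):
            rec_path = ""
            if t.recording is not None:
                os.makedirs(os.path.join(base, signals_dir), exist_ok=True)
                fname = f"{t.participant_id}_{t.consistency.name}_{t.bolus_index}.csv"
                rec_path = os.path.join(signals_dir, fname)
                write_recording(t.recording, os.path.join(base, rec_path))
            writer.writerow(
                [
                    t.participant_id,
                    t.group,
                    t.consistency.name,
                    t.bolus_index,
                    NR if t.rating.pas is None else t.rating.pas,
                    NR if t.rating.vallecular_fill is None else _fmt(t.rating.vallecular_fill),
                    NR if t.rating.pyriform_fill is None else _fmt(t.rating.pyriform_fill),
                    rec_path,
                ]
            )
    return path


def _fmt(x: float) -> str:
    return repr(float(x))


def _is_hdf5(path) -> bool:
    return str(path).lower().endswith((".h5", ".hdf5"))


def write_recording(recording: Recording, path) -> str:
    if _is_hdf5(path):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("si", data=recording.si_axis)
            f.create_dataset("ap", data=recording.ap_axis)
            f.attrs["fs_hz"] = recording.fs
            f.attrs["bit_depth"] = recording.bit_depth
            f.attrs["trial_id"] = recording.trial_id
        return path
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={_fmt(recording.fs)}\n")
        fh.write(f"# bit_depth={recording.bit_depth}\n")
        fh.write(f"# trial_id={recording.trial_id}\n")
        fh.write("si,ap\n")
        for a, b in zip(recording.si_axis, recording.ap_axis):
            fh.write(f"{float(a)!r},{float(b)!r}\n")
    return path


def read_recording(path) -> Recording:
    if _is_hdf5(path):
        import h5py

        with h5py.File(path, "r") as f:
            keys = set(f.keys())
            if keys != {"si", "ap"}:
                raise DataError(f"{path}: expected exactly channels si/ap, got {sorted(keys)}")
            rec = Recording(
                si_axis=f["si"][:],
                ap_axis=f["ap"][:],
                fs=float(f.attrs["fs_hz"]),
                bit_depth=int(f.attrs["bit_depth"]),
                trial_id=str(f.attrs.get("trial_id", "")),
            )
        return rec
    meta = {"fs_hz": None, "bit_depth": 12, "trial_id": ""}
    si, ap = [], []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = (s.strip() for s in body.split("=", 1))
                    meta[k] = v
                continue
            if line.replace(" ", "") == "si,ap":
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise DataError(
                    f"{path}: expected 2 channels per line, got {len(parts)}"
                )
            si.append(float(parts[0]))
            ap.append(float(parts[1]))
    if meta["fs_hz"] is None:
        raise DataError(f"{path}: missing fs_hz header")
    fs = float(meta["fs_hz"])
    if fs <= 0:
        raise DataError(f"{path}: fs_hz must be positive, got {fs}")
    return Recording(
        si_axis=np.array(si),
        ap_axis=np.array(ap),
        fs=fs,
        bit_depth=int(meta["bit_depth"]),
        trial_id=str(meta["trial_id"]),
    )
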