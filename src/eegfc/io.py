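"""Readers and writers: recordings (CSV/EDF), cohorts, labeled matrices."""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .recording import EEGRecording

__all__ = [
    "read_recording",
    "write_recording_csv",
    "write_cohort",
    "read_cohort",
    "matrix_to_csv",
    "matrix_from_csv",
]


def read_recording(
    path: str | pathlib.Path,
    fmt: str | None = None,
    fs: float | None = None,
    channel_order: list[str] | None = None,
    subject_id: str = "",
    group: str = "",
) -> EEGRecording:
    """Read a recording from CSV (header = channel labels, one sample per
    row) or EDF.

    CSV carries no sampling rate, so ``fs`` is required for it; EDF supplies
    its own. ``channel_order`` reorders channels to a configured montage
    (all requested labels must be present).
    """
    path = pathlib.Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "csv":
        if fs is None:
            raise ValueError("fs is required when reading CSV recordings")
        df = pd.read_csv(path, header=0, float_precision="round_trip")
        labels = [str(c) for c in df.columns]
        if any(lbl.replace(".", "").replace("-", "").isdigit() for lbl in labels):
            raise ValueError(f"{path}: header row of channel labels missing")
        if len(set(labels)) != len(labels):
            raise ValueError(f"{path}: duplicated channel labels")
        try:
            data = df.to_numpy(dtype=float).T
        except (TypeError, ValueError) as exc:
            bad = df.apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
            row = int(np.flatnonzero(bad)[0]) if bad.any() else -1
            raise ValueError(f"{path}: non-numeric cell at data row {row}") from exc
        rec = EEGRecording(labels, fs, data, subject_id=subject_id, group=group)
    elif fmt == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading EDF requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        rec = EEGRecording(
            list(raw.ch_names), float(raw.info["sfreq"]), raw.get_data(),
            subject_id=subject_id, group=group,
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if channel_order is not None:
        missing = [c for c in channel_order if c not in rec.channel_labels]
        if missing:
            raise ValueError(f"{path}: channels absent from file: {missing}")
        idx = [rec.channel_labels.index(c) for c in channel_order]
        rec = EEGRecording(
            list(channel_order), rec.fs, rec.data[idx],
            subject_id=rec.subject_id, group=rec.group, meta=rec.meta,
        )
    return rec


def write_recording_csv(rec: EEGRecording, path: str | pathlib.Path) -> None:
    """Write a recording as CSV: header of labels, one sample per row."""
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, index=False)


def write_cohort(recs: list[EEGRecording], outdir: str | pathlib.Path) -> pathlib.Path:
    """Write one CSV per subject plus a manifest; returns the manifest path."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recs:
        fname = f"{rec.subject_id}.csv"
        write_recording_csv(rec, outdir / fname)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "file": fname,
                "fs": rec.fs,
                "seed": rec.meta.get("subject_seed", ""),
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest: str | pathlib.Path) -> list[EEGRecording]:
    """Read every subject listed in a cohort manifest CSV."""
    manifest = pathlib.Path(manifest)
    table = pd.read_csv(manifest)
    recs = []
    for _, row in table.iterrows():
        recs.append(
            read_recording(
                manifest.parent / row["file"],
                fs=float(row["fs"]),
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
            )
        )
    return recs


def matrix_to_csv(W: np.ndarray, labels: list[str], path: str | pathlib.Path) -> None:
    pd.DataFrame(W, index=labels, columns=labels).to_csv(path)


def matrix_from_csv(path: str | pathlib.Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
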