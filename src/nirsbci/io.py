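"""File formats: long-format TSV recordings with a JSON sidecar, events
tables, participant profiles, and result exports.

A recording is stored as ``<stem>.tsv`` (columns time_s, channel,
wavelength_nm, intensity) plus ``<stem>.json`` holding the sampling rate,
wavelengths, montage, and optics parameters. Long TSV keeps everything
diffable and greppable at the modest data rates involved.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage
from .optics import OpticsParameters, RawIntensityRecording

logger = logging.getLogger(__name__)


class IOError_(ValueError):
    pass


def write_recording(rec: RawIntensityRecording, stem: str | Path,
                    montage: Montage | None = None,
                    optics: OpticsParameters | None = None) -> tuple[Path, Path]:
    """Write ``<stem>.tsv`` + ``<stem>.json``; returns both paths."""
    stem = Path(stem)
    n_ch, _, n = rec.data.shape
    t = np.arange(n) / rec.fs
    frames = []
    for w, wl in enumerate(rec.wavelengths):
        for ch in range(n_ch):
            frames.append(pd.DataFrame({
                "time_s": t, "channel": ch, "wavelength_nm": wl,
                "intensity": rec.data[ch, w],
            }))
    tsv = stem.with_suffix(".tsv")
    pd.concat(frames, ignore_index=True).to_csv(tsv, sep="\t", index=False,
                                                float_format="%.9g")
    sidecar = {
        "fs_hz": rec.fs,
        "wavelengths_nm": list(rec.wavelengths),
        "n_channels": n_ch,
        "n_samples": n,
        "session": rec.session,
        "participant": rec.participant,
    }
    if montage is not None:
        sidecar["montage"] = json.loads(montage.to_json())
    if optics is not None:
        sidecar["optics"] = optics.to_dict()
    js = stem.with_suffix(".json")
    js.write_text(json.dumps(sidecar, indent=2))
    return tsv, js


def read_recording(stem: str | Path) -> RawIntensityRecording:
    """Read and validate a recording written by :func:`write_recording`.

    Raises specific errors for a missing sidecar, a truncated table (naming
    the offending line), fs/sample-count mismatches, and non-positive
    intensities; unexpected wavelengths produce a warning only.
    """
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    js = stem.with_suffix(".json")
    if not js.exists():
        raise IOError_(f"missing JSON sidecar {js}")
    if not tsv.exists():
        raise IOError_(f"missing recording table {tsv}")
    meta = json.loads(js.read_text())
    try:
        df = pd.read_csv(tsv, sep="\t")
    except pd.errors.ParserError as exc:
        raise IOError_(f"malformed recording table {tsv}: {exc}") from None

    wavelengths = tuple(meta["wavelengths_nm"])
    if set(np.round(df["wavelength_nm"].unique(), 6)) != set(np.round(wavelengths, 6)):
        raise IOError_("wavelengths in table do not match sidecar")
    if wavelengths != (690.0, 830.0):
        logger.warning("unusual wavelengths %s; proceeding with declared values",
                       wavelengths)

    n_ch, n = int(meta["n_channels"]), int(meta["n_samples"])
    expected = n_ch * n * 2
    if len(df) != expected:
        # locate the first deviation for a useful message
        raise IOError_(
            f"recording table {tsv} has {len(df)} data rows, expected {expected} "
            f"(truncated near line {len(df) + 2})"
        )
    data = np.empty((n_ch, 2, n))
    for w, wl in enumerate(wavelengths):
        sub = df[np.isclose(df["wavelength_nm"], wl)]
        for ch in range(n_ch):
            series = sub[sub["channel"] == ch]["intensity"].to_numpy()
            if len(series) != n:
                raise IOError_(
                    f"channel {ch} at {wl} nm has {len(series)} samples, expected {n}"
                )
            data[ch, w] = series
    rec = RawIntensityRecording(
        fs=float(meta["fs_hz"]), data=data, wavelengths=wavelengths,
        session=int(meta.get("session", 0)),
        participant=str(meta.get("participant", "P0")),
    )
    rec.validate()
    return rec


def write_events(schedule: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    schedule.to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    required = {"session", "block", "interval", "onset_s", "duration_s", "task", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise IOError_(f"events table missing columns {sorted(missing)}")
    df["task"] = df["task"].fillna("")
    return df


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    profiles.to_csv(path, index=False)
    return path


def read_profiles(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
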