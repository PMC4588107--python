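"""Low-pass filtering and trial segmentation.

The hemodynamic response of interest lives below ~0.1 Hz; Mayer waves
(~0.1 Hz), respiration (0.2-0.4 Hz), and the cardiac cycle (0.5-2.0 Hz) are
suppressed with a third-order Chebyshev type-I IIR low-pass (0.1 dB passband
ripple, passband to 0.1 Hz, stopband from 0.5 Hz) realized as cascaded
second-order sections and applied causally, matching a real-time feedback
setting. Task intervals are then cut into 20-s epochs starting at task onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .optics import HemodynamicRecording


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    order: int = 3
    passband_hz: float = 0.1
    ripple_db: float = 0.1
    stopband_hz: float = 0.5
    fs: float = 31.25


def design_lowpass(spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Chebyshev type-I low-pass as second-order sections.

    An odd-order type-I design has unit gain at DC and stays within
    [-ripple, 0] dB across the passband. Raises if any pole falls on or
    outside the unit circle.
    """
    sos = signal.cheby1(
        spec.order, spec.ripple_db, spec.passband_hz, btype="low",
        fs=spec.fs, output="sos",
    )
    _, poles, _ = signal.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise PreprocessError("unstable filter design (pole on/outside unit circle)")
    return sos


def filter_recording(
    rec: HemodynamicRecording,
    spec: FilterSpec = FilterSpec(),
    zero_phase: bool = False,
) -> HemodynamicRecording:
    """Filter every channel/chromophore series; tHb is re-derived as the sum
    of the filtered HbO and Hb (which coincides with filtering tHb for a
    linear filter, up to rounding).

    ``zero_phase`` switches to forward-backward filtering; the default is the
    causal single pass.
    """
    if abs(rec.fs - spec.fs) > 1e-9:
        raise PreprocessError(f"recording fs {rec.fs} != filter fs {spec.fs}")
    sos = design_lowpass(spec)
    fn = (lambda x: signal.sosfiltfilt(sos, x, axis=-1)) if zero_phase else (
        lambda x: signal.sosfilt(sos, x, axis=-1))
    out = np.empty_like(rec.data)
    out[:, 0] = fn(rec.data[:, 0])
    out[:, 1] = fn(rec.data[:, 1])
    out[:, 2] = out[:, 0] + out[:, 1]
    return HemodynamicRecording(
        fs=rec.fs, data=out, session=rec.session, participant=rec.participant
    )


@dataclass
class TrialEpoch:
    """One 20-s task window of filtered concentration data.

    ``data`` is (n_channels, 3, n_samples); the first sample of every series
    has been subtracted so each epoch starts at zero (slope features are
    offset-invariant; this also anchors the topography baseline).
    """

    participant: str
    session: int
    block: int
    interval: int
    task: str
    onset_s: float
    fs: float
    data: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def segment_trials(
    recordings: HemodynamicRecording | list[HemodynamicRecording],
    schedule: pd.DataFrame,
    exclusions: pd.DataFrame | None = None,
    window_s: float = 20.0,
) -> list[TrialEpoch]:
    """Cut task intervals into epochs of ``round(window_s * fs)`` samples.

    One epoch per task interval in the schedule, except intervals listed in
    ``exclusions`` (matched on session, block, interval). Raises if any task
    onset+window extends past its recording.
    """
    if isinstance(recordings, HemodynamicRecording):
        recordings = [recordings]
    by_session = {rec.session: rec for rec in recordings}

    excluded: set[tuple[int, int, int]] = set()
    if exclusions is not None and len(exclusions):
        excluded = {
            (int(r.session), int(r.block), int(r.interval))
            for r in exclusions.itertuples()
        }

    task_rows = schedule[schedule["phase"] == "task"].sort_values(
        ["session", "onset_s"])
    epochs = []
    bad = []
    for row in task_rows.itertuples():
        key = (int(row.session), int(row.block), int(row.interval))
        if key in excluded:
            continue
        rec = by_session.get(int(row.session))
        if rec is None:
            bad.append(key)
            continue
        n_win = int(round(window_s * rec.fs))
        i0 = int(round(row.onset_s * rec.fs))
        if i0 + n_win > rec.n_samples:
            bad.append(key)
            continue
        window = rec.data[:, :, i0 : i0 + n_win].copy()
        window -= window[:, :, :1]
        epochs.append(TrialEpoch(
            participant=rec.participant, session=int(row.session),
            block=int(row.block), interval=int(row.interval), task=str(row.task),
            onset_s=float(row.onset_s), fs=rec.fs, data=window,
        ))
    if bad:
        raise PreprocessError(f"events outside recording bounds: {bad}")
    return epochs
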