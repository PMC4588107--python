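"""Modified Beer-Lambert law (MBLL) conversion from raw optical intensities
to chromophore concentration changes.

The MBLL relates the change in optical density at each wavelength to the
concentration changes of oxygenated and deoxygenated hemoglobin::

    dOD_lambda = (eps_HbO(lambda) * d[HbO] + eps_Hb(lambda) * d[Hb]) * d * DPF

where ``d`` is the geometric source-detector distance and ``DPF`` the
differential pathlength factor. Inverting the 2x2 extinction system at the
two wavelengths yields d[HbO] and d[Hb]; total hemoglobin is their sum.

Absolute micromolar scaling depends on the extinction tabulation and DPF
convention chosen; all downstream features are slopes and therefore invariant
to that common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage

CHROMOPHORES = ("hbo", "hbr", "thb")

#: Molar extinction coefficients in 1/(mM*cm), base-10 convention, from the
#: commonly used compiled hemoglobin spectra (Gratzer/Kollias tabulation as
#: distributed by S. Prahl, OMLC). Rows: wavelength; columns: (HbO, Hb).
DEFAULT_EXTINCTION = {
    690.0: (0.276, 2.0520),
    830.0: (0.974, 0.6930),
}


class OpticsError(ValueError):
    """Raised for invalid optical parameters or intensities."""


@dataclass(frozen=True)
class OpticsParameters:
    """Parameters of the MBLL conversion.

    Attributes
    ----------
    extinction
        2x2 matrix (wavelength x chromophore) in 1/(mM*cm), base-10.
    distance_cm
        Geometric source-detector separation (cm).
    dpf
        Differential pathlength factor per wavelength (dimensionless).
        Default 6.0 at both wavelengths, the common adult-forehead convention.
    """

    wavelengths: tuple[float, float] = (690.0, 830.0)
    extinction: tuple[tuple[float, float], ...] | None = None
    distance_cm: float = 3.0
    dpf: tuple[float, float] = (6.0, 6.0)

    def __post_init__(self):
        if self.extinction is None:
            try:
                eps = tuple(DEFAULT_EXTINCTION[float(w)] for w in self.wavelengths)
            except KeyError as exc:
                raise OpticsError(
                    f"no default extinction coefficients for wavelength {exc}; "
                    "pass them explicitly"
                ) from None
            object.__setattr__(self, "extinction", eps)
        if self.distance_cm <= 0:
            raise OpticsError("source-detector distance must be positive")
        if any(v <= 0 for v in self.dpf):
            raise OpticsError("DPF must be positive")
        cond = np.linalg.cond(self.extinction_matrix())
        if not np.isfinite(cond) or cond > 1e12:
            raise OpticsError("extinction matrix is singular or ill-conditioned")

    def extinction_matrix(self) -> np.ndarray:
        return np.asarray(self.extinction, dtype=float)

    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": list(self.wavelengths),
            "extinction_mM_cm": [list(r) for r in self.extinction],
            "distance_cm": self.distance_cm,
            "dpf": list(self.dpf),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "OpticsParameters":
        return cls(
            wavelengths=tuple(obj["wavelengths_nm"]),
            extinction=tuple(tuple(r) for r in obj["extinction_mM_cm"]),
            distance_cm=float(obj["distance_cm"]),
            dpf=tuple(obj["dpf"]),
        )


@dataclass
class HemodynamicRecording:
    """Concentration-change time series for one recording (session).

    ``data`` has shape (n_channels, 3, n_samples) with chromophore axis
    (HbO, Hb, tHb) in micromolar; tHb equals HbO + Hb at every sample.
    """

    fs: float
    data: np.ndarray
    session: int = 0
    participant: str = "P0"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != len(CHROMOPHORES):
            raise OpticsError("data must be (n_channels, 3, n_samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self, atol: float = 1e-9) -> None:
        resid = np.abs(self.data[:, 2] - self.data[:, 0] - self.data[:, 1]).max()
        if resid > atol:
            raise OpticsError(f"tHb differs from HbO+Hb by up to {resid:.3g} uM")


@dataclass
class RawIntensityRecording:
    """Raw dual-wavelength optical intensities for one recording.

    ``data`` has shape (n_channels, 2, n_samples); wavelength axis matches
    ``wavelengths``. Intensities are strictly positive (arbitrary units).
    """

    fs: float
    data: np.ndarray
    wavelengths: tuple[float, float] = (690.0, 830.0)
    session: int = 0
    participant: str = "P0"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise OpticsError("data must be (n_channels, 2, n_samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise OpticsError("non-finite intensity values present")
        if np.any(self.data <= 0):
            ch, _, idx = np.unravel_index(np.argmin(self.data), self.data.shape)
            raise OpticsError(
                f"non-positive intensity at channel {ch}, sample {idx}"
            )


def intensity_to_od(intensity: np.ndarray, reference: np.ndarray | float) -> np.ndarray:
    """Optical density change: OD = -log10(I / I0).

    ``reference`` broadcasts against ``intensity`` (e.g. per-channel baseline
    means against a (n_channels, n_samples) block).
    """
    intensity = np.asarray(intensity, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(intensity <= 0):
        flat = np.argmin(intensity)
        idx = tuple(int(i) for i in np.unravel_index(flat, intensity.shape))
        raise OpticsError(f"non-positive intensity at index {idx}")
    if np.any(reference <= 0):
        raise OpticsError("non-positive reference intensity")
    return -np.log10(intensity / reference)


def mbll(od_low: np.ndarray, od_high: np.ndarray, optics: OpticsParameters) -> np.ndarray:
    """Invert the MBLL for the two-wavelength optical-density series.

    Parameters
    ----------
    od_low, od_high
        Optical-density series at the first and second wavelength of
        ``optics.wavelengths``; any matching shapes (e.g. (n_channels, n)).

    Returns
    -------
    ndarray with a new chromophore axis inserted before the last axis:
    (..., 3, n_samples) holding (d[HbO], d[Hb], d[tHb]) in micromolar.
    """
    od_low = np.asarray(od_low, dtype=float)
    od_high = np.asarray(od_high, dtype=float)
    if od_low.shape != od_high.shape:
        raise OpticsError("optical-density series shapes differ between wavelengths")
    eps = optics.extinction_matrix()
    # effective pathlength per wavelength (cm)
    L = optics.distance_cm * np.asarray(optics.dpf, dtype=float)
    A = eps * L[:, None]  # (wavelength, chromophore), OD per mM
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise OpticsError("extinction system is singular") from None
    od = np.stack([od_low, od_high], axis=-2)  # (..., 2, n)
    conc_mM = np.einsum("ij,...jn->...in", Ainv, od)
    conc_uM = conc_mM * 1e3
    thb = conc_uM.sum(axis=-2, keepdims=True)
    return np.concatenate([conc_uM, thb], axis=-2)


def convert_recording(
    raw: RawIntensityRecording,
    optics: OpticsParameters,
    schedule=None,
) -> HemodynamicRecording:
    """Full intensity -> concentration conversion for one recording.

    The reference intensity I0 per channel/wavelength is the mean intensity
    over each block's 30-s baseline, applied to that block's samples (the
    protocol guarantees one baseline per block). Without a schedule the mean
    over the whole recording is used.

    ``schedule`` is an events table restricted to this recording's session,
    with columns onset_s / duration_s / phase / block.
    """
    raw.validate()
    segments: list[tuple[slice, np.ndarray]] = []
    if schedule is not None:
        sched = schedule[schedule["session"] == raw.session] if "session" in schedule else schedule
        baselines = sched[sched["phase"] == "baseline"].sort_values("onset_s")
        if len(baselines) == 0:
            raise OpticsError("schedule contains no baseline phases")
        rows = list(baselines.itertuples())
        for i, row in enumerate(rows):
            b0 = int(round(row.onset_s * raw.fs))
            b1 = int(round((row.onset_s + row.duration_s) * raw.fs))
            start = b0
            end = int(round(rows[i + 1].onset_s * raw.fs)) if i + 1 < len(rows) else raw.n_samples
            i0 = raw.data[:, :, b0:b1].mean(axis=2, keepdims=True)
            segments.append((slice(start, end), i0))
    else:
        segments.append((slice(0, raw.n_samples), raw.data.mean(axis=2, keepdims=True)))

    out = np.empty((raw.n_channels, len(CHROMOPHORES), raw.n_samples), dtype=float)
    for sl, i0 in segments:
        od = intensity_to_od(raw.data[:, :, sl], i0)
        out[:, :, sl] = mbll(od[:, 0], od[:, 1], optics)
    return HemodynamicRecording(
        fs=raw.fs, data=out, session=raw.session, participant=raw.participant
    )
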