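"""Probe geometry: the source-detector trapezoid, channel derivation, and the
mapping of channels onto the topographic image grid.

A measurement channel ("point of interrogation") is a source-detector pair at
the prescribed separation; its midpoint localizes the measurement on the
forehead. The default geometry places 5 sources and 3 detectors so that
exactly 9 pairs sit at 3.0 cm, matching the headband montage used for
prefrontal recordings with 690/830 nm light.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np


class MontageError(ValueError):
    """Raised for inconsistent probe geometry."""


class Channel(NamedTuple):
    source: int
    detector: int
    midpoint: tuple[float, float]


#: Default 2-D probe coordinates (cm). Reconstructed so that exactly nine
#: source-detector pairs are separated by 3.0 cm; override via config/JSON if
#: the true optode coordinates are known.
DEFAULT_SOURCES = ((-6.0, 1.5), (-3.0, -1.5), (0.0, 1.5), (3.0, -1.5), (6.0, 1.5))
DEFAULT_DETECTORS = ((-3.0, 1.5), (0.0, -1.5), (3.0, 1.5))


@dataclass(frozen=True)
class Montage:
    """Optode layout with channels derived from the pairing distance.

    Parameters
    ----------
    sources, detectors
        2-D optode positions in cm.
    wavelengths
        The two optical wavelengths in nm (default 690, 830).
    pairing_distance
        Source-detector separation (cm) that defines a channel.
    """

    sources: tuple[tuple[float, float], ...] = DEFAULT_SOURCES
    detectors: tuple[tuple[float, float], ...] = DEFAULT_DETECTORS
    wavelengths: tuple[float, float] = (690.0, 830.0)
    pairing_distance: float = 3.0

    def __post_init__(self):
        if len(self.sources) == 0 or len(self.detectors) == 0:
            raise MontageError("montage requires at least one source and one detector")
        if len(self.wavelengths) != 2:
            raise MontageError("exactly two wavelengths are supported")

    @property
    def channels(self) -> list[Channel]:
        return derive_channels(self)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_midpoints(self) -> np.ndarray:
        """(n_channels, 2) array of channel midpoints in cm."""
        return np.array([c.midpoint for c in self.channels], dtype=float)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sources_cm": [list(s) for s in self.sources],
                "detectors_cm": [list(d) for d in self.detectors],
                "wavelengths_nm": list(self.wavelengths),
                "pairing_distance_cm": self.pairing_distance,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Montage":
        obj = json.loads(text)
        return cls(
            sources=tuple(tuple(s) for s in obj["sources_cm"]),
            detectors=tuple(tuple(d) for d in obj["detectors_cm"]),
            wavelengths=tuple(obj["wavelengths_nm"]),
            pairing_distance=float(obj["pairing_distance_cm"]),
        )


def derive_channels(montage: Montage, atol: float = 1e-9) -> list[Channel]:
    """All source-detector pairs separated by the pairing distance.

    Ordered by source index, then detector index. Raises
    :class:`MontageError` (reporting the full distance matrix) if no pair
    matches, which almost always indicates mis-specified coordinates.
    """
    src = np.asarray(montage.sources, dtype=float)
    det = np.asarray(montage.detectors, dtype=float)
    dist = np.linalg.norm(src[:, None, :] - det[None, :, :], axis=-1)
    channels = [
        Channel(si, di, tuple((src[si] + det[di]) / 2.0))
        for si in range(len(src))
        for di in range(len(det))
        if abs(dist[si, di] - montage.pairing_distance) <= atol
    ]
    if not channels:
        raise MontageError(
            f"no source-detector pair at {montage.pairing_distance} cm; "
            f"distance matrix:\n{np.array_str(dist, precision=3)}"
        )
    return channels


@dataclass(frozen=True)
class ImageGrid:
    """Trapezoidal pixel raster for the topographic image.

    Row 0 is the short parallel side (``top_width`` pixels); widths grow
    linearly to ``bottom_width`` on the last row. Pixels are addressed
    (row, col) 0-based within an ``n_rows x bottom_width`` rectangle; a pixel
    belongs to the trapezoid mask when its center lies inside (boundary
    inclusive).
    """

    n_rows: int = 21
    top_width: int = 21
    bottom_width: int = 61

    def __post_init__(self):
        if self.n_rows < 2 or self.top_width < 1 or self.bottom_width < self.top_width:
            raise MontageError("degenerate image grid")
        if (self.bottom_width - self.top_width) % 2:
            raise MontageError("top and bottom widths must share parity (centered trapezoid)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.bottom_width)

    @property
    def center_col(self) -> float:
        return (self.bottom_width - 1) / 2.0

    def half_width(self, row: np.ndarray | float) -> np.ndarray | float:
        """Half-width (in pixel units, center to boundary) of the mask at a row."""
        frac = np.asarray(row, dtype=float) / (self.n_rows - 1)
        return (self.top_width - 1) / 2.0 + frac * (self.bottom_width - self.top_width) / 2.0

    @property
    def mask(self) -> np.ndarray:
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.bottom_width]
        return np.abs(cols - self.center_col) <= self.half_width(rows) + 1e-12

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "top_width": self.top_width,
            "bottom_width": self.bottom_width,
        }


def map_channels_to_grid(montage: Montage, grid: ImageGrid) -> np.ndarray:
    """Map channel midpoints into (row, col) pixel coordinates.

    The channel-midpoint bounding trapezoid is normalized onto the pixel
    trapezoid: the narrow extreme of the layout lands on row 0 and the wide
    extreme on the last row, and each row's lateral extent is stretched to the
    mask's half-width at that row. The map is invariant to uniform scaling,
    translation, and reflection of the montage coordinates.

    Returns float (row, col) coordinates, one per channel, all inside the mask.
    """
    mid = montage.channel_midpoints()
    y, x = mid[:, 1], mid[:, 0]
    if np.ptp(y) <= 1e-12:
        raise MontageError("channel layout is collinear; cannot span the image grid")
    # lateral extent at the two y extremes; wide side goes to the bottom row
    ylo, yhi = y.min(), y.max()
    xc = x.mean()
    h_lo = np.abs(x[np.isclose(y, ylo)] - xc).max()
    h_hi = np.abs(x[np.isclose(y, yhi)] - xc).max()
    if max(h_lo, h_hi) <= 1e-12:
        raise MontageError("channel layout is collinear; cannot span the image grid")
    if h_lo > h_hi:  # narrow side must map to row 0
        ylo, yhi = yhi, ylo
        h_lo, h_hi = h_hi, h_lo
    v = (y - ylo) / (yhi - ylo)
    rows = v * (grid.n_rows - 1)
    h = h_lo + (h_hi - h_lo) * v
    h = np.where(h <= 1e-12, 1.0, h)
    cols = grid.center_col + (x - xc) / h * grid.half_width(rows)
    coords = np.column_stack([rows, cols])

    inside = np.abs(coords[:, 1] - grid.center_col) <= grid.half_width(coords[:, 0]) + 1e-9
    if not inside.all():
        raise MontageError(f"channels {np.where(~inside)[0].tolist()} map outside the grid mask")
    return coords
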