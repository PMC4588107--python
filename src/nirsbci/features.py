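"""Feature extraction: temporal slopes, trapezoidal topographies, and
discrete orthonormal Tchebichef image moments.

Three feature sets describe each 20-s task epoch:

* temporal (108): least-squares slope of each channel/chromophore series over
  the four growing windows 0-5, 0-10, 0-15, 0-20 s, with the time axis of
  each window normalized to [0, 1] so slopes are comparable across windows
  (4 windows x 3 chromophores x 9 channels);
* spatial (180): per-sample topographic images are built by cubic
  scattered-data interpolation of the 9 channel values over the trapezoidal
  pixel grid, summarized by the 15 orthonormal Tchebichef moments of order
  p+q <= 4, whose time courses are then reduced to the same normalized-window
  slopes (4 windows x 3 chromophores x 15 moments);
* combined (288): temporal followed by spatial.

Both interpolation and the moment transform are linear in the channel
values, so the extractor precomputes a single (15 x 9) channel-to-moment
operator and applies it to whole epochs at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator, NearestNDInterpolator

from .montage import ImageGrid, Montage, map_channels_to_grid
from .optics import CHROMOPHORES
from .preprocess import TrialEpoch

#: Analysis windows in seconds (start, end), all anchored at task onset.
WINDOWS = ((0.0, 5.0), (0.0, 10.0), (0.0, 15.0), (0.0, 20.0))

#: Moment orders (p, q) with p+q <= 4, ordered by total order then p.
MOMENT_ORDERS = tuple(
    (p, s - p) for s in range(5) for p in range(s + 1)
)

FEATURE_SETS = ("temporal", "spatial", "combined")


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureVector:
    """Ordered, named features of one epoch for one feature set."""

    set: str
    values: np.ndarray
    names: tuple[str, ...]
    epoch_key: tuple

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise FeatureError("values/names length mismatch")


def _epoch_key(epoch: TrialEpoch) -> tuple:
    return (epoch.participant, epoch.session, epoch.block, epoch.interval)


def _slope_weights(n: int) -> np.ndarray:
    """Weights w such that w @ y is the least-squares slope of y against the
    window's time axis normalized to [0, 1]."""
    t = np.linspace(0.0, 1.0, n)
    t = t - t.mean()
    return t / (t @ t)


def window_slopes(series: np.ndarray, fs: float) -> np.ndarray:
    """Normalized-window slopes of (..., n_samples) series.

    Returns (4, ...) with the leading axis over ``WINDOWS``.
    """
    series = np.asarray(series, dtype=float)
    out = []
    for (w0, w1) in WINDOWS:
        i0, i1 = int(round(w0 * fs)), int(round(w1 * fs))
        i1 = min(i1, series.shape[-1])
        if i1 - i0 < 2:
            raise FeatureError(f"window {w0}-{w1}s has <2 samples at fs={fs}")
        w = _slope_weights(i1 - i0)
        out.append(series[..., i0:i1] @ w)
    return np.stack(out)


def temporal_features(epoch: TrialEpoch) -> FeatureVector:
    """Per-window, per-chromophore, per-channel slopes (length 108 with the
    default 9-channel montage)."""
    if not np.all(np.isfinite(epoch.data)):
        raise FeatureError("epoch contains non-finite samples")
    slopes = window_slopes(epoch.data, epoch.fs)  # (4, ch, 3)
    n_ch = epoch.data.shape[0]
    values = np.transpose(slopes, (0, 2, 1)).reshape(-1)  # window, chrom, channel
    names = tuple(
        f"t|w0-{int(w1)}|{chrom}|ch{c}"
        for (_, w1) in WINDOWS
        for chrom in CHROMOPHORES
        for c in range(n_ch)
    )
    return FeatureVector("temporal", values, names, _epoch_key(epoch))


# ---------------------------------------------------------------------------
# Topographic interpolation and Tchebichef moments
# ---------------------------------------------------------------------------

def interpolate_topography(
    frame: np.ndarray,
    grid: ImageGrid,
    channel_coords: np.ndarray,
) -> np.ndarray:
    """Cubic scattered-data interpolation of 9 channel values onto the grid.

    Pixel centers inside the trapezoid mask get Clough-Tocher cubic
    interpolant values (exact at the channel positions and for planar
    fields); the rare boundary pixels outside the interpolant's hull fall
    back to nearest-channel values; pixels outside the mask are 0.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise FeatureError("non-finite channel values")
    coords = np.asarray(channel_coords, dtype=float)
    if len(frame) != len(coords):
        raise FeatureError("one value per channel required")
    pts = coords[:, ::-1]  # (col, row) as (x, y)
    mask = grid.mask
    rows, cols = np.nonzero(mask)
    pix = np.column_stack([cols, rows]).astype(float)
    interp = CloughTocher2DInterpolator(pts, frame, tol=1e-12)
    vals = interp(pix)
    nan = np.isnan(vals)
    if nan.any():
        vals[nan] = NearestNDInterpolator(pts, frame)(pix[nan])
    image = np.zeros(grid.shape)
    image[rows, cols] = vals
    return image


def tchebichef_polynomials(n_points: int, max_order: int) -> np.ndarray:
    """Orthonormal discrete Chebyshev (Tchebichef) polynomials on
    x = 0..n_points-1, rows 0..max_order; satisfies T @ T.T = I."""
    N = n_points
    if max_order >= N:
        raise FeatureError("polynomial order must be below the number of points")
    x = np.arange(N, dtype=float)
    T = np.zeros((max_order + 1, N))
    T[0] = 1.0 / np.sqrt(N)
    if max_order >= 1:
        T[1] = (2 * x + 1 - N) * np.sqrt(3.0 / (N * (N * N - 1)))
    for p in range(2, max_order + 1):
        c = np.sqrt((4 * p * p - 1.0) / (N * N - p * p))
        a1 = (2.0 / p) * c
        a2 = ((1.0 - N) / p) * c
        a3 = ((p - 1.0) / p) * np.sqrt((2.0 * p + 1) / (2.0 * p - 3)) * np.sqrt(
            (N * N - (p - 1.0) ** 2) / (N * N - p * p)
        )
        T[p] = (a1 * x + a2) * T[p - 1] - a3 * T[p - 2]
    return T


def tchebichef_moments(image: np.ndarray, max_order: int = 4) -> np.ndarray:
    """Orthonormal Tchebichef moments eta_pq = sum_xy t_p(row) t_q(col) f.

    Returns the 15 moments with p + q <= max_order, ordered by total order
    then p (see ``MOMENT_ORDERS``).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise FeatureError("image must be 2-D")
    Tr = tchebichef_polynomials(image.shape[0], max_order)
    Tc = tchebichef_polynomials(image.shape[1], max_order)
    full = Tr @ image @ Tc.T  # (p, q)
    return np.array([full[p, q] for p, q in MOMENT_ORDERS])


class SpatialFeatureExtractor:
    """Precomputed linear channel-to-moment operator for one montage/grid.

    Because both the Clough-Tocher interpolant and the moment transform are
    linear in the channel values, the composite map from a 9-channel frame to
    its 15 moments is a fixed (15 x 9) matrix, computed once from the unit
    basis frames.
    """

    def __init__(self, montage: Montage | None = None, grid: ImageGrid | None = None,
                 max_order: int = 4):
        self.montage = montage or Montage()
        self.grid = grid or ImageGrid()
        self.max_order = max_order
        self.channel_coords = map_channels_to_grid(self.montage, self.grid)
        n_ch = len(self.channel_coords)
        basis = np.empty((len(MOMENT_ORDERS), n_ch))
        for c in range(n_ch):
            e = np.zeros(n_ch)
            e[c] = 1.0
            img = interpolate_topography(e, self.grid, self.channel_coords)
            basis[:, c] = tchebichef_moments(img, max_order)
        self.channel_to_moments = basis

    def moment_series(self, epoch: TrialEpoch) -> np.ndarray:
        """(3, 15, n_samples) moment time courses of an epoch."""
        if epoch.data.shape[0] != self.channel_to_moments.shape[1]:
            raise FeatureError("epoch channel count does not match the extractor")
        return np.einsum("mc,ckn->kmn", self.channel_to_moments, epoch.data)

    def spatial_features(self, epoch: TrialEpoch) -> FeatureVector:
        """Normalized-window slopes of every moment series (length 180)."""
        if not np.all(np.isfinite(epoch.data)):
            raise FeatureError("epoch contains non-finite samples")
        series = self.moment_series(epoch)  # (3, 15, n)
        slopes = window_slopes(series, epoch.fs)  # (4, 3, 15)
        values = slopes.reshape(-1)
        names = tuple(
            f"s|w0-{int(w1)}|{chrom}|m{p}{q}"
            for (_, w1) in WINDOWS
            for chrom in CHROMOPHORES
            for (p, q) in MOMENT_ORDERS
        )
        return FeatureVector("spatial", values, names, _epoch_key(epoch))


def spatial_features(epoch: TrialEpoch, grid: ImageGrid | None = None,
                     montage: Montage | None = None) -> FeatureVector:
    """Convenience wrapper building a fresh extractor (prefer the class for
    batch work)."""
    return SpatialFeatureExtractor(montage, grid).spatial_features(epoch)


def combined_features(temporal: FeatureVector, spatial: FeatureVector) -> FeatureVector:
    """Concatenate the temporal and spatial sets of the same epoch."""
    if temporal.set != "temporal" or spatial.set != "spatial":
        raise FeatureError("expected one temporal and one spatial vector")
    if temporal.epoch_key != spatial.epoch_key:
        raise FeatureError(
            f"feature vectors come from different epochs: "
            f"{temporal.epoch_key} vs {spatial.epoch_key}"
        )
    return FeatureVector(
        "combined",
        np.concatenate([temporal.values, spatial.values]),
        temporal.names + spatial.names,
        temporal.epoch_key,
    )


@dataclass
class FeatureMatrix:
    """Stacked features for a list of epochs, one matrix per feature set."""

    X: dict  # set name -> (n_epochs, n_features) array
    names: dict  # set name -> tuple of feature names
    labels: "pd.DataFrame"

    def subset(self, tasks) -> "FeatureMatrix":
        import pandas as pd  # local to keep module import light

        keep = self.labels["task"].isin(tasks).to_numpy()
        return FeatureMatrix(
            X={k: v[keep] for k, v in self.X.items()},
            names=self.names,
            labels=self.labels.loc[keep].reset_index(drop=True),
        )


def extract_features(
    epochs: list[TrialEpoch],
    extractor: SpatialFeatureExtractor | None = None,
) -> FeatureMatrix:
    """Temporal, spatial, and combined feature matrices for a set of epochs."""
    import pandas as pd

    if not epochs:
        raise FeatureError("no epochs to extract features from")
    extractor = extractor or SpatialFeatureExtractor()
    rows_t, rows_s = [], []
    names_t = names_s = None
    for ep in epochs:
        ft = temporal_features(ep)
        fs_ = extractor.spatial_features(ep)
        rows_t.append(ft.values)
        rows_s.append(fs_.values)
        names_t, names_s = ft.names, fs_.names
    Xt = np.vstack(rows_t)
    Xs = np.vstack(rows_s)
    labels = pd.DataFrame({
        "participant": [e.participant for e in epochs],
        "session": [e.session for e in epochs],
        "block": [e.block for e in epochs],
        "interval": [e.interval for e in epochs],
        "task": [e.task for e in epochs],
    })
    return FeatureMatrix(
        X={"temporal": Xt, "spatial": Xs, "combined": np.hstack([Xt, Xs])},
        names={"temporal": names_t, "spatial": names_s,
               "combined": names_t + names_s},
        labels=labels,
    )
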