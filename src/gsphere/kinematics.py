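"""Static/dynamic acceleration separation, DBA power proxies and the unit
posture sphere.

Measured acceleration is the sum of a gravity-derived *static* component,
set by the tag's orientation, and a movement-derived *dynamic* component.
The static part is estimated with a centred running mean over a window of
about twice the period of the dominant stroking frequency; subtracting it
from the raw signal leaves the dynamic part, from which VeDBA and ODBA —
the standard linear proxies for metabolic power — are computed.
Normalising the static vector to unit length projects posture onto the
surface of a sphere (the g-sphere): radius 1, inclination measured from
the +y (heave, "North pole" = upright) axis, rotation in the x–z plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accel_io import AccelSeries

__all__ = [
    "StaticSeries",
    "DynamicSeries",
    "DBASeries",
    "UnitPostureSeries",
    "smooth_static",
    "suggest_window",
    "dynamic_component",
    "vedba",
    "odba",
    "power_metrics",
    "normalize_to_sphere",
]


@dataclass
class StaticSeries:
    """Smoothed (gravity/posture) acceleration per axis, in g."""

    sx: np.ndarray
    sy: np.ndarray
    sz: np.ndarray
    window_samples: int

    def __len__(self) -> int:
        return len(self.sx)

    def xyz(self) -> np.ndarray:
        return np.column_stack([self.sx, self.sy, self.sz])


@dataclass
class DynamicSeries:
    """Movement (raw minus static) acceleration per axis, in g."""

    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray

    def __len__(self) -> int:
        return len(self.dx)


@dataclass
class DBASeries:
    """Dynamic-body-acceleration power proxies, in g.

    ``vedba`` is the Euclidean norm of the dynamic vector; ``odba`` the sum
    of absolute components.  Elementwise, vedba <= odba <= sqrt(3)*vedba.
    """

    vedba: np.ndarray
    odba: np.ndarray

    def __len__(self) -> int:
        return len(self.vedba)


@dataclass
class UnitPostureSeries:
    """Static acceleration normalised onto the unit sphere.

    Samples whose pre-normalisation magnitude ``length_g`` falls below the
    exclusion threshold carry no unit vector (NaN) and are flagged in
    ``excluded``; the spherical radius of every retained sample is exactly 1.
    ``theta`` is inclination from the +y pole in radians, ``phi`` the
    rotation angle in the x–z plane (atan2(z, x)).
    """

    ux: np.ndarray
    uy: np.ndarray
    uz: np.ndarray
    length_g: np.ndarray
    excluded: np.ndarray
    theta: np.ndarray = field(default=None)  # type: ignore[assignment]
    phi: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.theta is None:
            with np.errstate(invalid="ignore"):
                self.theta = np.arccos(np.clip(self.uy, -1.0, 1.0))
                self.phi = np.arctan2(self.uz, self.ux)

    def __len__(self) -> int:
        return len(self.ux)

    @property
    def n_retained(self) -> int:
        return int(np.count_nonzero(~self.excluded))

    def unit_xyz(self) -> np.ndarray:
        """Retained unit vectors as an (n_retained, 3) array."""
        keep = ~self.excluded
        return np.column_stack([self.ux[keep], self.uy[keep], self.uz[keep]])


def _require_uniform(series: AccelSeries) -> None:
    if not series.is_uniform():
        raise ValueError(
            "smoothing requires uniform sampling (spacing jitter above 1% of the median); "
            "resample the trace externally"
        )


def smooth_static(series: AccelSeries, window_samples: int) -> StaticSeries:
    """Centred running mean per axis — the static (gravity) component.

    ``window_samples`` is the total span of the window.  Even spans are
    widened by one sample so the window is exactly centred.  At the trace
    boundaries the window shrinks to the samples in view (a true mean of
    what the window covers), so constant input yields identical constant
    output and the result stays aligned sample-for-sample with the input.
    """
    n = len(series)
    w = int(window_samples)
    if w < 1:
        raise ValueError("window_samples must be >= 1")
    if w > n:
        raise ValueError(f"window ({w}) longer than series ({n})")
    _require_uniform(series)
    half = w // 2  # even spans get a symmetric span of w+1
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    counts = (hi - lo).astype(float)

    def _run(x: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(x)])
        return (c[hi] - c[lo]) / counts

    return StaticSeries(_run(series.ax), _run(series.ay), _run(series.az), w)


def suggest_window(series: AccelSeries, dominant_period_s: float) -> int:
    """Smoothing span of about twice the dominant stroke period, in samples."""
    if dominant_period_s <= 0:
        raise ValueError("dominant_period_s must be positive")
    return max(1, int(round(2.0 * dominant_period_s * series.rate_hz)))


def dynamic_component(series: AccelSeries, static: StaticSeries) -> DynamicSeries:
    """Raw minus static, per axis; static + dynamic reconstructs raw to
    machine precision."""
    if len(series) != len(static):
        raise ValueError("series and static lengths differ")
    return DynamicSeries(series.ax - static.sx, series.ay - static.sy, series.az - static.sz)


def vedba(dyn: DynamicSeries) -> np.ndarray:
    """Vectorial dynamic body acceleration: Euclidean norm of (dx, dy, dz)."""
    return np.sqrt(dyn.dx**2 + dyn.dy**2 + dyn.dz**2)


def odba(dyn: DynamicSeries) -> np.ndarray:
    """Overall dynamic body acceleration: |dx| + |dy| + |dz|."""
    return np.abs(dyn.dx) + np.abs(dyn.dy) + np.abs(dyn.dz)


def power_metrics(dyn: DynamicSeries) -> DBASeries:
    return DBASeries(vedba=vedba(dyn), odba=odba(dyn))


def normalize_to_sphere(static: StaticSeries, min_length_g: float = 1e-6) -> UnitPostureSeries:
    """Project the static vector onto the unit sphere.

    Samples with magnitude below ``min_length_g`` (a tag in free fall, or a
    numerically degenerate smoothing output) have no defined posture; they
    are excluded, not raised.  Raises only when *no* sample survives.
    """
    sx, sy, sz = static.sx, static.sy, static.sz
    length = np.sqrt(sx**2 + sy**2 + sz**2)
    excluded = length < min_length_g
    if excluded.all():
        raise ValueError("no postural data: every static vector is below the length threshold")
    safe = np.where(excluded, 1.0, length)
    ux = np.where(excluded, np.nan, sx / safe)
    uy = np.where(excluded, np.nan, sy / safe)
    uz = np.where(excluded, np.nan, sz / safe)
    return UnitPostureSeries(ux=ux, uy=uy, uz=uz, length_g=length, excluded=excluded)
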