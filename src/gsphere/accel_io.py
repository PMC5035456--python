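"""Tri-axial accelerometer trace model and CSV input/output.

The axis convention is fixed throughout the package: the animal's surge
(anterior-posterior) axis is x, heave (dorso-ventral) is y and sway
(lateral) is z.  A trunk-mounted tag on an upright stationary subject
therefore reads approximately (0, 1, 0) g.

All acceleration is held internally in units of g; inputs recorded in
m/s^2 are converted on read (divide by 9.81).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AccelSeries", "CsvConfig", "read_accel_csv", "write_accel_csv", "n_measurements"]

#: standard gravity used for m/s^2 -> g conversion
G_MS2 = 9.81

#: column name used for behaviour-state tags on write
_LABEL_COL = "label"


@dataclass
class AccelSeries:
    """A uniformly (or near-uniformly) sampled tri-axial acceleration trace.

    Parameters
    ----------
    t : array of float
        Timestamps in seconds, strictly increasing.
    ax, ay, az : array of float
        Raw acceleration per body axis in g (surge, heave, sway).
    rate_hz : float
        Nominal sampling frequency.  If omitted it is inferred as
        1 / median(dt).
    attributes : dict of str -> array
        Optional auxiliary channels (e.g. ``depth`` in metres), one value
        per sample.
    labels : array of str, optional
        Per-sample behaviour-state tags (typically from the simulator).
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    rate_hz: float | None = None
    attributes: dict[str, np.ndarray] = field(default_factory=dict)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.t)
        if n < 1:
            raise ValueError("empty trace: need at least one sample")
        for name, arr in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if len(arr) != n:
                raise ValueError(f"channel {name} has length {len(arr)}, expected {n}")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("non-monotone timestamps: time must be strictly increasing")
        if self.rate_hz is None:
            if n < 2:
                raise ValueError("cannot infer sampling rate from a single sample")
            self.rate_hz = 1.0 / float(np.median(np.diff(self.t)))
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.attributes = {k: np.asarray(v, dtype=float) for k, v in self.attributes.items()}
        for k, v in self.attributes.items():
            if len(v) != n:
                raise ValueError(f"attribute {k!r} has length {len(v)}, expected {n}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def xyz(self) -> np.ndarray:
        """Raw samples as an (n, 3) array in (surge, heave, sway) order."""
        return np.column_stack([self.ax, self.ay, self.az])

    def is_uniform(self, jitter: float = 0.01) -> bool:
        """True when sample spacing deviates < ``jitter`` (relative) from its median."""
        if len(self) < 3:
            return True
        dt = np.diff(self.t)
        med = np.median(dt)
        return bool(np.max(np.abs(dt - med)) <= jitter * med)


@dataclass
class CsvConfig:
    """Column mapping for arbitrary logger CSV exports."""

    time_col: str = "time_s"
    x_col: str = "ax_g"
    y_col: str = "ay_g"
    z_col: str = "az_g"
    unit: str = "g"  # "g" or "ms2"
    attribute_cols: tuple[str, ...] = ()
    label_col: str | None = None


def read_accel_csv(path: str | Path, config: CsvConfig | None = None) -> AccelSeries:
    """Read a comma-separated, headered trace file into an :class:`AccelSeries`.

    Non-numeric rows are rejected with their 1-based file line numbers.
    The sampling rate is inferred from the median timestamp spacing, so
    mildly irregular logger output loads without preprocessing.
    """
    config = config or CsvConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"zero-length file: {path}")
    needed = [config.time_col, config.x_col, config.y_col, config.z_col, *config.attribute_cols]
    if config.label_col:
        needed.append(config.label_col)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"missing mapped column(s) {missing} in {path}; found {list(df.columns)}")

    numeric_cols = [c for c in needed if c != config.label_col]
    coerced = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1) & ~df[numeric_cols].isna().any(axis=1)
    bad |= df[numeric_cols].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise ValueError(f"non-numeric or missing values in {path} at line(s) {lines[:20]}")

    scale = 1.0 if config.unit == "g" else 1.0 / G_MS2
    if config.unit not in ("g", "ms2"):
        raise ValueError(f"unknown unit {config.unit!r}: expected 'g' or 'ms2'")
    attributes = {c: coerced[c].to_numpy() for c in config.attribute_cols}
    labels = df[config.label_col].astype(str).to_numpy() if config.label_col else None
    return AccelSeries(
        t=coerced[config.time_col].to_numpy(),
        ax=coerced[config.x_col].to_numpy() * scale,
        ay=coerced[config.y_col].to_numpy() * scale,
        az=coerced[config.z_col].to_numpy() * scale,
        attributes=attributes,
        labels=labels,
    )


def write_accel_csv(series: AccelSeries, path: str | Path) -> Path:
    """Write a trace to CSV so that a read round-trip reproduces every channel.

    Floats are printed with 17 significant digits (shortest exact
    representation territory), so read(write(s)) is bitwise-identical.
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "time_s": series.t,
        "ax_g": series.ax,
        "ay_g": series.ay,
        "az_g": series.az,
    }
    for k, v in series.attributes.items():
        cols[k] = v
    if series.labels is not None:
        cols[_LABEL_COL] = series.labels
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    return path


def n_measurements(duration_s: float, rate_hz: float, n_channels: int = 3) -> int:
    """Total scalar measurements in a deployment of the given length.

    A single day at 40 Hz across three axes already exceeds ten million
    values, which is why the facet-binned summaries exist.
    """
    return int(round(duration_s * rate_hz)) * n_channels
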