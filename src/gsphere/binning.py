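"""Per-facet statistics on the posture sphere: binning, normalisation,
differential sphere algebra and lifestyle curves.

A *g-sphere* holds, per tessellation facet: (i) the number of posture
samples intersecting it, (ii) the mean of each data channel over those
samples and (iii) a frequency distribution of one chosen attribute
(typically VeDBA) in fixed-width bins.  Counts and histograms can be
normalised globally (the whole sphere sums to 100%) or locally (each
populated facet's histogram sums to 100%), and two spheres built on the
same tessellation and bin layout can be differenced or summed facet- and
bin-wise to contrast individuals, periods or states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geodesic import GeodesicSphere, build_geodesic, locate_facet_many
from .kinematics import UnitPostureSeries

__all__ = [
    "GSphere",
    "LifestyleCurve",
    "bin_series",
    "normalize",
    "difference",
    "summation",
    "lifestyle_curve",
    "gsphere_to_json",
    "gsphere_from_json",
    "facet_table",
]

RAW, GLOBAL, PER_FACET = "raw", "global", "per_facet"


@dataclass
class GSphere:
    """Facet-binned summary of a posture trace on a geodesic tessellation.

    ``counts`` is in samples while ``normalization == 'raw'`` and in
    percent of retained samples afterwards.  ``hist`` rows are the
    per-facet attribute frequency distributions (samples, percent of the
    grand total, or percent per populated facet, depending on mode).
    Operation spheres produced by :func:`difference` carry the absolute
    values in ``counts``/``hist`` and the signed layers alongside.
    """

    sphere: GeodesicSphere
    counts: np.ndarray                    # (F,)
    hist: np.ndarray                      # (F, B)
    channel_means: dict[str, np.ndarray]  # per-facet means; NaN where empty
    n_bins: int
    bin_range: tuple[float, float]
    attribute: str = "VeDBA"
    normalization: str = RAW
    provenance: str = "data"              # "data" | "operation"
    n_samples: int = 0                    # retained samples behind a data sphere
    signed_counts: np.ndarray | None = None
    signed_hist: np.ndarray | None = None

    @property
    def n_facets(self) -> int:
        return self.sphere.n_facets

    @property
    def populated(self) -> np.ndarray:
        """Boolean mask of facets intersected by at least one sample."""
        if self.provenance == "data":
            return self.counts > 0
        return (self.counts != 0) | (np.abs(self.hist).sum(axis=1) != 0)

    def bin_edges(self) -> np.ndarray:
        lo, hi = self.bin_range
        return np.linspace(lo, hi, self.n_bins + 1)

    def compatible_with(self, other: "GSphere") -> bool:
        return (
            self.sphere.level == other.sphere.level
            and self.n_bins == other.n_bins
            and self.bin_range == other.bin_range
        )


@dataclass
class LifestyleCurve:
    """Cumulative time and DBA shares against sphere coverage.

    ``coverage_percent[k]`` is the percentage of all facets accounted for
    by the k most-occupied facets; ``time_percent`` and ``dba_percent``
    are the cumulative shares of samples and of total DBA (count x facet
    mean) carried by those facets.  Both curves start at 0 and end at 100.
    """

    coverage_percent: np.ndarray
    time_percent: np.ndarray
    dba_percent: np.ndarray
    label: str = ""


def bin_series(
    posture: UnitPostureSeries,
    attribute: np.ndarray,
    sphere: GeodesicSphere,
    n_bins: int = 20,
    bin_range: tuple[float, float] = (0.0, 4.0),
    attribute_name: str = "VeDBA",
) -> GSphere:
    """Bin a posture series into sphere facets (raw counts and histograms).

    Every retained sample increments exactly one facet's count,
    contributes to that facet's channel means, and lands in exactly one
    attribute bin.  Bins are half-open ``[lo + k*d, lo + (k+1)*d)``;
    values below ``lo`` clamp into bin 0 and values at or above ``hi``
    clamp into the last bin, so no sample is silently dropped.
    """
    attribute = np.asarray(attribute, dtype=float)
    if len(attribute) != len(posture):
        raise ValueError("attribute length must match posture length")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    lo, hi = float(bin_range[0]), float(bin_range[1])
    if not lo < hi:
        raise ValueError("bin_range must satisfy lo < hi")

    keep = ~posture.excluded
    n_kept = int(np.count_nonzero(keep))
    if n_kept == 0:
        raise ValueError("empty input: no samples survive posture exclusion")

    pts = np.column_stack([posture.ux[keep], posture.uy[keep], posture.uz[keep]])
    # smoothing can leave |u| a hair off 1; re-normalise before lookup
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    facet_ids = locate_facet_many(sphere, pts)

    f = sphere.n_facets
    counts = np.bincount(facet_ids, minlength=f).astype(float)

    vals = attribute[keep]
    width = (hi - lo) / n_bins
    bins = np.clip(np.floor((vals - lo) / width), 0, n_bins - 1).astype(np.int64)
    hist = np.bincount(facet_ids * n_bins + bins, minlength=f * n_bins).astype(float)
    hist = hist.reshape(f, n_bins)

    means: dict[str, np.ndarray] = {}
    safe = np.where(counts > 0, counts, 1.0)
    for name, channel in (("ux", pts[:, 0]), ("uy", pts[:, 1]), ("uz", pts[:, 2]),
                          (attribute_name, vals)):
        sums = np.bincount(facet_ids, weights=channel, minlength=f)
        means[name] = np.where(counts > 0, sums / safe, np.nan)

    return GSphere(sphere=sphere, counts=counts, hist=hist, channel_means=means,
                   n_bins=n_bins, bin_range=(lo, hi), attribute=attribute_name,
                   normalization=RAW, provenance="data", n_samples=n_kept)


def normalize(g: GSphere, mode: str = GLOBAL) -> GSphere:
    """Normalise a raw g-sphere to percentages.

    ``global``: counts and histogram mass become percentages of the total
    retained sample count, so the whole sphere sums to 100.
    ``per_facet``: each populated facet's histogram is rescaled to total
    100 on its own (empty facets keep all-zero histograms), making the
    DBA distribution of a rare posture as visible as that of a dominant
    one; the counts layer is still expressed as global percentages so the
    same sphere can drive a spherical histogram.
    """
    if mode not in (GLOBAL, PER_FACET):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if g.normalization != RAW:
        if g.normalization == mode:
            return replace(g)
        raise ValueError(
            f"sphere is already normalized ({g.normalization!r}); cannot re-normalize as {mode!r}"
        )
    total = g.counts.sum()
    if total <= 0:
        raise ValueError("cannot normalize an empty sphere")
    counts = g.counts * 100.0 / total
    if mode == GLOBAL:
        hist = g.hist * 100.0 / total
    else:
        facet_tot = g.hist.sum(axis=1, keepdims=True)
        hist = np.divide(g.hist * 100.0, facet_tot, out=np.zeros_like(g.hist),
                         where=facet_tot > 0)
    return replace(g, counts=counts, hist=hist, normalization=mode)


def _check_op_inputs(ga: GSphere, gb: GSphere) -> None:
    if not ga.compatible_with(gb):
        raise ValueError(
            "incompatible g-spheres: "
            f"tessellation level {ga.sphere.level} vs {gb.sphere.level}, "
            f"bins {ga.n_bins}@{ga.bin_range} vs {gb.n_bins}@{gb.bin_range}"
        )
    if ga.normalization == RAW or gb.normalization == RAW:
        raise ValueError("normalize both g-spheres before combining them "
                         "(percentages eradicate data-volume bias)")
    if ga.normalization != gb.normalization:
        raise ValueError(
            f"normalization modes differ: {ga.normalization!r} vs {gb.normalization!r}"
        )


def difference(ga: GSphere, gb: GSphere) -> GSphere:
    """Facet- and bin-wise absolute difference of two normalised g-spheres.

    The magnitude |GA - GB| is the primary layer; the signed difference
    GA - GB is stored alongside so a rendering can colour each facet/bin
    by which input was larger.  Symmetric in magnitude.
    """
    _check_op_inputs(ga, gb)
    signed_counts = ga.counts - gb.counts
    signed_hist = ga.hist - gb.hist
    means = {k: ga.channel_means[k] for k in ga.channel_means}
    return replace(
        ga,
        counts=np.abs(signed_counts),
        hist=np.abs(signed_hist),
        channel_means=means,
        provenance="operation",
        n_samples=0,
        signed_counts=signed_counts,
        signed_hist=signed_hist,
    )


def summation(ga: GSphere, gb: GSphere) -> GSphere:
    """Facet- and bin-wise sum of two normalised g-spheres (commutative)."""
    _check_op_inputs(ga, gb)
    return replace(
        ga,
        counts=ga.counts + gb.counts,
        hist=ga.hist + gb.hist,
        provenance="operation",
        n_samples=0,
        signed_counts=None,
        signed_hist=None,
    )


def lifestyle_curve(g: GSphere, label: str = "") -> LifestyleCurve:
    """Cumulative time/DBA allocation against percentage sphere coverage.

    Facets are ranked by occupancy (count, descending; ties by facet id);
    walking down that ranking, each step adds one facet's share of total
    samples and of total DBA (count x per-facet mean DBA).  Curves are
    monotone and end at 100; coverage ends at the occupied fraction of
    the sphere.
    """
    counts = g.counts
    if counts.sum() <= 0:
        raise ValueError("empty sphere: no occupied facets")
    mean_dba = np.nan_to_num(g.channel_means[g.attribute], nan=0.0)
    dba_mass = counts * mean_dba
    occupied = np.flatnonzero(counts > 0)
    order = occupied[np.lexsort((occupied, -counts[occupied]))]
    time_cum = np.concatenate([[0.0], np.cumsum(counts[order])]) * 100.0 / counts.sum()
    dba_total = dba_mass.sum()
    if dba_total > 0:
        dba_cum = np.concatenate([[0.0], np.cumsum(dba_mass[order])]) * 100.0 / dba_total
    else:
        dba_cum = time_cum.copy()
    coverage = np.arange(len(order) + 1) * 100.0 / g.n_facets
    return LifestyleCurve(coverage_percent=coverage, time_percent=time_cum,
                          dba_percent=dba_cum, label=label)


# ---------------------------------------------------------------------------
# serialization

def gsphere_to_json(g: GSphere, path: str | Path) -> Path:
    """Serialise a g-sphere to a documented JSON layout.

    The tessellation is stored by level only (its construction is
    deterministic); per-facet records are written sparsely for facets
    with any mass.
    """
    pop = np.flatnonzero(g.populated)
    records = []
    for fid in pop.tolist():
        rec = {
            "facet": fid,
            "count": g.counts[fid],
            "hist": g.hist[fid].tolist(),
            "means": {k: (None if np.isnan(v[fid]) else float(v[fid]))
                      for k, v in g.channel_means.items()},
        }
        if g.signed_counts is not None:
            rec["signed_count"] = g.signed_counts[fid]
            rec["signed_hist"] = g.signed_hist[fid].tolist()
        records.append(rec)
    payload = {
        "format": "gsphere-1",
        "level": g.sphere.level,
        "n_bins": g.n_bins,
        "bin_range": list(g.bin_range),
        "attribute": g.attribute,
        "normalization": g.normalization,
        "provenance": g.provenance,
        "n_samples": g.n_samples,
        "signed": g.signed_counts is not None,
        "facets": records,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def gsphere_from_json(path: str | Path, sphere: GeodesicSphere | None = None) -> GSphere:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "gsphere-1":
        raise ValueError(f"not a g-sphere file: {path}")
    level = payload["level"]
    if sphere is None:
        sphere = build_geodesic(level)
    elif sphere.level != level:
        raise ValueError(f"supplied tessellation level {sphere.level} != stored {level}")
    f, b = sphere.n_facets, payload["n_bins"]
    counts = np.zeros(f)
    hist = np.zeros((f, b))
    mean_keys = set()
    for rec in payload["facets"]:
        mean_keys.update(rec["means"])
    means = {k: np.full(f, np.nan) for k in mean_keys}
    signed = payload.get("signed", False)
    signed_counts = np.zeros(f) if signed else None
    signed_hist = np.zeros((f, b)) if signed else None
    for rec in payload["facets"]:
        fid = rec["facet"]
        counts[fid] = rec["count"]
        hist[fid] = rec["hist"]
        for k, v in rec["means"].items():
            if v is not None:
                means[k][fid] = v
        if signed:
            signed_counts[fid] = rec["signed_count"]
            signed_hist[fid] = rec["signed_hist"]
    return GSphere(sphere=sphere, counts=counts, hist=hist, channel_means=means,
                   n_bins=b, bin_range=tuple(payload["bin_range"]),
                   attribute=payload["attribute"], normalization=payload["normalization"],
                   provenance=payload["provenance"], n_samples=payload["n_samples"],
                   signed_counts=signed_counts, signed_hist=signed_hist)


def facet_table(g: GSphere) -> pd.DataFrame:
    """Populated facets as a tidy table (one row per facet, hist bins wide)."""
    pop = np.flatnonzero(g.populated)
    data = {"facet": pop, "count": g.counts[pop]}
    for k, v in g.channel_means.items():
        data[f"mean_{k}"] = v[pop]
    for j in range(g.n_bins):
        data[f"bin_{j}"] = g.hist[pop, j]
    return pd.DataFrame(data)
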