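"""Renderable scene construction for the five g-sphere visualizations.

Scenes are camera-independent geometry: point clouds (raw and spherical
plots), facet-normal prisms (the "Dubai" spherical histogram), spines of
stacked discs (the g-urchin) and 2-d lifestyle curves.  Construction is a
pure function of the data, so tests assert on geometry rather than
pixels; rendering backends (matplotlib PNG/SVG, OBJ or JSON export) sit
behind the scene objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .accel_io import AccelSeries
from .binning import GSphere, LifestyleCurve, RAW
from .kinematics import StaticSeries, UnitPostureSeries

__all__ = [
    "Scene", "Prism", "Disc", "Spine",
    "scene_raw", "scene_spherical", "scene_dubai", "scene_urchin",
    "plot_lifestyle", "scene_to_json", "render_scene_png",
]


@dataclass
class Prism:
    """Triangular prism extruded from a facet along its outward normal."""

    facet: int
    base: np.ndarray          # (3, 3) facet corner vertices
    direction: np.ndarray     # unit outward normal (facet-centre direction)
    length: float
    value: float              # normalized facet value driving the length
    color_value: float


@dataclass
class Disc:
    """One histogram-bin disc stacked on an urchin spine."""

    bin_index: int
    radial_position: float    # distance of disc centre from the origin
    thickness: float
    diameter: float
    frequency: float          # the bin's (normalized) frequency
    value: float              # the attribute value at the bin centre


@dataclass
class Spine:
    facet: int
    anchor: np.ndarray        # spine start (offset above the facet centre)
    direction: np.ndarray
    connector: np.ndarray     # (2, 3) line from facet centre to anchor
    discs: list[Disc]


@dataclass
class Scene:
    """Geometry primitives plus the metadata needed to interpret them."""

    kind: str
    points: np.ndarray | None = None            # (n, 3)
    point_colors: np.ndarray | None = None      # (n,)
    path: np.ndarray | None = None              # (m, 3) chronological polyline
    prisms: list[Prism] = field(default_factory=list)
    spines: list[Spine] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_primitives(self) -> int:
        n = 0 if self.points is None else len(self.points)
        return n + len(self.prisms) + len(self.spines)


def _colour_attr(n: int, colour_attr) -> np.ndarray | None:
    if colour_attr is None:
        return None
    c = np.asarray(colour_attr, dtype=float)
    if len(c) != n:
        raise ValueError(f"colour attribute length {len(c)} != {n} samples")
    return c


def scene_raw(series: AccelSeries | StaticSeries, colour_attr=None,
              with_path: bool = False) -> Scene:
    """Direct 3-d scatter of (smoothed or raw) acceleration, in g.

    Stationary data populate a shell of radius ~1 g; dynamic movement
    throws points off the shell.  ``colour_attr`` (e.g. VeDBA) is bound
    per point; ``with_path`` adds the chronological polyline.
    """
    pts = series.xyz()
    colors = _colour_attr(len(pts), colour_attr)
    return Scene(kind="raw", points=pts, point_colors=colors,
                 path=pts if with_path else None,
                 meta={"units": "g"})


def scene_spherical(posture: UnitPostureSeries, radius_attr=None,
                    radius_scale: float = 1.0, with_path: bool = False) -> Scene:
    """Posture points on the unit sphere, optionally radius-encoded.

    With ``radius_attr`` bound (e.g. dive depth), each point sits at
    radius 1 + radius_scale * attribute, a monotone map, so a zero
    attribute stays on the sphere surface.
    """
    keep = ~posture.excluded
    u = np.column_stack([posture.ux[keep], posture.uy[keep], posture.uz[keep]])
    if radius_attr is None:
        pts = u
        colors = None
    else:
        attr = np.asarray(radius_attr, dtype=float)
        if len(attr) != len(posture):
            raise ValueError(f"radius attribute length {len(attr)} != {len(posture)} samples")
        radius = 1.0 + radius_scale * attr[keep]
        pts = u * radius[:, None]
        colors = attr[keep]
    return Scene(kind="spherical", points=pts, point_colors=colors,
                 path=pts if with_path else None,
                 meta={"radius_attr": radius_attr is not None,
                       "radius_scale": radius_scale})


def scene_dubai(g: GSphere, max_length: float = 0.5) -> Scene:
    """Spherical histogram: one prism per populated facet.

    Prism length (and colour) is linearly proportional to the facet's
    normalized value, with the fullest facet drawn at ``max_length``
    sphere radii.  Facets without data get no prism.
    """
    if g.normalization == RAW:
        raise ValueError("dubai plot needs a normalized g-sphere")
    pop = np.flatnonzero(g.populated)
    top = float(np.max(np.abs(g.counts[pop]))) if len(pop) else 1.0
    prisms = []
    for fid in pop.tolist():
        value = float(g.counts[fid])
        prisms.append(Prism(
            facet=fid,
            base=g.sphere.facet_vertices(fid),
            direction=g.sphere.centers[fid],
            length=max_length * abs(value) / top if top > 0 else 0.0,
            value=value,
            color_value=value,
        ))
    return Scene(kind="dubai", prisms=prisms,
                 meta={"max_length": max_length, "normalization": g.normalization})


def scene_urchin(g: GSphere, spine_offset: float = 0.05,
                 spine_length: float = 0.5, max_disc_diameter: float = 0.12,
                 diameter_mode: str = "linear") -> Scene:
    """G-urchin: per-facet spines of stacked discs encoding DBA histograms.

    Each populated facet gets a spine along the facet normal, starting
    ``spine_offset`` radii above the surface (a connector line joins it
    to the facet centre).  Each non-empty histogram bin becomes a disc:
    radial position maps the bin's attribute value (low DBA near the
    surface), thickness is the bin width, diameter is proportional to the
    bin frequency (``diameter_mode='area'`` makes disc *area* the
    proportional quantity instead).
    """
    if g.normalization == RAW:
        raise ValueError("urchin plot needs normalized histograms (global or per_facet)")
    if diameter_mode not in ("linear", "area"):
        raise ValueError("diameter_mode must be 'linear' or 'area'")
    hist = np.abs(g.hist)
    if not np.any(hist > 0):
        raise ValueError("histograms absent: nothing to draw")
    pop = np.flatnonzero(hist.sum(axis=1) > 0)
    lo, hi = g.bin_range
    span = hi - lo
    bin_width_radial = spine_length / g.n_bins
    top_freq = float(hist[pop].max())
    spines = []
    for fid in pop.tolist():
        direction = g.sphere.centers[fid]
        anchor = direction * (1.0 + spine_offset)
        discs = []
        for j in np.flatnonzero(hist[fid] > 0).tolist():
            value = lo + (j + 0.5) * span / g.n_bins
            rel = hist[fid, j] / top_freq
            diameter = max_disc_diameter * (np.sqrt(rel) if diameter_mode == "area" else rel)
            discs.append(Disc(
                bin_index=j,
                radial_position=1.0 + spine_offset + (j + 0.5) * bin_width_radial,
                thickness=bin_width_radial,
                diameter=float(diameter),
                frequency=float(hist[fid, j]),
                value=float(value),
            ))
        spines.append(Spine(
            facet=fid, anchor=anchor, direction=direction,
            connector=np.vstack([direction, anchor]), discs=discs,
        ))
    return Scene(kind="urchin", spines=spines,
                 meta={"spine_offset": spine_offset, "spine_length": spine_length,
                       "diameter_mode": diameter_mode,
                       "normalization": g.normalization})


def plot_lifestyle(curves: list[LifestyleCurve], ax=None):
    """2-d lifestyle figure: DBA share solid, time share dashed, per curve.

    x is percentage sphere coverage; both axes span [0, 100].
    """
    if not curves:
        raise ValueError("need at least one lifestyle curve")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    cycle = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, c in enumerate(curves):
        col = cycle[i % len(cycle)]
        label = c.label or f"curve {i}"
        ax.plot(c.coverage_percent, c.dba_percent, "-", color=col, label=f"{label} (DBA)")
        ax.plot(c.coverage_percent, c.time_percent, "--", color=col, label=f"{label} (time)")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.set_xlabel("sphere coverage (% of facets)")
    ax.set_ylabel("cumulative share (%)")
    ax.legend(fontsize=8)
    return ax.figure


def scene_to_json(scene: Scene, path: str | Path) -> Path:
    """Dump the primitive list to JSON for external renderers."""
    def clean(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [clean(v) for v in obj]
        return obj

    payload = {
        "kind": scene.kind,
        "meta": clean(scene.meta),
        "points": clean(scene.points) if scene.points is not None else None,
        "point_colors": clean(scene.point_colors) if scene.point_colors is not None else None,
        "path": clean(scene.path) if scene.path is not None else None,
        "prisms": [clean(asdict(p)) for p in scene.prisms],
        "spines": [clean(asdict(s)) for s in scene.spines],
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def render_scene_png(scene: Scene, path: str | Path, dpi: int = 120) -> Path:
    """Quick static render (matplotlib 3-d) of any scene kind."""
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    if scene.points is not None:
        c = scene.point_colors
        ax.scatter(scene.points[:, 0], scene.points[:, 1], scene.points[:, 2],
                   s=2, c=c if c is not None else "steelblue", cmap="coolwarm")
    if scene.path is not None:
        ax.plot(scene.path[:, 0], scene.path[:, 1], scene.path[:, 2],
                lw=0.3, color="grey", alpha=0.5)
    for p in scene.prisms:
        centre = p.base.mean(axis=0)
        tip = centre + p.direction * p.length
        ax.plot(*np.column_stack([centre, tip]), lw=2, color="firebrick")
    for s in scene.spines:
        tip = s.anchor + s.direction * (max((d.radial_position for d in s.discs),
                                            default=1.0) - 1.0)
        ax.plot(*np.column_stack([s.connector[0], tip]), lw=0.8, color="k")
        for d in s.discs:
            pos = s.direction * d.radial_position
            ax.scatter(*pos, s=(40 * d.diameter / 0.12) ** 2 * 0.5 + 2,
                       c=[d.value], cmap="coolwarm", vmin=0, vmax=1)
    ax.set_box_aspect((1, 1, 1))
    for setter in (ax.set_xlim, ax.set_ylim, ax.set_zlim):
        setter(-1.6, 1.6)
    path = Path(path)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
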