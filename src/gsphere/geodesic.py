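"""Geodesic (subdivided-icosahedron) sphere tessellation and facet lookup.

Latitude/longitude grids tessellate the sphere into facets of wildly
unequal area, which biases any frequency representation.  A geodesic
sphere — an icosahedron whose triangular facets are repeatedly split in
four, with every new vertex projected back onto the unit sphere — gives a
close-to-uniform tessellation: 20 * 4^level facets, 10 * 4^level + 2
vertices, with only slight variation in facet size and shape.

The icosahedron is oriented with one vertex at the +y pole, so the
"North pole = normal upright posture" convention of the posture sphere
lands exactly on a vertex.

Point-to-facet assignment means finding the facet a unit vector
*intersects*, i.e. the spherical triangle containing it (a point exactly
on a shared edge or vertex belongs to the smallest facet id among the
tied facets).  Three independent routes compute that partition:

* :func:`locate_facet` — hierarchical descent through the subdivision
  tree: a small beam of candidate parents, their children scored by the
  cosine between the test vector and the facet-centre direction, then an
  exact point-in-spherical-triangle refinement over the winning leaf's
  vertex neighbourhood (the cosine winner and the containing facet can
  differ in a narrow band along facet boundaries);
* :func:`locate_facet_brute` — exhaustive containment scan over all
  leaf facets (the plain reference);
* :func:`locate_facet_winding` — the classical winding test: a point
  interior to a spherical triangle sees its vertices under angles that
  sum to 2*pi.  A second independent cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GeodesicSphere",
    "build_geodesic",
    "locate_facet",
    "locate_facet_many",
    "locate_facet_brute",
    "locate_facet_brute_many",
    "nearest_center_many",
    "locate_facet_winding",
    "locate_facet_winding_many",
    "facet_areas",
    "export_obj",
]

MAX_LEVEL = 7
_TIE_EPS = 1e-12   # cosine tie zone
_EDGE_EPS = 1e-12  # edge-plane determinant tolerance for containment
_BEAM = 3          # parents kept per level of the hierarchical descent


@dataclass
class GeodesicSphere:
    """Subdivided icosahedron with the full facet hierarchy retained.

    Facet ids are contiguous per level; the four children of facet ``k``
    at level ``l`` are facets ``4k .. 4k+3`` at level ``l+1``, so the
    hierarchy needs no explicit link table.
    """

    level: int
    vertices: np.ndarray                 # (V, 3) unit vectors, shared across levels
    faces_by_level: list = field(repr=False, default_factory=list)   # [(F_l, 3) int]
    centers_by_level: list = field(repr=False, default_factory=list)  # [(F_l, 3) unit]

    @property
    def faces(self) -> np.ndarray:
        """Leaf-level facets as vertex-index triples."""
        return self.faces_by_level[-1]

    @property
    def centers(self) -> np.ndarray:
        """Leaf-level facet-centre directions (unit vectors)."""
        return self.centers_by_level[-1]

    @property
    def n_facets(self) -> int:
        return len(self.faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def facet_vertices(self, facet_id: int) -> np.ndarray:
        """The three unit-sphere corners of a leaf facet, shape (3, 3)."""
        return self.vertices[self.faces[facet_id]]

    # --- lazily built leaf-level lookup tables -------------------------
    _edge_normals: np.ndarray | None = field(default=None, repr=False, compare=False)
    _neighborhood: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def edge_normals(self) -> np.ndarray:
        """(F, 3, 3) outward edge-plane normals of the leaf facets.

        A unit vector v lies inside facet f iff v . edge_normals[f, k] >= 0
        for all three edges (facets are wound so all determinants are
        positive for interior points).
        """
        if self._edge_normals is None:
            tri = self.vertices[self.faces]
            a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
            self._edge_normals = np.stack(
                [np.cross(a, b), np.cross(b, c), np.cross(c, a)], axis=1)
        return self._edge_normals

    @property
    def neighborhood(self) -> np.ndarray:
        """(F, K) leaf facets sharing at least one vertex with each facet
        (itself included), padded by repeating the facet's own id."""
        if self._neighborhood is None:
            vert_to_faces: dict[int, list[int]] = {}
            for fid, face in enumerate(self.faces):
                for vtx in face:
                    vert_to_faces.setdefault(int(vtx), []).append(fid)
            lists = []
            for fid, face in enumerate(self.faces):
                s: set[int] = set()
                for vtx in face:
                    s.update(vert_to_faces[int(vtx)])
                lists.append(sorted(s))
            k = max(len(s) for s in lists)
            neigh = np.empty((len(lists), k), dtype=np.int64)
            for fid, s in enumerate(lists):
                neigh[fid, : len(s)] = s
                neigh[fid, len(s) :] = fid
            self._neighborhood = neigh
        return self._neighborhood


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Unit icosahedron with a vertex at (0, 1, 0), outward-wound faces."""
    y = 1.0 / np.sqrt(5.0)
    r = 2.0 / np.sqrt(5.0)
    verts = [(0.0, 1.0, 0.0)]
    upper = 2.0 * np.pi * np.arange(5) / 5.0
    lower = upper + np.pi / 5.0
    verts += [(r * np.cos(a), y, r * np.sin(a)) for a in upper]
    verts += [(r * np.cos(a), -y, r * np.sin(a)) for a in lower]
    verts.append((0.0, -1.0, 0.0))
    v = np.array(verts)

    faces = []
    for i in range(5):
        j = (i + 1) % 5
        u0, u1 = 1 + i, 1 + j
        l0, l1 = 6 + i, 6 + j
        faces += [(0, u0, u1), (u0, l0, u1), (u1, l0, l1), (11, l1, l0)]
    f = np.array(faces)
    # enforce outward winding: det[a, b, c] > 0
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    flip = np.einsum("ij,ij->i", a, np.cross(b, c)) < 0
    f[flip] = f[flip][:, [0, 2, 1]]
    return v, f


def _face_centers(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    c = vertices[faces].mean(axis=1)
    return c / np.linalg.norm(c, axis=1, keepdims=True)


def build_geodesic(level: int) -> GeodesicSphere:
    """Subdivide an icosahedron ``level`` times, projecting midpoints outward.

    ``level`` is capped at 7 (327,680 facets) to guard against runaway
    memory from a typo'd argument.
    """
    if level < 0:
        raise ValueError("subdivision level must be non-negative")
    if level > MAX_LEVEL:
        raise ValueError(f"subdivision level {level} exceeds the guard of {MAX_LEVEL}")
    verts, faces = _icosahedron()
    vert_list = [tuple(v) for v in verts]
    faces_by_level = [faces]
    for _ in range(level):
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key not in midpoint_cache:
                m = np.array(vert_list[i]) + np.array(vert_list[j])
                m /= np.linalg.norm(m)
                midpoint_cache[key] = len(vert_list)
                vert_list.append(tuple(m))
            return midpoint_cache[key]

        children = np.empty((4 * len(faces), 3), dtype=faces.dtype)
        for k, (a, b, c) in enumerate(faces):
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            children[4 * k : 4 * k + 4] = [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
        faces = children
        faces_by_level.append(faces)

    vertices = np.array(vert_list)
    centers = [_face_centers(vertices, f) for f in faces_by_level]
    return GeodesicSphere(level=level, vertices=vertices,
                          faces_by_level=faces_by_level, centers_by_level=centers)


def _check_unit(v: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norms = np.linalg.norm(v, axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError("test vector(s) must be unit length within 1e-9")
    return v


def nearest_center_many(sphere: GeodesicSphere, v: np.ndarray) -> np.ndarray:
    """Leaf facet whose centre direction maximises the cosine with each
    vector (the raw smallest-angle rule; ties to the smallest id).

    This is the search heuristic, not the partition of record: near facet
    boundaries the nearest centre and the containing facet can differ.
    """
    v = _check_unit(v)
    cos = v @ sphere.centers.T
    best = cos.max(axis=1, keepdims=True)
    tied = cos >= best - _TIE_EPS
    ids = np.arange(sphere.n_facets)
    return np.where(tied, ids, sphere.n_facets).min(axis=1).astype(np.int64)


def locate_facet(sphere: GeodesicSphere, v: np.ndarray) -> int:
    """Facet id containing the unit vector ``v``, by hierarchical descent.

    At each level the children of a small beam of best-so-far parents are
    scored by the cosine between ``v`` and the facet-centre direction; at
    the leaf, an exact point-in-spherical-triangle test over the winner's
    vertex neighbourhood settles the boundary band where nearest-centre
    and containment disagree.  Points on an edge or vertex (determinant
    ties within 1e-12) break to the smallest facet id.
    """
    return int(locate_facet_many(sphere, _check_unit(v)[None, :])[0])


def locate_facet_many(sphere: GeodesicSphere, v: np.ndarray) -> np.ndarray:
    """Vectorised :func:`locate_facet` for an (n, 3) array of unit vectors."""
    v = _check_unit(v)
    n = len(v)
    cos = v @ sphere.centers_by_level[0].T                       # (n, 20)
    beam = np.argsort(-cos, axis=1)[:, :_BEAM]                   # (n, beam)
    for lvl in range(1, sphere.level + 1):
        cand = (4 * beam[:, :, None] + np.arange(4)).reshape(n, -1)   # (n, 4*beam)
        centers = sphere.centers_by_level[lvl][cand]                  # (n, 4*beam, 3)
        cos = np.einsum("nj,nkj->nk", v, centers)
        order = np.argsort(-cos, axis=1)[:, :_BEAM]
        beam = np.take_along_axis(cand, order, axis=1)
    return _refine_containment(sphere, v, beam[:, 0])


def _refine_containment(sphere: GeodesicSphere, v: np.ndarray,
                        best: np.ndarray) -> np.ndarray:
    """Exact containment among the vertex neighbourhood of ``best``."""
    cand = sphere.neighborhood[best]                             # (n, k)
    normals = sphere.edge_normals[cand]                          # (n, k, 3, 3)
    dets = np.einsum("nj,nkej->nke", v, normals)                 # (n, k, 3)
    inside = (dets >= -_EDGE_EPS).all(axis=2)
    pick = np.where(inside, cand, sphere.n_facets).min(axis=1)
    missed = pick == sphere.n_facets
    if np.any(missed):
        # numerically outside every candidate (deep-boundary sliver):
        # nearest-centre assignment among the candidates
        cos = np.einsum("nj,nkj->nk", v[missed], sphere.centers[cand[missed]])
        sub = np.take_along_axis(cand[missed], np.argmax(cos, axis=1)[:, None], axis=1)
        pick[missed] = sub[:, 0]
    return pick.astype(np.int64)


def locate_facet_brute(sphere: GeodesicSphere, v: np.ndarray) -> int:
    """Reference assignment: exhaustive containment scan over all leaf
    facets, ties (shared edges/vertices) to the smallest id."""
    return int(locate_facet_brute_many(sphere, _check_unit(v)[None, :])[0])


def locate_facet_brute_many(sphere: GeodesicSphere, v: np.ndarray) -> np.ndarray:
    v = _check_unit(v)
    out = np.empty(len(v), dtype=np.int64)
    normals = sphere.edge_normals                                 # (f, 3, 3)
    chunk = max(1, 4_000_000 // max(sphere.n_facets, 1))
    for lo in range(0, len(v), chunk):
        pts = v[lo : lo + chunk]
        dets = np.einsum("nj,fej->nfe", pts, normals)             # (n, f, 3)
        inside = (dets >= -_EDGE_EPS).all(axis=2)
        ids = np.where(inside, np.arange(sphere.n_facets), sphere.n_facets).min(axis=1)
        missed = ids == sphere.n_facets
        if np.any(missed):
            ids[missed] = nearest_center_many(sphere, pts[missed])
        out[lo : lo + chunk] = ids
    return out


def _winding_sums(points: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Sum of angles subtended at each point by consecutive facet vertices.

    Vertices are projected onto the tangent plane at the point; the three
    pairwise angles between the projections sum to 2*pi exactly when the
    point lies inside the spherical triangle.  Shapes: points (n, 3),
    a/b/c (f, 3); returns (n, f).
    """
    def project(x: np.ndarray) -> np.ndarray:
        d = points @ x.T                                  # (n, f)
        return x[None, :, :] - d[:, :, None] * points[:, None, :]

    pa, pb, pc = project(a), project(b), project(c)

    def angle(u: np.ndarray, w: np.ndarray) -> np.ndarray:
        cross = np.linalg.norm(np.cross(u, w), axis=-1)
        dot = np.einsum("nfj,nfj->nf", u, w)
        return np.arctan2(cross, dot)

    return angle(pa, pb) + angle(pb, pc) + angle(pc, pa)


def locate_facet_winding(sphere: GeodesicSphere, v: np.ndarray, tol: float = 1e-6) -> int:
    """Linear-scan winding assignment: the facet whose angle sum reaches 2*pi.

    Points exactly on a facet edge or vertex can fail the 2*pi test
    numerically; those fall back to the smallest-angle (centre cosine)
    assignment with a warning.
    """
    v = _check_unit(v)
    tri = sphere.vertices[sphere.faces]                   # (f, 3, 3)
    sums = _winding_sums(v[None, :], tri[:, 0], tri[:, 1], tri[:, 2])[0]
    # the facet antipodal to v also winds to 2*pi (seen "through" the
    # sphere); restrict the scan to the hemisphere facing v
    sums = np.where(sphere.centers @ v > 0, sums, 0.0)
    hits = np.flatnonzero(np.abs(sums - 2.0 * np.pi) < tol)
    if len(hits):
        return int(hits[0])
    warnings.warn("winding search found no facet (point on a boundary?); "
                  "falling back to the containment/nearest-centre reference")
    return locate_facet_brute(sphere, v)


def locate_facet_winding_many(sphere: GeodesicSphere, v: np.ndarray,
                              tol: float = 1e-6, chunk: int = 512) -> np.ndarray:
    """Vectorised winding assignment; boundary misses fall back silently
    to the smallest-angle rule (they are the tie zone by construction)."""
    v = _check_unit(v)
    tri = sphere.vertices[sphere.faces]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    out = np.empty(len(v), dtype=np.int64)
    for lo in range(0, len(v), chunk):
        pts = v[lo : lo + chunk]
        sums = _winding_sums(pts, a, b, c)
        sums = np.where(pts @ sphere.centers.T > 0, sums, 0.0)  # antipodal guard
        best = np.argmax(sums, axis=1)
        found = np.abs(np.take_along_axis(sums, best[:, None], axis=1)[:, 0] - 2 * np.pi) < tol
        ids = np.where(found, best, locate_facet_brute_many(sphere, pts))
        out[lo : lo + chunk] = ids
    return out


def facet_areas(sphere: GeodesicSphere) -> np.ndarray:
    """Spherical (solid-angle) area of every leaf facet, via the excess
    formula of Van Oosterom & Strackee; the areas sum to 4*pi."""
    tri = sphere.vertices[sphere.faces]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    num = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)))
    den = 1.0 + np.einsum("ij,ij->i", a, b) + np.einsum("ij,ij->i", b, c) + np.einsum("ij,ij->i", c, a)
    return 2.0 * np.arctan2(num, den)


def export_obj(sphere: GeodesicSphere, path: str | Path) -> Path:
    """Write the leaf tessellation as a Wavefront OBJ mesh (1-based faces)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# geodesic sphere, subdivision level {sphere.level}\n")
        for x, y, z in sphere.vertices:
            fh.write(f"v {x:.12g} {y:.12g} {z:.12g}\n")
        for a, b, c in sphere.faces:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")
    return path
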