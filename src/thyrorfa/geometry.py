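"""Layered neck phantom, RF needle electrode, and tetrahedral meshing.

The phantom is a rectangular block of stacked tissue layers (skin, fat,
muscle, thyroid along +y, measured from the skin surface at y = 0) with a
triaxial ellipsoidal nodule embedded at mid-thyroid depth and an 18-gauge
needle electrode inserted along +x, parallel to the XY plane, with its
active tip centered in the nodule.

Meshing strategy: a graded structured hexahedral grid whose planes are
snapped to every material interface that is axis-aligned (layer boundaries,
the square electrode channel, the active-tip extents), split into six
tetrahedra per hex (Kuhn split, conforming on structured grids).  Regions
are assigned per element from the element centroid.  Cell size grows
geometrically away from the electrode so the near-tip field is resolved
without an unstructured mesher.

The electrode conductor is represented as a square prism of side equal to
the 18-gauge outer diameter (1.27 mm), so that its boundary coincides with
grid planes; the distal `tip_length` of the prism is the active conductor,
the remainder to the +x domain face is the insulated shaft.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fem import tet_volumes

__all__ = [
    "GeometryError",
    "NeckPhantom",
    "ElectrodeSpec",
    "Mesh",
    "MeshOptions",
    "PRESETS",
    "build_phantom",
    "mesh_phantom",
    "region_volume",
    "structured_box_mesh",
    "spherical_shell_mesh",
]

REGIONS = ("skin", "fat", "muscle", "thyroid", "nodule", "tip", "shaft")
BOUNDARY_LABELS = ("skin_surface", "outer_ground", "tip_surface")

GAUGE_18_DIAMETER = 1.27e-3  # m, standard needle-gauge table


class GeometryError(ValueError):
    """Inconsistent phantom/electrode geometry."""


@dataclass(frozen=True)
class NeckPhantom:
    """Layered tissue block with an embedded ellipsoidal nodule.

    Lengths in meters.  ``layer_thicknesses`` maps region name to slab
    thickness along +y starting at the skin surface y = 0; tissue beyond the
    thyroid layer (up to ``domain_extent[1]``) is treated as deep muscle.
    """

    layer_thicknesses: dict = field(default_factory=lambda: {
        "skin": 1e-3, "fat": 6e-3, "muscle": 30e-3, "thyroid": 20e-3})
    nodule_semi_axes: tuple = (20e-3, 15.9e-3, 15e-3)
    nodule_center: tuple = (0.0, 47e-3, 0.0)
    domain_extent: tuple = (120e-3, 80e-3, 80e-3)

    @property
    def nodule_volume(self) -> float:
        a, b, c = self.nodule_semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    @property
    def layer_bounds(self) -> dict:
        """Region -> (y_lo, y_hi) of each slab."""
        out, y = {}, 0.0
        for name in ("skin", "fat", "muscle", "thyroid"):
            t = self.layer_thicknesses[name]
            out[name] = (y, y + t)
            y += t
        return out

    @property
    def bounds(self) -> np.ndarray:
        """(2,3) array of [min, max] domain corners."""
        ex, ey, ez = self.domain_extent
        return np.array([[-ex / 2, 0.0, -ez / 2], [ex / 2, ey, ez / 2]])

    def __post_init__(self):
        for name, t in self.layer_thicknesses.items():
            if t <= 0:
                raise GeometryError(f"layer {name!r} thickness must be positive")
        if min(self.nodule_semi_axes) <= 0:
            raise GeometryError("nodule semi-axes must be positive")
        lo, hi = self.layer_bounds["thyroid"]
        if not (lo < self.nodule_center[1] < hi):
            raise GeometryError("nodule center must lie inside the thyroid slab")
        bmin, bmax = self.bounds
        c = np.asarray(self.nodule_center)
        s = np.asarray(self.nodule_semi_axes)
        for ax, nm in enumerate("xyz"):
            if c[ax] - s[ax] < bmin[ax] or c[ax] + s[ax] > bmax[ax]:
                raise GeometryError(
                    f"nodule does not fit within the domain along {nm}")


@dataclass(frozen=True)
class ElectrodeSpec:
    """18-gauge needle electrode inserted along +x through the nodule center.

    The active tip is the distal ``tip_length`` of the conductor, centered on
    the nodule center; the shaft continues to the +x domain face.
    """

    tip_length: float = 10e-3
    outer_diameter: float = GAUGE_18_DIAMETER
    shaft_length: float = 100e-3
    insertion_axis: tuple = (1.0, 0.0, 0.0)
    tip_end_point: tuple = (-5e-3, 47e-3, 0.0)  # distal end of active tip

    def __post_init__(self):
        if not (0 < self.tip_length < self.shaft_length):
            raise GeometryError("require 0 < tip_length < shaft_length")
        if abs(self.insertion_axis[2]) > 1e-12:
            raise GeometryError("insertion axis must be parallel to the XY plane")

    @classmethod
    def centered_in(cls, phantom: NeckPhantom, tip_length: float,
                    **kw) -> "ElectrodeSpec":
        cx, cy, cz = phantom.nodule_center
        return cls(tip_length=tip_length,
                   tip_end_point=(cx - tip_length / 2, cy, cz), **kw)


@dataclass
class Mesh:
    """Labeled tetrahedral mesh.

    ``region`` holds per-tet indices into :data:`REGIONS`; ``boundary_tris``
    are the labeled facets with ``boundary_label`` indexing
    :data:`BOUNDARY_LABELS`.
    """

    nodes: np.ndarray          # (N,3) float
    tets: np.ndarray           # (M,4) int
    region: np.ndarray         # (M,) int
    boundary_tris: np.ndarray  # (B,3) int
    boundary_label: np.ndarray # (B,) int
    _vols: np.ndarray | None = None

    @property
    def volumes(self) -> np.ndarray:
        if self._vols is None:
            self._vols = tet_volumes(self.nodes, self.tets)
        return self._vols

    def region_mask(self, name: str) -> np.ndarray:
        if name not in REGIONS:
            raise KeyError(f"unknown region {name!r}")
        return self.region == REGIONS.index(name)

    def boundary_nodes(self, label: str) -> np.ndarray:
        if label not in BOUNDARY_LABELS:
            raise KeyError(f"unknown boundary label {label!r}")
        tris = self.boundary_tris[self.boundary_label
                                  == BOUNDARY_LABELS.index(label)]
        return np.unique(tris)


def build_phantom(nodule_volume: float = 20e-6,
                  nodule_shape: tuple = (20.0, 15.9, 15.0),
                  layer_thicknesses: dict | None = None,
                  domain_extent: tuple = (120e-3, 80e-3, 80e-3),
                  nodule_center: tuple | None = None) -> NeckPhantom:
    """Construct the layered phantom with a nodule of the requested volume.

    ``nodule_shape`` fixes the semi-axis ratios (long axis along the
    electrode); the axes are scaled together so the ellipsoid volume equals
    ``nodule_volume`` exactly.  Default volume 20 mL.
    """
    if nodule_volume <= 0:
        raise GeometryError("nodule volume must be positive")
    shape = np.asarray(nodule_shape, dtype=float)
    if np.min(shape) <= 0:
        raise GeometryError("nodule shape ratios must be positive")
    layers = dict(layer_thicknesses or {
        "skin": 1e-3, "fat": 6e-3, "muscle": 30e-3, "thyroid": 20e-3})
    if nodule_center is None:
        y0 = sum(layers[k] for k in ("skin", "fat", "muscle"))
        nodule_center = (0.0, y0 + layers["thyroid"] / 2, 0.0)
    unit_vol = 4.0 / 3.0 * np.pi * np.prod(shape)
    semi = tuple(shape * (nodule_volume / unit_vol) ** (1.0 / 3.0))
    return NeckPhantom(layer_thicknesses=layers, nodule_semi_axes=semi,
                       nodule_center=nodule_center, domain_extent=domain_extent)


# ---------------------------------------------------------------------------
# structured graded meshing


@dataclass(frozen=True)
class MeshOptions:
    """Grading parameters of the structured grid.

    ``h_min`` is the target edge near the electrode, ``h_max`` the edge at
    the outer boundary, ``growth`` the edge-length increase per unit
    distance from the refined region.
    """

    h_min: float
    h_max: float
    growth: float = 0.45


# Presets calibrated by element count: fine ~1e5 tets (the reference
# resolution), medium ~6e4, coarse ~3.5e4; "tiny" (~9e3) is a desk-scale
# preset for fast unit tests and optimizer sweeps.  Cells adjacent to the
# electrode channel are pinned at its 1.27 mm width by the snap planes.
PRESETS = {
    "tiny": MeshOptions(h_min=2.4e-3, h_max=18e-3, growth=1.0),
    "coarse": MeshOptions(h_min=1.5e-3, h_max=11e-3, growth=0.7),
    "medium": MeshOptions(h_min=1.15e-3, h_max=9.5e-3, growth=0.65),
    "fine": MeshOptions(h_min=0.9e-3, h_max=8e-3, growth=0.6),
}


def _graded_segment(a: float, b: float, hfun) -> np.ndarray:
    """Points in (a, b] stepped by the local target size ``hfun(t)``."""
    pts = [a]
    t = a
    guard = 0
    while t < b - 1e-12:
        t = t + max(float(hfun(t)), 1e-6)
        pts.append(min(t, b))
        guard += 1
        if guard > 100000:
            raise RuntimeError("grading failed to terminate")
    pts = np.asarray(pts)
    if len(pts) < 2:
        return np.asarray([a, b])
    # rescale so the last step lands exactly on b without a sliver cell
    return a + (pts - a) * (b - a) / (pts[-1] - a)


def _graded_axis(snaps, fine_lo, fine_hi, opts: MeshOptions) -> np.ndarray:
    """1D node coordinates honoring snap planes, graded away from
    [fine_lo, fine_hi]."""
    snaps = np.unique(np.asarray(snaps, dtype=float))

    def hfun(t):
        d = max(fine_lo - t, t - fine_hi, 0.0)
        return min(opts.h_min + opts.growth * d, opts.h_max)

    parts = [np.array([snaps[0]])]
    for a, b in zip(snaps[:-1], snaps[1:]):
        parts.append(_graded_segment(a, b, hfun)[1:])
    return np.concatenate(parts)


# Kuhn split of a hex into 6 tets sharing the main diagonal 000-111.
# Corner order used below: c[i,j,k] with bits (x,y,z).
_KUHN = [
    ((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)),
    ((0, 0, 0), (1, 1, 0), (0, 1, 0), (1, 1, 1)),
    ((0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 1, 1), (0, 0, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)),
    ((0, 0, 0), (1, 0, 1), (1, 0, 0), (1, 1, 1)),
]


def structured_box_mesh(xs, ys, zs):
    """Tensor-grid tetrahedral mesh of a box.

    Returns ``(nodes, tets)`` with positively oriented tets; the Kuhn split
    uses the same diagonal in every cell, hence is conforming.
    """
    xs, ys, zs = (np.asarray(v, dtype=float) for v in (xs, ys, zs))
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1),
                          np.arange(nz - 1), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    tets = np.empty((len(i) * 6, 4), dtype=np.int64)
    for t, corners in enumerate(_KUHN):
        ids = [nid(i + di, j + dj, k + dk) for (di, dj, dk) in corners]
        tets[t::6] = np.column_stack(ids)
    # fix orientation pattern-wise
    vols = tet_volumes(nodes, tets)
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    if np.any(tet_volumes(nodes, tets) <= 0):
        raise GeometryError("zero-volume element in structured grid")
    return nodes, tets


def _classify_regions(cent: np.ndarray, phantom: NeckPhantom,
                      electrode: ElectrodeSpec) -> np.ndarray:
    region = np.empty(cent.shape[0], dtype=np.int64)
    y = cent[:, 1]
    # deep tissue beyond the thyroid slab is labeled muscle
    region[:] = REGIONS.index("muscle")
    for name in ("skin", "fat", "muscle", "thyroid"):
        lo, hi = phantom.layer_bounds[name]
        region[(y >= lo) & (y < hi)] = REGIONS.index(name)
    c = np.asarray(phantom.nodule_center)
    s = np.asarray(phantom.nodule_semi_axes)
    in_nodule = (((cent - c) / s) ** 2).sum(axis=1) <= 1.0
    region[in_nodule] = REGIONS.index("nodule")
    # electrode: square prism around the insertion axis
    re = electrode.outer_diameter / 2
    x0 = electrode.tip_end_point[0]
    x1 = x0 + electrode.tip_length
    cy, cz = electrode.tip_end_point[1], electrode.tip_end_point[2]
    in_prism = (np.abs(cent[:, 1] - cy) < re) & (np.abs(cent[:, 2] - cz) < re)
    region[in_prism & (cent[:, 0] >= x0) & (cent[:, 0] < x1)] = REGIONS.index("tip")
    region[in_prism & (cent[:, 0] >= x1)] = REGIONS.index("shaft")
    return region


def _boundary_facets(nodes, tets, region, phantom) -> tuple[np.ndarray, np.ndarray]:
    """Exterior facets (skin surface vs grounded outer boundary) and the
    active-tip interface facets."""
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, local]                      # (M,4,3)
    flat = faces.reshape(-1, 3)
    keys = np.sort(flat, axis=1)
    order = np.lexsort(keys.T)
    ks = keys[order]
    new = np.ones(len(ks), dtype=bool)
    new[1:] = np.any(ks[1:] != ks[:-1], axis=1)
    grp = np.cumsum(new) - 1
    counts = np.bincount(grp)

    tip_code = REGIONS.index("tip")
    is_tip = np.repeat(region == tip_code, 4)    # per face slot

    tris, labels = [], []
    # exterior facets: singleton groups
    ext_slots = order[np.isin(grp, np.nonzero(counts == 1)[0])]
    ext = flat[ext_slots]
    ytol = 1e-9
    on_skin = np.all(np.abs(nodes[ext][:, :, 1]) < ytol, axis=1)
    tris.append(ext)
    lab = np.where(on_skin, BOUNDARY_LABELS.index("skin_surface"),
                   BOUNDARY_LABELS.index("outer_ground"))
    labels.append(lab)
    # tip interface facets: pair groups with one tip parent and one non-tip
    pair_groups = np.nonzero(counts == 2)[0]
    if pair_groups.size:
        first = np.searchsorted(grp, pair_groups, side="left")
        a, b = order[first], order[first + 1]
        mixed = is_tip[a] != is_tip[b]
        if np.any(mixed):
            tris.append(flat[np.where(is_tip[a], a, b)[mixed]])
            labels.append(np.full(int(mixed.sum()),
                                  BOUNDARY_LABELS.index("tip_surface")))
    return np.concatenate(tris), np.concatenate(labels)


def mesh_phantom(phantom: NeckPhantom, electrode: ElectrodeSpec,
                 resolution: str | MeshOptions = "coarse") -> Mesh:
    """Labeled graded tetrahedral mesh of phantom + electrode."""
    opts = PRESETS[resolution] if isinstance(resolution, str) else resolution
    bmin, bmax = phantom.bounds
    re = electrode.outer_diameter / 2
    x0 = electrode.tip_end_point[0]
    x1 = x0 + electrode.tip_length
    cy, cz = electrode.tip_end_point[1], electrode.tip_end_point[2]
    if not (bmin[0] < x0 and x1 < bmax[0]):
        raise GeometryError("electrode tip lies outside the domain along x")
    c = np.asarray(phantom.nodule_center)
    s = np.asarray(phantom.nodule_semi_axes)
    mid = np.array([(x0 + x1) / 2, cy, cz])
    if np.sum(((mid - c) / s) ** 2) > 1.0:
        raise GeometryError("electrode tip midpoint must lie inside the nodule")

    layer_snaps = sorted({b for lo_hi in phantom.layer_bounds.values()
                          for b in lo_hi})
    xs = _graded_axis([bmin[0], x0, x1, bmax[0]],
                      x0 - 2e-3, x1 + 2e-3, opts)
    ys = _graded_axis(layer_snaps + [cy - re, cy + re, bmax[1]],
                      cy - re - 2e-3, cy + re + 2e-3, opts)
    zs = _graded_axis([bmin[2], cz - re, cz + re, bmax[2]],
                      cz - re - 2e-3, cz + re + 2e-3, opts)
    nodes, tets = structured_box_mesh(xs, ys, zs)
    cent = nodes[tets].mean(axis=1)
    region = _classify_regions(cent, phantom, electrode)
    tris, labels = _boundary_facets(nodes, tets, region, phantom)
    return Mesh(nodes=nodes, tets=tets, region=region,
                boundary_tris=tris, boundary_label=labels)


def region_volume(mesh: Mesh, region: str) -> float:
    """Total volume (m^3) of all tets labeled ``region``."""
    return float(mesh.volumes[mesh.region_mask(region)].sum())


# ---------------------------------------------------------------------------
# cube-sphere shell mesh (verification geometry for the electric solver)


def spherical_shell_mesh(a: float, b: float, n_surf: int = 6,
                         n_rad: int = 12):
    """Conforming tet mesh of the spherical shell a <= r <= b.

    Cube-sphere surface grid (6 faces, ``n_surf`` cells per edge) extruded
    along geometrically graded radii; each hex is split into 24 tets through
    its cell and face centroids, which keeps the mesh conforming across the
    cube-face seams.  Returns ``(nodes, tets, inner_nodes, outer_nodes)``.
    """
    if not (0 < a < b):
        raise GeometryError("require 0 < a < b")
    # welded cube-surface directions
    u = np.linspace(-1, 1, n_surf + 1)
    pts = []
    for axis in range(3):
        for sign in (-1.0, 1.0):
            U, V = np.meshgrid(u, u, indexing="ij")
            P = np.zeros(U.shape + (3,))
            P[..., axis] = sign
            P[..., (axis + 1) % 3] = U
            P[..., (axis + 2) % 3] = V
            pts.append(P.reshape(-1, 3))
    pts = np.concatenate(pts)
    key = np.round(pts, 9)
    _, uniq_idx, inv = np.unique(key, axis=0, return_index=True,
                                 return_inverse=True)
    dirs = pts[uniq_idx]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    nsd = len(dirs)

    # surface quads in welded indexing
    quads = []
    off = 0
    m = n_surf + 1
    for _face in range(6):
        idx = inv[off:off + m * m].reshape(m, m)
        q = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]],
                     axis=-1).reshape(-1, 4)
        quads.append(q)
        off += m * m
    quads = np.concatenate(quads)

    radii = a * (b / a) ** (np.arange(n_rad + 1) / n_rad)
    shell_nodes = (radii[:, None, None] * dirs[None, :, :]).reshape(-1, 3)

    def sid(layer, d):
        return layer * nsd + d

    # hex corner lists per (layer, quad): inner quad then outer quad
    hexes = []
    for layer in range(n_rad):
        hexes.append(np.column_stack([
            sid(layer, quads[:, 0]), sid(layer, quads[:, 1]),
            sid(layer, quads[:, 2]), sid(layer, quads[:, 3]),
            sid(layer + 1, quads[:, 0]), sid(layer + 1, quads[:, 1]),
            sid(layer + 1, quads[:, 2]), sid(layer + 1, quads[:, 3])]))
    hexes = np.concatenate(hexes)

    nodes, tets = _split_hexes_24(shell_nodes, hexes)
    r = np.linalg.norm(nodes, axis=1)
    inner = np.nonzero(np.abs(r - a) < 1e-9 * b)[0]
    outer = np.nonzero(np.abs(r - b) < 1e-9 * b)[0]
    return nodes, tets, inner, outer


_HEX_FACES = np.array([
    [0, 1, 2, 3], [4, 5, 6, 7],
    [0, 1, 5, 4], [1, 2, 6, 5], [2, 3, 7, 6], [3, 0, 4, 7]])


def _split_hexes_24(nodes: np.ndarray, hexes: np.ndarray):
    """Split each hex into 24 tets via cell and face centroids (conforming
    for arbitrary, possibly non-structured hex meshes)."""
    nh = len(hexes)
    cell_c = nodes[hexes].mean(axis=1)
    face_nodes = hexes[:, _HEX_FACES]                  # (nh,6,4)
    face_c = nodes[face_nodes].mean(axis=2)            # (nh,6,3)
    fkey = np.round(face_c.reshape(-1, 3), 12)
    _, fi, finv = np.unique(fkey, axis=0, return_index=True,
                            return_inverse=True)
    n0 = len(nodes)
    all_nodes = np.concatenate([nodes, face_c.reshape(-1, 3)[fi], cell_c])
    face_id = (n0 + finv).reshape(nh, 6)
    cell_id = n0 + len(fi) + np.arange(nh)

    tets = []
    for f in range(6):
        fn = face_nodes[:, f]                          # (nh,4)
        fc = face_id[:, f]
        cc = cell_id
        for e in range(4):
            v0, v1 = fn[:, e], fn[:, (e + 1) % 4]
            tets.append(np.column_stack([v0, v1, fc, cc]))
    tets = np.concatenate(tets)
    vols = tet_volumes(all_nodes, tets)
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    vols = tet_volumes(all_nodes, tets)
    keep = vols > 1e-30
    return all_nodes, tets[keep]
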