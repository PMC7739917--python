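"""Voxelized sparse vascular domains and synthetic fixtures.

A flow domain is a dense voxel grid over the bounding box of the vessel
lumen.  Each voxel carries a site class (solid, bulk fluid, wall-adjacent
fluid, inlet, outlet) and, for boundary voxels, a patch id.  Inlet/outlet
patches are the "iolets" through which boundary conditions and the
artery-vein coupling act.

Coordinate convention: voxel indices are 0-based; the physical position of
voxel (i, j, k) is ``origin + (index + 0.5) * dx`` metres (centre-of-voxel
convention, matching halfway bounce-back which places walls half a spacing
beyond the last fluid voxel).

All fixture generators are deterministic: identical parameters (and seed,
where one applies) give identical domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import FixtureError, GeometryError, MappingError

__all__ = [
    "SOLID",
    "FLUID",
    "WALL_ADJ",
    "INLET",
    "OUTLET",
    "VoxelDomain",
    "BoundaryPatch",
    "identify_patches",
    "make_tube",
    "make_one_to_n_domain",
    "make_random_boundary_fixture",
    "make_bifurcating_tree",
    "write_domain",
    "read_domain",
]

SOLID, FLUID, WALL_ADJ, INLET, OUTLET = 0, 1, 2, 3, 4

_FLUID_CLASSES = (FLUID, WALL_ADJ, INLET, OUTLET)

# 26-connectivity structuring element, used both for wall-adjacency checks
# and for patch component labelling (avoids splitting oblique patches).
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BoundaryPatch:
    """One inlet or outlet: its voxels, geometry, and running flow means.

    ``normal`` is the unit vector pointing from the patch into the fluid.
    ``mean_v`` is the patch-average face-normal velocity in the natural
    flow direction (into the domain for inlets, out of it for outlets), so
    a forward-flowing patch reports a positive value for either kind.
    """

    id: int
    kind: str  # "inlet" | "outlet"
    sites: np.ndarray  # (n, 3) voxel indices
    centroid: np.ndarray  # (3,) metres, world frame
    normal: np.ndarray  # (3,) unit, into the fluid
    area: float  # m^2, voxel-face count * dx^2
    mean_v: float = 0.0  # m/s
    mean_P: float = 0.0  # Pa

    @property
    def mean_q(self) -> float:
        """Volumetric flow rate, area * mean_v (m^3/s)."""
        return self.area * self.mean_v

    @property
    def flow_dir(self) -> np.ndarray:
        """Unit vector of forward flow: +normal at inlets, -normal at outlets."""
        return self.normal if self.kind == "inlet" else -self.normal


@dataclass
class VoxelDomain:
    """A voxelized flow domain with classified sites and labelled patches."""

    site_class: np.ndarray  # uint8, shape (nx, ny, nz)
    dx: float  # lattice spacing, metres
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # metres
    patch_id: np.ndarray | None = None  # int32, -1 where no patch
    patches: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.site_class.shape

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.site_class != SOLID

    @property
    def n_fluid(self) -> int:
        return int(self.fluid_mask.sum())

    def patch(self, pid: int) -> BoundaryPatch:
        for p in self.patches:
            if p.id == pid:
                return p
        raise GeometryError(f"no patch with id {pid}")

    def patches_of_kind(self, kind: str) -> list:
        return [p for p in self.patches if p.kind == kind]


def _mark_wall_adjacent(site_class: np.ndarray) -> None:
    """Relabel bulk-fluid voxels that touch a solid voxel (26-neighbourhood)."""
    solid = site_class == SOLID
    near_solid = ndimage.binary_dilation(solid, structure=_CONN26)
    site_class[(site_class == FLUID) & near_solid] = WALL_ADJ


_AXIS_DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _patch_normal(site_class: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Inward unit normal of a planar boundary patch.

    Each patch site votes for the axis direction d with solid (or the array
    edge) behind it and fluid ahead of it; the winning direction is the
    normal.  Equivalent to the mean inward direction for the axis-aligned
    planar patches the fixtures produce, but immune to contamination from
    side walls at the patch rim.
    """
    shape = site_class.shape
    votes = np.zeros(len(_AXIS_DIRS))
    any_fluid_neighbour = False
    for di, d in enumerate(_AXIS_DIRS):
        ahead = sites + d
        behind = sites - d
        ok_a = np.all((ahead >= 0) & (ahead < shape), axis=1)
        ok_b = np.all((behind >= 0) & (behind < shape), axis=1)
        fluid_ahead = np.zeros(len(sites), dtype=bool)
        fluid_ahead[ok_a] = (
            site_class[tuple(ahead[ok_a].T)] != SOLID
        )
        solid_behind = ~ok_b
        solid_behind[ok_b] = site_class[tuple(behind[ok_b].T)] == SOLID
        votes[di] = np.sum(fluid_ahead & solid_behind)
        any_fluid_neighbour = any_fluid_neighbour or fluid_ahead.any()
    if not any_fluid_neighbour or votes.max() == 0:
        raise GeometryError("boundary patch has no interior fluid neighbour")
    return _AXIS_DIRS[int(votes.argmax())].astype(float)


def identify_patches(domain: VoxelDomain) -> list:
    """Label connected inlet/outlet components as patches.

    Components are found with 26-connectivity separately for each kind;
    patch ids are assigned deterministically (inlets first, then outlets,
    each in array scan order).  Writes ``domain.patch_id`` and
    ``domain.patches`` and returns the patch list.

    centroid = origin + (mean voxel index + 0.5) * dx
    area     = number of patch voxels * dx^2  (face counting)
    """
    sc = domain.site_class
    patch_id = np.full(sc.shape, -1, dtype=np.int32)
    patches: list[BoundaryPatch] = []
    next_id = 0
    for kind, cls in (("inlet", INLET), ("outlet", OUTLET)):
        labels, n = ndimage.label(sc == cls, structure=_CONN26)
        for lab in range(1, n + 1):
            sites = np.argwhere(labels == lab)
            normal = _patch_normal(sc, sites)
            centroid = domain.origin + (sites.mean(axis=0) + 0.5) * domain.dx
            patch_id[tuple(sites.T)] = next_id
            patches.append(
                BoundaryPatch(
                    id=next_id,
                    kind=kind,
                    sites=sites,
                    centroid=centroid,
                    normal=normal,
                    area=len(sites) * domain.dx**2,
                )
            )
            next_id += 1
    domain.patch_id = patch_id
    domain.patches = patches
    return patches


def _finalize(domain: VoxelDomain) -> VoxelDomain:
    _mark_wall_adjacent(domain.site_class)
    identify_patches(domain)
    return domain


def make_tube(
    radius: int,
    length: int,
    axis: str = "z",
    dx: float = 1.0,
    periodic: bool = False,
    origin=(0.0, 0.0, 0.0),
) -> VoxelDomain:
    """Axis-aligned voxel cylinder with an inlet and an outlet end.

    Parameters
    ----------
    radius, length : int
        Lumen radius and length in lattice sites; requires radius >= 3 and
        length >= 2 * radius.
    periodic : bool
        If True the tube has no end caps or patches and wraps along its
        axis (used for body-force-driven Poiseuille validation).

    Notes
    -----
    The lumen contains the voxel centres within radius + 1/2 of the axis
    (d^2 <= r^2 + r in integer arithmetic), so with halfway bounce-back the
    no-slip wall sits at R = radius + 1/2: the nominal, equal-area and
    hydrodynamic radii then all coincide, and the end-patch area is
    approximately pi (R dx)^2.
    """
    if radius < 3 or length < 2 * radius:
        raise FixtureError(
            f"degenerate tube (radius={radius}, length={length}); "
            "need radius >= 3 and length >= 2*radius"
        )
    side = 2 * radius + 3  # lumen + 1 solid pad each side
    c = radius + 1
    ii, jj = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    disc = (ii - c) ** 2 + (jj - c) ** 2 <= radius * (radius + 1)

    nz = length if periodic else length + 2
    sc = np.zeros((side, side, nz), dtype=np.uint8)
    if periodic:
        sc[disc, :] = FLUID
    else:
        sc[disc, 1 : length + 1] = FLUID
        inlet_layer, outlet_layer = 1, length
        sc[:, :, inlet_layer][disc] = INLET
        sc[:, :, outlet_layer][disc] = OUTLET

    if axis != "z":
        order = {"x": (2, 0, 1), "y": (0, 2, 1)}[axis]
        sc = np.transpose(sc, order)
    dom = VoxelDomain(site_class=sc, dx=dx, origin=np.asarray(origin, float))
    dom.meta = {"fixture": "tube", "radius": radius, "length": length, "axis": axis}
    return _finalize(dom)


def _carve_box(sc, x0, x1, y0, y1, z0, z1):
    sc[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] = FLUID


def make_one_to_n_domain(
    n: int, dx: float = 1.0, side: int = 7, channel_len: int = 40
) -> tuple:
    """Synthetic 1:N coupling test geometry (arterial tube + N-branch vein).

    The arterial domain is a single square channel with one inlet (top) and
    one outlet (bottom).  The venous domain sits below it in the world
    frame: n parallel inlet channels of equal square cross-section descend
    into a collecting plenum that drains through one outlet channel.  The
    arterial outlet is horizontally offset from the venous inlet row so
    every outlet-inlet centroid distance is distinct and nearest-neighbour
    mapping is unambiguous.

    Returns ``(arterial, venous)`` domains.
    """
    if not 1 <= n <= 8:
        raise FixtureError(f"branch count n={n} outside [1, 8]")
    s = side  # square channel side, sites
    gap = 4  # solid gap between venous channels

    # --- arterial: square channel along z, flowing +z (downwards in world)
    La = channel_len
    a_sc = np.zeros((s + 2, s + 2, La + 2), dtype=np.uint8)
    _carve_box(a_sc, 1, s, 1, s, 1, La)
    a_sc[1 : s + 1, 1 : s + 1, 1] = INLET
    a_sc[1 : s + 1, 1 : s + 1, La] = OUTLET

    # --- venous: n channels -> plenum -> single outlet channel
    W = 2 + n * s + (n - 1) * gap
    Lc = 24  # inlet channel length
    plen_h = 7  # plenum height
    Lout = 8  # outlet channel length
    Lv = Lc + plen_h + Lout
    v_sc = np.zeros((W, s + 2, Lv + 2), dtype=np.uint8)
    ch_x0 = [1 + k * (s + gap) for k in range(n)]
    for x0 in ch_x0:
        _carve_box(v_sc, x0, x0 + s - 1, 1, s, 1, Lc)
        v_sc[x0 : x0 + s, 1 : s + 1, 1] = INLET
    _carve_box(v_sc, 1, W - 2, 1, s, Lc + 1, Lc + plen_h)
    mid = ch_x0[n // 2]
    _carve_box(v_sc, mid, mid + s - 1, 1, s, Lc + plen_h + 1, Lv)
    v_sc[mid : mid + s, 1 : s + 1, Lv] = OUTLET

    # World placement: artery above, vein below, with the arterial channel
    # offset 1.7 sites left of venous channel 0 so L_1 < L_2 < ... strictly.
    gap_z = 5.0 * dx
    art_origin = np.array([(ch_x0[0] - 1 - 1.7) * dx, 0.0, 0.0])
    ven_origin = np.array([0.0, 0.0, (La + 2) * dx + gap_z])

    art = VoxelDomain(site_class=a_sc, dx=dx, origin=art_origin)
    art.meta = {"fixture": "one_to_n:arterial", "n": n}
    ven = VoxelDomain(site_class=v_sc, dx=dx, origin=ven_origin)
    ven.meta = {"fixture": "one_to_n:venous", "n": n}
    return _finalize(art), _finalize(ven)


def make_random_boundary_fixture(
    n_outlets: int, n_inlets: int, seed: int, area: float = 1.0, box: float = 1.0
) -> tuple:
    """Seeded random patch clouds standing in for large coupled trees.

    Produces ``n_outlets`` arterial-outlet and ``n_inlets`` venous-inlet
    patches with uniform random centroids in a cube of side ``box`` metres
    and equal areas, for exercising the coupling-map construction at
    realistic patch counts without building voxel geometry.
    """
    if n_outlets < 1:
        raise FixtureError("need at least one outlet")
    if n_inlets < n_outlets:
        raise MappingError(
            f"{n_inlets} inlets cannot cover {n_outlets} outlets (need >=)"
        )
    rng = np.random.default_rng(seed)
    dummy_sites = np.zeros((1, 3), dtype=int)
    ez = np.array([0.0, 0.0, 1.0])

    def mk(i, kind, c):
        return BoundaryPatch(
            id=i, kind=kind, sites=dummy_sites, centroid=c,
            normal=ez if kind == "inlet" else -ez, area=area,
        )

    outlets = [
        mk(i, "outlet", rng.uniform(0, box, 3)) for i in range(n_outlets)
    ]
    inlets = [
        mk(n_outlets + i, "inlet", rng.uniform(0, box, 3))
        for i in range(n_inlets)
    ]
    return outlets, inlets


def make_bifurcating_tree(dx: float = 1.0) -> VoxelDomain:
    """Three-generation bifurcating arterial tree for velocity-area analysis.

    A root square channel (9x9 sites) splits into two 7x7 daughters
    (offset in x) which each split into two 7x7 granddaughters (offset in
    y): 1 inlet, 4 outlets.  Total cross-sectional area grows distally
    (81 -> 98 -> 196 sites) as in real arterial trees, so by mass
    conservation the mean flow speed falls from root to leaves.  Junctions
    are short connector slabs spanning parent and daughter footprints; the
    segment extents are chosen so measurement planes at one-quarter,
    one-half and three-quarters of the domain length cut clean single-,
    double- and quadruple-vessel cross-sections.
    """
    s0, s1, s2 = 9, 7, 7
    X, Y, Z = 27, 23, 72
    sc = np.zeros((X, Y, Z), dtype=np.uint8)
    cx, cy = X // 2, Y // 2
    off1, off2 = 8, 7

    def box(cx_, cy_, s, z0, z1):
        h = s // 2
        _carve_box(sc, cx_ - h, cx_ + h, cy_ - h, cy_ + h, z0, z1)

    # generation 0: root
    z0a, z0b = 1, 26
    box(cx, cy, s0, z0a, z0b)
    # junction 0 -> 1: slab spanning root and both daughters
    h0, h1 = s0 // 2, s1 // 2
    _carve_box(sc, cx - off1 - h1, cx + off1 + h1, cy - h0, cy + h0, 24, 30)
    # generation 1: two daughters offset in x
    z1a, z1b = 27, 44
    h2 = s2 // 2
    for dxc in (-off1, off1):
        box(cx + dxc, cy, s1, z1a, z1b)
        # junction 1 -> 2: slab spanning daughter and its two children
        _carve_box(
            sc, cx + dxc - h1, cx + dxc + h1,
            cy - off2 - h2, cy + off2 + h2, 42, 48,
        )
    # generation 2: four leaves offset in x and y
    z2a, z2b = 45, 70
    for dxc in (-off1, off1):
        for dyc in (-off2, off2):
            box(cx + dxc, cy + dyc, s2, z2a, z2b)

    # patches: inlet on root top, outlets on leaf bottoms
    lay = sc[:, :, z0a]
    sc[:, :, z0a][(lay != SOLID)] = INLET
    lay = sc[:, :, z2b]
    sc[:, :, z2b][(lay != SOLID)] = OUTLET

    dom = VoxelDomain(site_class=sc, dx=dx)
    dom.meta = {"fixture": "bifurcating_tree", "generations": 3}
    return _finalize(dom)


# ---------------------------------------------------------------------------
# Geometry container I/O (HDF5)

_MAGIC = "vasclbm-geometry"
_VERSION = 1


def _write_domain_group(domain: VoxelDomain, h5) -> None:
    h5.attrs["dx"] = domain.dx
    h5.attrs["origin"] = domain.origin
    h5.attrs["shape"] = np.asarray(domain.shape)
    h5.create_dataset("site_class", data=domain.site_class)
    h5.create_dataset(
        "patch_id",
        data=domain.patch_id
        if domain.patch_id is not None
        else np.full(domain.shape, -1, np.int32),
    )
    g = h5.create_group("patches")
    for p in domain.patches:
        pg = g.create_group(str(p.id))
        pg.attrs["kind"] = p.kind
        pg.attrs["normal"] = p.normal
        pg.attrs["centroid"] = p.centroid
        pg.attrs["area"] = p.area
        pg.create_dataset("sites", data=p.sites)


def _read_domain_group(h5) -> VoxelDomain:
    dom = VoxelDomain(
        site_class=h5["site_class"][...],
        dx=float(h5.attrs["dx"]),
        origin=np.asarray(h5.attrs["origin"], float),
        patch_id=h5["patch_id"][...],
    )
    patches = []
    for key in sorted(h5["patches"], key=int):
        pg = h5["patches"][key]
        patches.append(
            BoundaryPatch(
                id=int(key),
                kind=str(pg.attrs["kind"]),
                sites=pg["sites"][...],
                centroid=np.asarray(pg.attrs["centroid"], float),
                normal=np.asarray(pg.attrs["normal"], float),
                area=float(pg.attrs["area"]),
            )
        )
    dom.patches = patches
    return dom


def write_domain(domain, path) -> None:
    """Write one domain — or a ``{name: domain}`` dict — to an HDF5 container.

    Layout: root attrs (magic, version); per domain the attrs dx, origin,
    shape plus datasets ``site_class`` (uint8) and ``patch_id`` (int32) and
    a ``patches`` group carrying id, kind, normal, centroid, area and the
    site list.  A dict input stores each domain under a named subgroup
    (e.g. ``arterial``/``venous`` for coupled pairs).  Round-trips
    bit-exactly.
    """
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["magic"] = _MAGIC
        h5.attrs["version"] = _VERSION
        if isinstance(domain, dict):
            for name, dom in domain.items():
                _write_domain_group(dom, h5.create_group(name))
        else:
            _write_domain_group(domain, h5)


def read_domain(path, group: str | None = None):
    """Read a container written by :func:`write_domain`.

    Returns a :class:`VoxelDomain` for single-domain containers (or when
    ``group`` selects one member), else a ``{name: VoxelDomain}`` dict.
    """
    import h5py

    with h5py.File(path, "r") as h5:
        if h5.attrs.get("magic") != _MAGIC:
            raise GeometryError(f"{path} is not a vasclbm geometry container")
        if "site_class" in h5:
            return _read_domain_group(h5)
        if group is not None:
            return _read_domain_group(h5[group])
        return {name: _read_domain_group(h5[name]) for name in h5}
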