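"""Flow-chamber geometry: coral shapes, graded Cartesian meshing, zone tagging.

The computational domain is a rectangular flow chamber (default
0.25 m x 0.05 m x 0.10 m, i.e. 25 cm long, 5 cm wide, 10 cm tall) with a
single idealised coral on the floor: a hemisphere for massive corals or a
vertical-axis cylinder for a branch section.  The mesh is a structured,
graded Cartesian grid: uniform fine cells in a window around the coral,
geometric stretching (ratio <= ``grading``) toward the far field.  Curved
coral surfaces are represented by stair-step zone tagging (a cell belongs to
the coral iff its centre lies inside the shape); the outermost shell of
coral cells, nominally ``tissue_thickness`` deep, is tagged as living tissue
and the interior as skeleton.

Axes: x = along-flow (length), y = lateral (width), z = vertical (height,
z=0 at the floor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# zone labels
FLUID = 0
TISSUE = 1
SKELETON = 2

ZONE_NAMES = {FLUID: "fluid", TISSUE: "tissue", SKELETON: "skeleton"}

#: boundary patch names (x-, x+, z-, z+, y- and y+ jointly)
PATCHES = ("inlet", "outlet", "bottom", "top", "sides")

HEMISPHERE = "hemisphere"
CYLINDER = "cylinder"


@dataclass(frozen=True)
class CoralShape:
    """Idealised coral: hemisphere (massive) or vertical cylinder (branch).

    Parameters
    ----------
    kind : {"hemisphere", "cylinder"}
    radius : float
        Radius r in metres (diameter d = 2r).
    height : float, optional
        Branch length z in metres; required for cylinders.
    tissue_thickness : float
        Depth of the living-tissue shell over the skeleton (m).  Default
        1 mm; real tissue occupies the outermost few millimetres.
    """

    kind: str
    radius: float
    height: float | None = None
    tissue_thickness: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.kind not in (HEMISPHERE, CYLINDER):
            raise ValueError(f"unknown coral kind {self.kind!r}")
        if not self.radius > 0:
            raise ValueError("coral radius must be positive")
        if self.kind == CYLINDER:
            if self.height is None or not self.height > 0:
                raise ValueError("cylinder requires a positive height")
        if not 0 < self.tissue_thickness < self.radius:
            raise ValueError("tissue thickness must lie in (0, radius)")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def extent_z(self) -> float:
        """Height of the shape above the floor."""
        return self.radius if self.kind == HEMISPHERE else float(self.height)


def surface_area(coral: CoralShape) -> float:
    """Total surface area (m^2).

    Hemisphere: curved cap plus basal disc, A = 2*pi*r^2 + pi*r^2 = 3*pi*r^2.
    Cylinder: lateral surface plus both end discs, A = 2*pi*r*z + 2*pi*r^2.
    """
    r = coral.radius
    if coral.kind == HEMISPHERE:
        return 3.0 * math.pi * r * r
    z = float(coral.height)
    return 2.0 * math.pi * r * z + 2.0 * math.pi * r * r


def volume(coral: CoralShape) -> float:
    """Solid volume (m^3): (2/3)*pi*r^3 for a hemisphere, pi*r^2*z for a cylinder."""
    r = coral.radius
    if coral.kind == HEMISPHERE:
        return (2.0 / 3.0) * math.pi * r**3
    return math.pi * r * r * float(coral.height)


def av_ratio(coral: CoralShape) -> float:
    """Surface-area-to-volume ratio S = A/V (m^-1).

    Reduces to 4.5/r for hemispheres and 2/r + 2/z for cylinders.  S controls
    how fast a coral accumulates and sheds heat: branches (large S) track the
    ambient temperature quickly, massive colonies (small S) lag behind.
    """
    v = volume(coral)
    if v == 0.0:
        raise ValueError("zero-volume coral")
    return surface_area(coral) / v


def projected_area(coral: CoralShape) -> float:
    """Horizontally projected (irradiated) area under an overhead beam (m^2)."""
    return math.pi * coral.radius**2


def exposed_area(coral: CoralShape) -> float:
    """Water-contacting (irradiable) surface area (m^2): excludes the base.

    Hemisphere: the curved cap 2*pi*r^2.  Cylinder standing on the floor:
    lateral surface plus the top disc, 2*pi*r*z + pi*r^2.
    """
    r = coral.radius
    if coral.kind == HEMISPHERE:
        return 2.0 * math.pi * r * r
    return 2.0 * math.pi * r * float(coral.height) + math.pi * r * r


@dataclass(frozen=True)
class ChamberDomain:
    """Rectangular flow chamber; defaults to the 25 x 5 x 10 cm validation chamber."""

    length: float = 0.25
    width: float = 0.05
    height: float = 0.10

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("chamber dimensions must be positive")


def _side_spacings(side: float, h0: float, ratio: float) -> list[float]:
    """Geometric spacings growing from h0*ratio that cover >= side."""
    if side <= 1e-12:
        return []
    spacings = []
    h = h0 * ratio
    total = 0.0
    while total < side:
        spacings.append(h)
        total += h
        h *= ratio
    return spacings


def graded_axis(
    length: float, window: tuple[float, float], n: int, ratio: float = 1.2
) -> np.ndarray:
    """Node positions of a graded 1-D grid on [0, length].

    Cells are uniform inside ``window`` and stretch geometrically (factor
    ``ratio`` per cell) outside it.  ``n`` is a target total cell count; the
    fine spacing is chosen by bisection so the actual count is as close to
    ``n`` as the grading permits (never above it by more than rounding).
    """
    a = max(0.0, window[0])
    b = min(length, window[1])
    if not 0 <= a < b <= length:
        raise ValueError("refinement window must intersect the axis")
    if n < 4:
        raise ValueError("need at least 4 cells per axis")
    if ratio < 1.0:
        raise ValueError("grading ratio must be >= 1")
    if a <= 1e-12 and b >= length - 1e-12:
        return np.linspace(0.0, length, n + 1)

    def count(hf: float) -> int:
        nf = max(1, int(math.ceil((b - a) / hf)))
        return (
            nf
            + len(_side_spacings(a, (b - a) / nf, ratio))
            + len(_side_spacings(length - b, (b - a) / nf, ratio))
        )

    lo, hi = (b - a) / (4 * n), length
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if count(mid) > n:
            lo = mid
        else:
            hi = mid
    hf = hi
    nf = max(1, int(math.ceil((b - a) / hf)))
    hf = (b - a) / nf

    def side_nodes(side: float, reverse: bool) -> np.ndarray:
        sp = np.array(_side_spacings(side, hf, ratio))
        if sp.size == 0:
            return np.array([])
        sp *= side / sp.sum()  # rescale to fit exactly; preserves ratios
        if reverse:
            sp = sp[::-1]
        return np.cumsum(sp)[:-1]

    left = side_nodes(a, reverse=True)
    right = b + np.concatenate([side_nodes(length - b, reverse=False), [length - b]])
    fine = a + hf * np.arange(nf + 1)
    nodes = np.concatenate([[0.0] if a > 1e-12 else [], left, fine, right if b < length - 1e-12 else []])
    nodes = np.unique(np.round(nodes, 12))
    nodes[0], nodes[-1] = 0.0, length
    return nodes


@dataclass
class Mesh:
    """Structured graded Cartesian mesh with per-cell zone labels.

    Cell (i, j, k) spans ``[xf[i], xf[i+1]] x [yf[j], yf[j+1]] x [zf[k], zf[k+1]]``.
    ``zone`` holds FLUID/TISSUE/SKELETON labels, shape (nx, ny, nz).
    """

    xf: np.ndarray
    yf: np.ndarray
    zf: np.ndarray
    zone: np.ndarray
    domain: ChamberDomain
    coral: CoralShape | None = None
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.xc = 0.5 * (self.xf[1:] + self.xf[:-1])
        self.yc = 0.5 * (self.yf[1:] + self.yf[:-1])
        self.zc = 0.5 * (self.zf[1:] + self.zf[:-1])
        self.dx = np.diff(self.xf)
        self.dy = np.diff(self.yf)
        self.dz = np.diff(self.zf)
        if self.zone.shape != self.shape:
            raise ValueError("zone array does not match grid shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return len(self.xc), len(self.yc), len(self.zc)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def cell_volumes(self) -> np.ndarray:
        return (
            self.dx[:, None, None] * self.dy[None, :, None] * self.dz[None, None, :]
        )

    def zone_volume(self, *labels: int) -> float:
        vol = self.cell_volumes()
        mask = np.isin(self.zone, labels)
        return float(vol[mask].sum())

    def coral_mask(self) -> np.ndarray:
        return self.zone != FLUID

    def surface_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """Coral cells with at least one fluid face.

        Returns (mask, weights) where weights are the exposed face areas
        (m^2), used for area-weighted surface averages.
        """
        coral = self.coral_mask()
        if not coral.any():
            raise ValueError("mesh has no coral cells")
        nx, ny, nz = self.shape
        ax = self.dy[None, :, None] * self.dz[None, None, :]
        ay = self.dx[:, None, None] * self.dz[None, None, :]
        az = self.dx[:, None, None] * self.dy[None, :, None]
        w = np.zeros(self.shape)
        c = coral
        w[1:][c[1:] & ~c[:-1]] += np.broadcast_to(ax, self.shape)[1:][c[1:] & ~c[:-1]]
        w[:-1][c[:-1] & ~c[1:]] += np.broadcast_to(ax, self.shape)[:-1][c[:-1] & ~c[1:]]
        w[:, 1:][c[:, 1:] & ~c[:, :-1]] += np.broadcast_to(ay, self.shape)[:, 1:][c[:, 1:] & ~c[:, :-1]]
        w[:, :-1][c[:, :-1] & ~c[:, 1:]] += np.broadcast_to(ay, self.shape)[:, :-1][c[:, :-1] & ~c[:, 1:]]
        w[:, :, 1:][c[:, :, 1:] & ~c[:, :, :-1]] += np.broadcast_to(az, self.shape)[:, :, 1:][c[:, :, 1:] & ~c[:, :, :-1]]
        w[:, :, :-1][c[:, :, :-1] & ~c[:, :, 1:]] += np.broadcast_to(az, self.shape)[:, :, :-1][c[:, :, :-1] & ~c[:, :, 1:]]
        # top-of-domain / boundary-adjacent coral cells: count the exposed
        # outer face only when the coral touches the top (never in practice)
        mask = w > 0
        return mask, w

    def column_top_coral(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Indices (i, j, k) of the topmost coral cell in each column that has one."""
        coral = self.coral_mask()
        has = coral.any(axis=2)
        ii, jj = np.nonzero(has)
        nz = self.shape[2]
        kk = nz - 1 - np.argmax(coral[ii, jj, ::-1], axis=1)
        return ii, jj, kk

    def fine_spacing(self) -> float:
        """Max cell width (any axis) among coral-containing cells."""
        coral = self.coral_mask()
        if not coral.any():
            return float(max(self.dx.max(), self.dy.max(), self.dz.max()))
        i, j, k = np.nonzero(coral)
        return float(
            max(self.dx[i].max(), self.dy[j].max(), self.dz[k].max())
        )


def build_empty_mesh(domain: ChamberDomain, resolution: tuple[int, int, int]) -> Mesh:
    """Uniform mesh of the bare chamber (no coral); used for oracle cases."""
    nx, ny, nz = resolution
    zone = np.zeros(resolution, dtype=np.int8)
    return Mesh(
        np.linspace(0.0, domain.length, nx + 1),
        np.linspace(0.0, domain.width, ny + 1),
        np.linspace(0.0, domain.height, nz + 1),
        zone,
        domain,
    )


def build_mesh(
    domain: ChamberDomain,
    coral: CoralShape,
    resolution: tuple[int, int, int],
    grading: float = 1.2,
    upstream_frac: float = 0.4,
    margin: float | None = None,
) -> Mesh:
    """Mesh the chamber with local refinement around the coral.

    The coral sits on the floor, centred laterally, with its upstream edge at
    ``upstream_frac`` of the chamber length.  ``resolution`` is the target
    cell-count triple (nx, ny, nz).  The fine spacing near the coral must
    resolve at least 8 cells across the coral diameter and must not exceed
    twice the tissue thickness (else the tissue shell is unresolved); too
    coarse a resolution is rejected.
    """
    r, t = coral.radius, coral.tissue_thickness
    cx = upstream_frac * domain.length + r
    cy = 0.5 * domain.width
    if cx + r > domain.length or 2 * r > domain.width or coral.extent_z > domain.height:
        raise ValueError("coral does not fit inside the chamber")
    if margin is None:
        margin = max(0.15 * coral.diameter, 1.5e-3)

    xfn = graded_axis(domain.length, (cx - r - margin, cx + r + margin), resolution[0], grading)
    yfn = graded_axis(domain.width, (cy - r - margin, cy + r + margin), resolution[1], grading)
    zfn = graded_axis(domain.height, (0.0, coral.extent_z + margin), resolution[2], grading)

    xc = 0.5 * (xfn[1:] + xfn[:-1])
    yc = 0.5 * (yfn[1:] + yfn[:-1])
    zc = 0.5 * (zfn[1:] + zfn[:-1])
    X = xc[:, None, None] - cx
    Y = yc[None, :, None] - cy
    Z = zc[None, None, :]

    if coral.kind == HEMISPHERE:
        rho = np.sqrt(X**2 + Y**2 + Z**2)
        inside = rho <= r
        tissue = inside & (rho >= r - t)
    else:
        rad = np.sqrt(X**2 + Y**2 + 0.0 * Z)
        zh = float(coral.height)
        inside = (rad <= r) & (Z <= zh)
        tissue = inside & ((rad >= r - t) | (Z >= zh - t))

    zone = np.zeros(inside.shape, dtype=np.int8)
    zone[inside] = SKELETON
    zone[tissue] = TISSUE
    # the living tissue covers the whole surface: promote any coral cell
    # whose centre sits deeper than the nominal shell but which still faces
    # water (stair-step corners on coarse grids)
    fluid_adjacent = np.zeros_like(inside)
    c = inside
    fluid_adjacent[1:] |= ~c[:-1]
    fluid_adjacent[:-1] |= ~c[1:]
    fluid_adjacent[:, 1:] |= ~c[:, :-1]
    fluid_adjacent[:, :-1] |= ~c[:, 1:]
    fluid_adjacent[:, :, 1:] |= ~c[:, :, :-1]
    fluid_adjacent[:, :, :-1] |= ~c[:, :, 1:]
    zone[inside & fluid_adjacent & (zone == SKELETON)] = TISSUE
    mesh = Mesh(xfn, yfn, zfn, zone, domain, coral, (cx, cy))

    if not inside.any():
        raise ValueError("resolution too coarse: no cell centre falls inside the coral")
    hf = mesh.fine_spacing()
    if hf > coral.diameter / 8 + 1e-12:
        raise ValueError(
            f"resolution too coarse: near-coral spacing {hf:.4g} m exceeds d/8 "
            f"= {coral.diameter / 8:.4g} m"
        )
    if hf > 2.0 * t + 1e-12:
        raise ValueError(
            f"resolution too coarse to resolve the {t * 1e3:.1f} mm tissue shell "
            f"(near-coral spacing {hf * 1e3:.2f} mm > 2x tissue thickness)"
        )
    return mesh
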