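"""Arena geometry, region partitions, and wall-collision handling.

The simulation works in dimensionless "sim-units" at a fixed scale of
14/3 units per millimetre (a 30 mm rectangle side is 140 units).  Four
arena kinds are supported: a rectangle, a circle, a donut (annulus
between an inner convex wall and an outer concave wall), and an
unbounded open field.  All arenas are centered at the origin.

Bearings follow the compass convention used by the motion model: 0 rad
points along +y and angles increase clockwise, so a unit step with
heading ``theta`` is ``(sin theta, cos theta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

import numpy as np

#: millimetres per simulation unit (140 units == 30 mm).
MM_PER_UNIT = 3.0 / 14.0
#: simulation units per millimetre.
UNITS_PER_MM = 14.0 / 3.0

TWO_PI = 2.0 * math.pi


def wrap_angle(a: float) -> float:
    """Wrap an angle difference into (-pi, pi]."""
    a = math.fmod(a, TWO_PI)
    if a > math.pi:
        a -= TWO_PI
    elif a <= -math.pi:
        a += TWO_PI
    return a


class FieldKind(str, Enum):
    RECTANGLE = "rectangle"
    CIRCLE = "circle"
    DONUT = "donut"
    OPEN = "open"


class Region(str, Enum):
    WALL = "wall"
    CENTRAL = "central"
    MIDDLE = "middle"
    CONVEX = "convex"
    CONCAVE = "concave"
    OUTSIDE = "outside"


@dataclass(frozen=True)
class FieldGeometry:
    """A validated arena geometry in simulation units.

    Parameters
    ----------
    kind
        One of rectangle / circle / donut / open.
    width, height
        Rectangle side lengths (sim-units).
    radius
        Circle radius (sim-units).
    inner_radius, outer_radius
        Donut wall radii (sim-units); inner < outer.
    """

    kind: FieldKind
    width: Optional[float] = None
    height: Optional[float] = None
    radius: Optional[float] = None
    inner_radius: Optional[float] = None
    outer_radius: Optional[float] = None
    mm_per_unit: float = MM_PER_UNIT

    def __post_init__(self) -> None:
        k = self.kind
        if k is FieldKind.RECTANGLE:
            if not (self.width and self.height and self.width > 0 and self.height > 0):
                raise ValueError("rectangle requires positive width and height")
        elif k is FieldKind.CIRCLE:
            if not (self.radius and self.radius > 0):
                raise ValueError("circle requires a positive radius")
        elif k is FieldKind.DONUT:
            if not (self.inner_radius and self.outer_radius):
                raise ValueError("donut requires inner_radius and outer_radius")
            if not (0 < self.inner_radius < self.outer_radius):
                raise ValueError("donut requires 0 < inner_radius < outer_radius")
        elif k is FieldKind.OPEN:
            if any(
                v is not None
                for v in (self.width, self.height, self.radius, self.inner_radius, self.outer_radius)
            ):
                raise ValueError("open field takes no dimensions")
        else:  # pragma: no cover - enum exhausts kinds
            raise ValueError(f"unknown field kind {k!r}")

    # -- basic geometry ------------------------------------------------

    @property
    def bounded(self) -> bool:
        return self.kind is not FieldKind.OPEN

    def area(self) -> float:
        if self.kind is FieldKind.RECTANGLE:
            return self.width * self.height
        if self.kind is FieldKind.CIRCLE:
            return math.pi * self.radius**2
        if self.kind is FieldKind.DONUT:
            return math.pi * (self.outer_radius**2 - self.inner_radius**2)
        raise ValueError("open field has no finite area")

    def contains(self, x: float, y: float, tol: float = 1e-9) -> bool:
        """Closed membership test (boundary points are inside).

        ``tol`` absorbs round-off in points clamped onto the wall.
        """
        if self.kind is FieldKind.OPEN:
            return True
        if self.kind is FieldKind.RECTANGLE:
            return abs(x) <= self.width / 2 + tol and abs(y) <= self.height / 2 + tol
        r = math.hypot(x, y)
        if self.kind is FieldKind.CIRCLE:
            return r <= self.radius + tol
        return self.inner_radius - tol <= r <= self.outer_radius + tol

    def wall_distance(self, x: float, y: float) -> float:
        """Distance from an interior point to the nearest wall."""
        if self.kind is FieldKind.OPEN:
            return math.inf
        if self.kind is FieldKind.RECTANGLE:
            return min(
                self.width / 2 - abs(x),
                self.height / 2 - abs(y),
            )
        r = math.hypot(x, y)
        if self.kind is FieldKind.CIRCLE:
            return self.radius - r
        return min(self.outer_radius - r, r - self.inner_radius)

    def bounding_box(self) -> Tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in sim-units."""
        if self.kind is FieldKind.RECTANGLE:
            return -self.width / 2, self.width / 2, -self.height / 2, self.height / 2
        if self.kind is FieldKind.CIRCLE:
            r = self.radius
            return -r, r, -r, r
        if self.kind is FieldKind.DONUT:
            r = self.outer_radius
            return -r, r, -r, r
        raise ValueError("open field has no bounding box")


def make_field(kind: str | FieldKind, **dims_mm: float) -> FieldGeometry:
    """Build a :class:`FieldGeometry` from dimensions given in millimetres.

    Keyword arguments by kind: rectangle ``width_mm, height_mm``;
    circle ``radius_mm``; donut ``inner_radius_mm, outer_radius_mm``;
    open takes none.

    >>> make_field("rectangle", width_mm=30, height_mm=60).width
    140.0
    """
    kind = FieldKind(kind)
    u = UNITS_PER_MM

    def take(name: str) -> float:
        try:
            v = dims_mm.pop(name)
        except KeyError:
            raise ValueError(f"{kind.value} field requires {name}") from None
        return float(v) * u

    if kind is FieldKind.RECTANGLE:
        field = FieldGeometry(kind, width=take("width_mm"), height=take("height_mm"))
    elif kind is FieldKind.CIRCLE:
        field = FieldGeometry(kind, radius=take("radius_mm"))
    elif kind is FieldKind.DONUT:
        field = FieldGeometry(
            kind, inner_radius=take("inner_radius_mm"), outer_radius=take("outer_radius_mm")
        )
    else:
        field = FieldGeometry(kind)
    if dims_mm:
        raise ValueError(f"unexpected dimensions for {kind.value}: {sorted(dims_mm)}")
    return field


# Named arenas used throughout the study.
NAMED_FIELDS = {
    "rect30x60": lambda: make_field("rectangle", width_mm=30, height_mm=60),
    "circle90": lambda: make_field("circle", radius_mm=45),
    "circle60": lambda: make_field("circle", radius_mm=30),
    "circle200": lambda: make_field("circle", radius_mm=100),
    "donut": lambda: make_field("donut", inner_radius_mm=30, outer_radius_mm=45),
    "open": lambda: make_field("open"),
}


def named_field(name: str) -> FieldGeometry:
    try:
        return NAMED_FIELDS[name]()
    except KeyError:
        raise ValueError(f"unknown field name {name!r}; choose from {sorted(NAMED_FIELDS)}") from None


@dataclass(frozen=True)
class RegionPartition:
    """Equal-area wall/central partition of a bounded arena.

    For rectangles and circles the wall region is the band within
    ``wall_margin`` of the wall; the central region is a concentric
    similar figure scaled so its area equals the band's area; the
    remainder is "middle".  For donuts the annulus is split at
    ``split_radius`` into equal-area halves: convex (inner wall side)
    and concave (outer wall side).

    The wall band is closed on its inner boundary: a point exactly at
    the margin distance counts as wall, so a wall-sliding agent is
    always in the wall region.  The central figure is likewise closed.
    """

    field: FieldGeometry
    wall_margin: float = 0.0
    # rectangle: central half-sides; circle: central radius
    central_half_width: Optional[float] = None
    central_half_height: Optional[float] = None
    central_radius: Optional[float] = None
    split_radius: Optional[float] = None

    def wall_area(self) -> float:
        f = self.field
        m = self.wall_margin
        if f.kind is FieldKind.RECTANGLE:
            return f.width * f.height - (f.width - 2 * m) * (f.height - 2 * m)
        if f.kind is FieldKind.CIRCLE:
            return math.pi * (f.radius**2 - (f.radius - m) ** 2)
        raise ValueError("wall/central partition applies to rectangle and circle fields")

    def central_area(self) -> float:
        f = self.field
        if f.kind is FieldKind.RECTANGLE:
            return 4 * self.central_half_width * self.central_half_height
        if f.kind is FieldKind.CIRCLE:
            return math.pi * self.central_radius**2
        raise ValueError("wall/central partition applies to rectangle and circle fields")

    def convex_area(self) -> float:
        f = self.field
        return math.pi * (self.split_radius**2 - f.inner_radius**2)

    def concave_area(self) -> float:
        f = self.field
        return math.pi * (f.outer_radius**2 - self.split_radius**2)


def partition_regions(field: FieldGeometry, wall_margin_mm: float = 5.0) -> RegionPartition:
    """Partition a bounded arena into the study's regions.

    Rectangle/circle: a wall band of ``wall_margin_mm`` plus an
    equal-area concentric similar central figure.  Donut: an equal-area
    convex/concave split at radius sqrt((ri^2 + ro^2)/2); the margin is
    ignored because the split exhausts the annulus.
    """
    if not field.bounded:
        raise ValueError("cannot partition an open field")
    m = wall_margin_mm * UNITS_PER_MM

    if field.kind is FieldKind.DONUT:
        split = math.sqrt((field.inner_radius**2 + field.outer_radius**2) / 2.0)
        return RegionPartition(field=field, wall_margin=m, split_radius=split)

    if field.kind is FieldKind.RECTANGLE:
        w, h = field.width, field.height
        if not (0 < m < min(w, h) / 2):
            raise ValueError("wall margin must be positive and below half the smallest side")
        band = w * h - (w - 2 * m) * (h - 2 * m)
        s = math.sqrt(band / (w * h))  # similar-figure scale
        return RegionPartition(
            field=field,
            wall_margin=m,
            central_half_width=s * w / 2,
            central_half_height=s * h / 2,
        )

    # circle
    R = field.radius
    if not (0 < m < R):
        raise ValueError("wall margin must be positive and below the radius")
    rc = math.sqrt(R**2 - (R - m) ** 2)
    if rc >= R - m:
        raise ValueError("wall margin too large: central figure would touch the band")
    return RegionPartition(field=field, wall_margin=m, central_radius=rc)


def classify_point(partition: RegionPartition, x: float, y: float) -> Region:
    """Assign exactly one region label to a point.

    Wall band closed on its inner boundary; central figure closed; in
    the donut the convex half is closed at the split radius.
    """
    f = partition.field
    if not f.contains(x, y):
        return Region.OUTSIDE
    if f.kind is FieldKind.DONUT:
        r = math.hypot(x, y)
        return Region.CONVEX if r <= partition.split_radius else Region.CONCAVE
    if f.wall_distance(x, y) <= partition.wall_margin:
        return Region.WALL
    if f.kind is FieldKind.RECTANGLE:
        if abs(x) <= partition.central_half_width and abs(y) <= partition.central_half_height:
            return Region.CENTRAL
    else:
        if math.hypot(x, y) <= partition.central_radius:
            return Region.CENTRAL
    return Region.MIDDLE


def classify_points(partition: RegionPartition, xy: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_point` over an (n, 2) array.

    Returns an object array of :class:`Region` labels.
    """
    xy = np.asarray(xy, dtype=float)
    out = np.empty(len(xy), dtype=object)
    for i, (x, y) in enumerate(xy):
        out[i] = classify_point(partition, x, y)
    return out


# -- collision ---------------------------------------------------------


def _clamp_to_boundary(field: FieldGeometry, x: float, y: float) -> Tuple[float, float]:
    """Nearest boundary point to an exterior point."""
    if field.kind is FieldKind.RECTANGLE:
        hx, hy = field.width / 2, field.height / 2
        return min(max(x, -hx), hx), min(max(y, -hy), hy)
    r = math.hypot(x, y)
    if field.kind is FieldKind.CIRCLE:
        if r == 0.0:  # pragma: no cover - center is never exterior
            return field.radius, 0.0
        s = field.radius / r
        return x * s, y * s
    # donut: clamp to whichever wall was crossed
    target = field.outer_radius if r > field.outer_radius else field.inner_radius
    s = target / r
    return x * s, y * s


def _tangent_candidates(field: FieldGeometry, bx: float, by: float) -> list[float]:
    """Bearings of the wall tangent directions at a boundary point.

    At a rectangle corner all four edge directions are candidates.
    """
    if field.kind is FieldKind.RECTANGLE:
        hx, hy = field.width / 2, field.height / 2
        eps = 1e-9
        cands: list[float] = []
        if abs(abs(bx) - hx) <= eps:  # on a vertical edge: tangents +/-y
            cands += [0.0, math.pi]
        if abs(abs(by) - hy) <= eps:  # on a horizontal edge: tangents +/-x
            cands += [math.pi / 2, -math.pi / 2]
        if not cands:  # pragma: no cover - clamped points lie on an edge
            raise ValueError("point is not on the rectangle boundary")
        return cands
    alpha = math.atan2(bx, by)  # bearing of the boundary point from center
    return [alpha + math.pi / 2, alpha - math.pi / 2]


def collide_and_slide(
    field: FieldGeometry,
    pos: Tuple[float, float],
    proposed: Tuple[float, float],
    heading: float,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Tuple[float, float], float, bool]:
    """Resolve one movement step against the arena wall.

    If ``proposed`` lies inside the field it is returned unchanged.
    Otherwise the position is clamped to the nearest point on the wall
    and the heading is realigned to the wall tangent direction closest
    to the incoming heading (so the along-wall sign of the motion is
    preserved).  An exact tie between the two tangents — head-on
    incidence — is broken by ``rng``.

    Returns ``(new_pos, new_heading, contact)``.
    """
    x0, y0 = pos
    if not field.contains(x0, y0):
        raise ValueError(f"position {pos} lies outside the field")
    px, py = proposed
    if field.contains(px, py):
        return (px, py), heading, False

    bx, by = _clamp_to_boundary(field, px, py)
    cands = _tangent_candidates(field, bx, by)
    diffs = [abs(wrap_angle(c - heading)) for c in cands]
    best = min(diffs)
    ties = [c for c, d in zip(cands, diffs) if d <= best + 1e-12]
    if len(ties) > 1:
        if rng is None:
            rng = np.random.default_rng()
        choice = ties[int(rng.integers(len(ties)))]
    else:
        choice = ties[0]
    return (bx, by), wrap_angle(choice), True
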