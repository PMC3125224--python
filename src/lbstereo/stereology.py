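"""Design-based stereological estimators and the density-to-absolute cascade.

Implements the classical toolbox on vector-geometry sections:

* point counting for volume fractions, ``V_V = sum P_struct / sum P_ref``;
* intersection counting for surface density, ``S_V = 2 sum I / sum L``
  (isotropic test lines of known length per point);
* the physical disector for numerical density,
  ``N_V = sum Q / (k * h * a(p) * sum P_ref)`` with ``k = 2`` when each
  section serves once as reference and once as look-up section;
* the planar rotator for individual particle volume,
  ``v = pi * t * sum_i (l_plus_i^2 + l_minus_i^2) / 2``,
  from distances between a random axis through the reference point and the
  profile boundary on systematic test lines with spacing ``t``;
* the conversion cascade from densities to absolute per-lung values, using
  the measured lung volume and the number-weighted mean cell volume as
  reference volumes (avoiding the reference trap);
* the sphere-model lamellar-body membrane surface
  ``r = (3 v / 4 pi)^(1/3)``, ``s = 4 pi r^2``, ``S(Lb, AE2) = N(Lb, AE2) * s``
  and the membrane-balance bookkeeping between experimental groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

from . import geometry as geo
from .microtome import CountingFrame, ProfileSet, Section, SectionPair
from .phantom import Phantom, UM3_PER_CM3

__all__ = [
    "TestSystem",
    "counts_to_estimates",
    "GridRealization",
    "CountRecord",
    "DensityEstimates",
    "AbsoluteEstimates",
    "MembraneBalance",
    "count_points",
    "count_intersections",
    "line_length_in_reference",
    "physical_disector",
    "DisectorResult",
    "estimate_N_V",
    "planar_rotator",
    "surface_density",
    "estimate_surface_per_cell",
    "cascade_to_absolute",
    "lb_sphere_surface",
    "membrane_balance",
    "UNITS",
]

UNITS = {
    "V_lung": "cm^3",
    "N_AE2_lung": "1",
    "vbar_AE2": "um^3",
    "N_Lb_AE2": "1",
    "V_Lb_AE2": "um^3",
    "V_Lb_lung": "um^3",
    "vbar_Lb": "um^3",
    "S_lumen_AE2": "um^2",
    "S_cell_AE2": "um^2",
    "S_Lb_AE2": "um^2",
    "rbar_Lb": "um",
    "V_V_Lb_AE2": "1",
    "V_V_mito_AE2": "1",
    "V_V_nuc_AE2": "1",
    "N_V_Lb_AE2": "um^-3",
    "S_V_lumen_AE2": "um^-1",
    "S_V_cell_AE2": "um^-1",
    "N_V_AE2_lung": "cm^-3",
}

# subset relations the point-count precondition accepts (structure, reference)
_CONTAINMENT = {
    ("lb", "cell"),
    ("lb", "lung"),
    ("nucleus", "cell"),
    ("nucleus", "lung"),
    ("nucleolus", "nucleus"),
    ("nucleolus", "cell"),
    ("nucleolus", "lung"),
    ("cell", "lung"),
}


@dataclass(frozen=True)
class TestSystem:
    """A coherent combined point and line grid test system.

    Square point lattice with spacing ``d`` (area per point ``a(p) = d^2``)
    whose rows double as test lines, so the line length per point is
    ``l(p) = d``. Each realisation applies an independent uniform translation
    within one grid period and a uniform rotation.
    """

    spacing: float
    seed: int = 0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")

    @property
    def area_per_point(self) -> float:
        return self.spacing**2

    @property
    def length_per_point(self) -> float:
        return self.spacing

    def realize(self, rng: np.random.Generator) -> "GridRealization":
        return GridRealization(
            spacing=self.spacing,
            offset=rng.uniform(0.0, self.spacing, size=2),
            angle=rng.uniform(0.0, np.pi),
            randomized=True,
        )

    def fixed(self) -> "GridRealization":
        """Deterministic, unrandomised realisation (for strict-mode checks)."""
        return GridRealization(self.spacing, np.zeros(2), 0.0, randomized=False)


@dataclass(frozen=True)
class GridRealization:
    spacing: float
    offset: np.ndarray
    angle: float
    randomized: bool = True

    def _rot(self):
        c, s = np.cos(self.angle), np.sin(self.angle)
        return np.array([[c, -s], [s, c]])

    def points(self, frame: CountingFrame) -> np.ndarray:
        """Grid points falling inside the frame, plane coordinates (n, 2)."""
        d = self.spacing
        R = self._rot()
        radius = frame.side * np.sqrt(0.5) + d
        k = int(np.ceil(radius / d)) + 1
        i = np.arange(-k, k + 1)
        U, V = np.meshgrid(self.offset[0] + i * d, self.offset[1] + i * d)
        pts = np.stack([U.ravel(), V.ravel()], axis=1) @ R.T + frame.center
        return pts[frame.contains_points(pts)]

    def lines(self, frame: CountingFrame):
        """Test lines crossing the frame: (anchor point (m, 2), direction (2,)).

        Lines are the rows of the same lattice (spacing ``d`` apart), which
        makes the point and line systems coherent.
        """
        d = self.spacing
        R = self._rot()
        direction = R @ np.array([1.0, 0.0])
        perp = R @ np.array([0.0, 1.0])
        radius = frame.side * np.sqrt(0.5) + d
        k = int(np.ceil(radius / d)) + 1
        offs = self.offset[1] + np.arange(-k, k + 1) * d
        anchors = frame.center[None, :] + offs[:, None] * perp[None, :]
        return anchors, direction


@dataclass
class CountRecord:
    """Raw counts of one lung's counting session (integer counts)."""

    P_struct: int = 0
    P_ref: int = 0
    I_lumen: int = 0
    I_cell: int = 0
    Q_dir1: int = 0
    Q_dir2: int = 0
    h: float = 0.0  # um
    a_p: float = 0.0  # um^2

    def __post_init__(self):
        for name in ("P_struct", "P_ref", "I_lumen", "I_cell", "Q_dir1", "Q_dir2"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer")


@dataclass(frozen=True)
class DensityEstimates:
    """Per-lung densities, each per unit of its reference volume."""

    V_V_Lb_AE2: float
    V_V_mito_AE2: float
    V_V_nuc_AE2: float
    N_V_Lb_AE2: float  # um^-3
    S_V_lumen_AE2: float  # um^-1
    S_V_cell_AE2: float  # um^-1
    N_V_AE2_lung: float  # cm^-3

    def validate(self) -> None:
        fracs = (self.V_V_Lb_AE2, self.V_V_mito_AE2, self.V_V_nuc_AE2)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("volume fractions must lie in [0, 1]")
        if sum(fracs) > 1.0:
            raise ValueError("volume fractions must sum to <= 1")
        if any(
            v < 0
            for v in (self.N_V_Lb_AE2, self.S_V_lumen_AE2, self.S_V_cell_AE2, self.N_V_AE2_lung)
        ):
            raise ValueError("densities must be nonnegative")


@dataclass(frozen=True)
class AbsoluteEstimates:
    """Per-lung absolute values after the density-to-absolute cascade."""

    V_lung: float  # cm^3
    N_AE2_lung: float
    vbar_AE2: float  # um^3
    N_Lb_AE2: float
    V_Lb_AE2: float  # um^3
    V_Lb_lung: float  # um^3
    vbar_Lb: float  # um^3
    S_lumen_AE2: float  # um^2
    S_cell_AE2: float  # um^2
    S_Lb_AE2: float  # um^2
    rbar_Lb: float  # um

    def validate(self, rtol: float = 1e-9) -> None:
        if self.N_Lb_AE2 > 0 and self.N_AE2_lung > 0:
            lhs = self.vbar_Lb
            rhs = self.V_Lb_lung / (self.N_Lb_AE2 * self.N_AE2_lung)
            if not np.isclose(lhs, rhs, rtol=1e-6):
                raise ValueError("vbar_Lb inconsistent with V_Lb_lung / N_Lb_lung")
        if self.S_lumen_AE2 > self.S_cell_AE2 * (1.0 + rtol) and self.S_cell_AE2 > 0:
            raise ValueError("luminal surface cannot exceed total cell surface")


# ---------------------------------------------------------------------------


def _points_in_cells(pts2d: np.ndarray, ps: ProfileSet) -> np.ndarray:
    """Membership of plane points in any AE2 profile (exact ellipse test)."""
    if len(ps.cell_ids) == 0 or len(pts2d) == 0:
        return np.zeros(len(pts2d), dtype=bool)
    inside = np.zeros(len(pts2d), dtype=bool)
    for c, ax, an in zip(ps.cell_center2d, ps.cell_axes2d, ps.cell_angle):
        rel = pts2d - c
        ca, sa = np.cos(an), np.sin(an)
        u = rel[:, 0] * ca + rel[:, 1] * sa
        v = -rel[:, 0] * sa + rel[:, 1] * ca
        inside |= (u / ax[0]) ** 2 + (v / ax[1]) ** 2 < 1.0
    return inside


def _points_in_discs(pts2d, centers, radii):
    if len(centers) == 0 or len(pts2d) == 0:
        return np.zeros(len(pts2d), dtype=bool)
    d2 = ((pts2d[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return (d2 < radii[None, :] ** 2).any(axis=1)


def _membership(pts2d, ps: ProfileSet, what: str) -> np.ndarray:
    if what == "cell":
        return _points_in_cells(pts2d, ps)
    if what == "lung":
        return ps.phantom.contains(ps.section.to_world(pts2d))
    if what == "lb":
        return _points_in_discs(pts2d, ps.lb_center2d, ps.lb_radius)
    if what == "nucleus":
        return _points_in_discs(pts2d, ps.nuc_center2d, ps.nuc_radius)
    if what == "nucleolus":
        return _points_in_discs(pts2d, ps.nll_center2d, ps.nll_radius)
    raise ValueError(f"unknown structure {what!r}")


def count_points(profiles: ProfileSet, grid: GridRealization, frame: CountingFrame,
                 structure: str, reference: str, strict: bool = False):
    """Grid points hitting the structure and the reference within the frame.

    Returns ``(P_struct, P_ref)``. The structure must be contained in the
    reference; a point counts for the structure only if it also hits the
    reference (they coincide geometrically for the supported pairs).
    """
    if (structure, reference) not in _CONTAINMENT:
        raise ValueError(
            f"structure {structure!r} is not contained in reference {reference!r}"
        )
    if strict and not grid.randomized:
        raise RuntimeError("strict mode requires a randomised test system")
    pts = grid.points(frame)
    in_ref = _membership(pts, profiles, reference)
    in_struct = _membership(pts, profiles, structure) & in_ref
    return int(in_struct.sum()), int(in_ref.sum())


def _cell_boundary_crossings(ps: ProfileSet, anchors, direction, frame):
    """Transversal crossings of test lines with cell boundaries in the frame.

    Returns the crossing points (m, 2) and their parent cell ids. The
    quadratic along each line is solved vectorised over all anchors per cell.
    """
    pk = ps.pk
    sec = ps.section
    w = direction[0] * sec.e1 + direction[1] * sec.e2
    p0 = sec.to_world(anchors)  # (m, 3)
    pts, cells = [], []
    for cid in ps.cell_ids:
        M = pk["cell_M"][cid]
        d = p0 - pk["cell_centers"][cid]
        Mw = M @ w
        A = float(w @ Mw)
        B = d @ Mw
        C = np.einsum("ij,jk,ik->i", d, M, d) - 1.0
        disc = B * B - A * C
        hit = disc > 0.0
        if not hit.any():
            continue
        sq = np.sqrt(disc[hit])
        for sgn in (-1.0, 1.0):
            s = (-B[hit] + sgn * sq) / A
            q2 = anchors[hit] + s[:, None] * direction
            inside = frame.contains_points(q2)
            pts.append(q2[inside])
            cells.append(np.full(int(inside.sum()), cid, dtype=int))
    if not pts:
        return np.zeros((0, 2)), np.zeros(0, dtype=int)
    return np.concatenate(pts, axis=0), np.concatenate(cells)


def count_intersections(profiles: ProfileSet, grid: GridRealization,
                        frame: CountingFrame,
                        boundary_kind: Literal["cell", "lumen"]) -> int:
    """Transversal crossings of the test lines with the named boundary.

    Tangencies contribute zero (they yield no transversal roots).
    """
    anchors, direction = grid.lines(frame)
    pts2d, cells = _cell_boundary_crossings(profiles, anchors, direction, frame)
    if boundary_kind == "cell" or len(pts2d) == 0:
        return len(pts2d)
    if boundary_kind != "lumen":
        raise ValueError(f"unknown boundary kind {boundary_kind!r}")
    return int(_classify_luminal(profiles, pts2d, cells).sum())


def _classify_luminal(ps: ProfileSet, pts2d: np.ndarray, cell_rows: np.ndarray):
    """Luminal-patch membership of boundary points, honouring periodic images."""
    pk = ps.pk
    world = ps.section.to_world(pts2d)
    luminal = np.zeros(len(world), dtype=bool)
    for cid in np.unique(cell_rows):
        sel = cell_rows == cid
        orig = ps.phantom.cells[int(pk["cell_orig"][cid])]
        luminal[sel] = orig.is_luminal(world[sel] - pk["cell_shift"][cid])
    return luminal


def line_length_in_reference(P_ref_cells: int, length_per_point: float) -> float:
    """Test-line length within the reference profiles, um (coherent grid)."""
    return P_ref_cells * length_per_point


# -- physical disector -------------------------------------------------------


def disector_margin(pair: SectionPair, half: float | None = None) -> float:
    """Probe excursion of a disector beyond the reference cube: the farthest
    point of the counting frame on either plane, measured from the anchor,
    plus how far the anchor itself pokes past a face of the cube (blocks cut
    near a face legitimately extend beyond it in the periodic tissue)."""
    anchor_out = 0.0
    if half is not None:
        anchor_out = float(np.max(np.maximum(np.abs(pair.anchor) - half, 0.0)))
    return anchor_out + float(
        np.hypot(max(abs(pair.z1), abs(pair.z2)), pair.frame.side * np.sqrt(0.5))
    ) + 1.0


@dataclass(frozen=True)
class DisectorResult:
    Q_dir1: int
    Q_dir2: int
    ids_dir1: np.ndarray
    ids_dir2: np.ndarray

    @property
    def Q_total(self) -> int:
        return self.Q_dir1 + self.Q_dir2


def physical_disector(pair: SectionPair, phantom: Phantom,
                      marker: Literal["nucleolus", "lb"],
                      both_directions: bool = True) -> DisectorResult:
    """Count disector events for the marker between the two sections.

    An event in direction 1 is a marker particle whose profile appears in
    section 1 (subject to the unbiased counting frame) while the particle is
    absent from section 2; direction 2 is symmetric. Returns the sampled
    particle ids per direction (used downstream to pick rotator cells).
    """
    if pair.z2 - pair.z1 <= 0:
        raise ValueError("disector height must be positive")
    pk = phantom.packed(disector_margin(pair, phantom.lung_side / 2.0))
    if marker == "nucleolus":
        centers, radii = pk["nll_centers"], pk["nll_radii"]
    elif marker == "lb":
        centers, radii = pk["lb_centers"], pk["lb_radii"]
    else:
        raise ValueError(f"unknown disector marker {marker!r}")
    signed = centers @ pair.normal - pair.anchor @ pair.normal
    d1 = signed - pair.z1
    d2 = signed - pair.z2
    present1 = np.abs(d1) < radii
    present2 = np.abs(d2) < radii

    def events(present_ref, present_look, dref):
        cand = np.nonzero(present_ref & ~present_look)[0]
        if len(cand) == 0:
            return cand
        rel = centers[cand] - pair.anchor
        c2d = np.stack([rel @ pair.e1, rel @ pair.e2], axis=1)
        r2d = np.sqrt(radii[cand] ** 2 - dref[cand] ** 2)
        ok = pair.frame.accepts_discs(c2d, r2d)
        return cand[ok]

    ids1 = events(present1, present2, d1)
    if both_directions:
        ids2 = events(present2, present1, d2)
    else:
        ids2 = np.zeros(0, dtype=int)
    return DisectorResult(Q_dir1=len(ids1), Q_dir2=len(ids2), ids_dir1=ids1, ids_dir2=ids2)


def estimate_N_V(Q_total: float, P_ref: float, a_p: float, h: float,
                 both_directions: bool = True) -> float:
    """Numerical density from pooled disector counts, um^-3.

    ``N_V = sum Q / (k * h * a(p) * sum P_ref)`` with ``k = 2`` when counting
    in both directions (each section once reference, once look-up).
    """
    if P_ref <= 0:
        raise ZeroDivisionError("undefined density: no reference points counted")
    if h <= 0 or a_p <= 0:
        raise ValueError("h and a(p) must be positive")
    k = 2.0 if both_directions else 1.0
    return float(Q_total) / (k * h * a_p * float(P_ref))


# -- planar rotator ----------------------------------------------------------


def planar_rotator(section: Section, cell, ref_point2d: np.ndarray,
                   axis_angle: float, line_spacing: float,
                   rng: np.random.Generator | None = None,
                   start: float | None = None,
                   center_override: np.ndarray | None = None) -> float:
    """Particle volume from one profile by the planar rotator, um^3.

    A rotation axis through the reference point is laid at ``axis_angle``
    within the section; test lines perpendicular to the axis are placed
    systematically with spacing ``t = line_spacing`` and a uniform random
    start. Each line contributes half the squared boundary distances on both
    sides of the axis; ``v = pi * t * sum``. Unbiased over isotropic sections
    through the reference point.
    """
    ref = np.asarray(ref_point2d, dtype=float)
    M = cell.quadric()
    center = cell.center if center_override is None else np.asarray(center_override)
    ref_world = section.to_world(ref[None, :])[0]
    rel = ref_world - center
    if rel @ M @ rel > 1.0:
        raise ValueError("reference point lies outside the cell profile")
    t = float(line_spacing)
    if t <= 0:
        raise ValueError("line spacing must be positive")
    A = np.array([np.cos(axis_angle), np.sin(axis_angle)])
    B = np.array([-A[1], A[0]])
    w = B[0] * section.e1 + B[1] * section.e2
    axis_w = A[0] * section.e1 + A[1] * section.e2
    # axis extent of the profile: support of the section ellipse along A
    roots = geo.line_quadric_roots(ref_world, axis_w, center, M)
    bound = max(abs(r) for r in roots) if roots else 0.0
    bound = bound + 2.0 * max(cell.axes)  # conservative cover of the profile
    if start is None:
        if rng is None:
            rng = np.random.default_rng()
        start = rng.uniform(0.0, 1.0)
    i = np.arange(-int(np.ceil(bound / t)) - 1, int(np.ceil(bound / t)) + 2)
    ys = (i + start) * t
    d = (ref_world - center) + ys[:, None] * axis_w
    Mw = M @ w
    A = float(w @ Mw)
    B = d @ Mw
    C = np.einsum("ij,jk,ik->i", d, M, d) - 1.0
    disc = B * B - A * C
    hit = disc > 0.0
    sq = np.sqrt(disc[hit])
    s_lo = (-B[hit] - sq) / A
    s_hi = (-B[hit] + sq) / A
    c_plus = 0.5 * (np.maximum(s_hi, 0.0) ** 2 - np.maximum(s_lo, 0.0) ** 2)
    c_minus = 0.5 * (np.maximum(-s_lo, 0.0) ** 2 - np.maximum(-s_hi, 0.0) ** 2)
    return float(np.pi * t * np.sum(c_plus + c_minus))


# -- surfaces and the cascade ------------------------------------------------


def surface_density(I_total: float, length_total: float) -> float:
    """``S_V = 2 * sum I / sum L`` (um^-1) from pooled intersection counts."""
    if length_total <= 0:
        raise ZeroDivisionError("undefined surface density: zero test-line length")
    return 2.0 * float(I_total) / float(length_total)


def estimate_surface_per_cell(I_lumen: float, I_cell: float, length_in_ref: float,
                              vbar_AE2: float):
    """Luminal and total cell surface per AE2 cell, um^2.

    Converts surface densities (per unit AE2 volume) to absolute per-cell
    surfaces with the number-weighted mean cell volume.
    """
    s_v_lumen = surface_density(I_lumen, length_in_ref)
    s_v_cell = surface_density(I_cell, length_in_ref)
    return s_v_lumen * vbar_AE2, s_v_cell * vbar_AE2


def cascade_to_absolute(densities: DensityEstimates, V_lung_cm3: float,
                        vbar_AE2: float, N_AE2_lung: float | None = None) -> AbsoluteEstimates:
    """Densities -> absolute values, avoiding the reference trap.

    ``N(AE2, lung) = N_V(AE2, lung) * V(lung)`` unless an externally obtained
    cell number is supplied; Lb quantities scale with the number-weighted
    mean cell volume and the cell number; the number-weighted mean Lb volume
    is total Lb volume per lung over total Lb number per lung.
    """
    if V_lung_cm3 <= 0 or vbar_AE2 <= 0:
        raise ZeroDivisionError("reference volumes must be positive")
    if N_AE2_lung is None:
        N_AE2_lung = densities.N_V_AE2_lung * V_lung_cm3
    if N_AE2_lung <= 0:
        raise ZeroDivisionError("cell number must be positive for the cascade")
    N_Lb_AE2 = densities.N_V_Lb_AE2 * vbar_AE2
    V_Lb_AE2 = densities.V_V_Lb_AE2 * vbar_AE2
    V_Lb_lung = V_Lb_AE2 * N_AE2_lung
    vbar_Lb = V_Lb_lung / (N_Lb_AE2 * N_AE2_lung) if N_Lb_AE2 > 0 else 0.0
    S_lumen = densities.S_V_lumen_AE2 * vbar_AE2
    S_cell = densities.S_V_cell_AE2 * vbar_AE2
    rbar, _, S_Lb = lb_sphere_surface(vbar_Lb, N_Lb_AE2) if vbar_Lb > 0 else (0.0, 0.0, 0.0)
    return AbsoluteEstimates(
        V_lung=V_lung_cm3,
        N_AE2_lung=N_AE2_lung,
        vbar_AE2=vbar_AE2,
        N_Lb_AE2=N_Lb_AE2,
        V_Lb_AE2=V_Lb_AE2,
        V_Lb_lung=V_Lb_lung,
        vbar_Lb=vbar_Lb,
        S_lumen_AE2=S_lumen,
        S_cell_AE2=S_cell,
        S_Lb_AE2=S_Lb,
        rbar_Lb=rbar,
    )


def lb_sphere_surface(vbar_Lb: float, N_Lb_AE2: float):
    """Sphere-model Lb membrane surface: (rbar, sbar, S(Lb, AE2)).

    Treats every lamellar body as a sphere of the number-weighted mean
    volume: ``rbar = (3 vbar / 4 pi)^(1/3)``, ``sbar = 4 pi rbar^2``,
    ``S(Lb, AE2) = N(Lb, AE2) * sbar``.
    """
    if vbar_Lb <= 0:
        raise ValueError("mean Lb volume must be positive")
    if N_Lb_AE2 < 0:
        raise ValueError("Lb number per cell cannot be negative")
    rbar = float(geo.radius_from_volume(vbar_Lb))
    sbar = float(geo.sphere_surface(rbar))
    return rbar, sbar, N_Lb_AE2 * sbar


@dataclass(frozen=True)
class MembraneBalance:
    """Group-mean membrane bookkeeping between luminal surface and Lb surface."""

    S_lumen_control: float
    S_Lb_control: float
    S_lumen_ir: float
    S_Lb_ir: float

    @property
    def sum_control(self) -> float:
        return self.S_lumen_control + self.S_Lb_control

    @property
    def sum_ir(self) -> float:
        return self.S_lumen_ir + self.S_Lb_ir

    @property
    def delta_S_Lb(self) -> float:
        """Membrane lost from the Lb pool: S_Lb(control) - S_Lb(I/R)."""
        return self.S_Lb_control - self.S_Lb_ir

    @property
    def delta_S_lumen(self) -> float:
        """Membrane gained by the luminal surface: S_lumen(I/R) - S_lumen(control)."""
        return self.S_lumen_ir - self.S_lumen_control


def membrane_balance(control: dict | AbsoluteEstimates, ir: dict | AbsoluteEstimates) -> MembraneBalance:
    """Per-group sums and between-group shifts of the limiting membrane.

    Accepts group means as AbsoluteEstimates or as mappings with keys
    ``S_lumen_AE2`` and ``S_Lb_AE2``.
    """

    def get(obj, key):
        return obj[key] if isinstance(obj, dict) else getattr(obj, key)

    return MembraneBalance(
        S_lumen_control=get(control, "S_lumen_AE2"),
        S_Lb_control=get(control, "S_Lb_AE2"),
        S_lumen_ir=get(ir, "S_lumen_AE2"),
        S_Lb_ir=get(ir, "S_Lb_AE2"),
    )


def counts_to_estimates(records, a_p: float, l_p: float, h_lm: float,
                        V_lung_cm3: float, vbar_AE2: float,
                        mito_fraction: float = 0.0,
                        P_nuc: int = 0) -> tuple[DensityEstimates, AbsoluteEstimates]:
    """Reduce externally supplied count records to density and absolute
    estimates (the import path for real counting sessions).

    ``records`` is an iterable of mappings or ``CountRecord``-like objects
    with per-disector fields: ``P_struct`` (points on Lb profiles), ``P_ref``
    (points on AE2 profiles), ``I_lumen``, ``I_cell``, ``Q_dir1``, ``Q_dir2``
    and ``h`` (the electron-microscopic disector height, um). Light
    microscopic nucleolus counts enter through ``h_lm`` with records whose
    ``P_ref`` are lung points -- supply those separately via keyword-style
    records carrying ``lm=True``. All grids share ``a_p``/``l_p``.
    """

    def get(r, k, default=0):
        if isinstance(r, dict):
            return r.get(k, default)
        return getattr(r, k, default)

    Q_em = P_lb = P_cell = I_lum = I_cell = 0
    dis_vol = 0.0
    Q_lm = P_lung = 0
    for r in records:
        if get(r, "lm", False):
            Q_lm += get(r, "Q_dir1") + get(r, "Q_dir2")
            P_lung += get(r, "P_ref")
            continue
        q = get(r, "Q_dir1") + get(r, "Q_dir2")
        Q_em += q
        P_lb += get(r, "P_struct")
        P_cell += get(r, "P_ref")
        I_lum += get(r, "I_lumen")
        I_cell += get(r, "I_cell")
        dis_vol += get(r, "h") * get(r, "P_ref") * a_p
    if P_cell == 0 or P_lung == 0 or dis_vol <= 0:
        raise ZeroDivisionError("undefined density: empty reference counts")
    L = P_cell * l_p
    dens = DensityEstimates(
        V_V_Lb_AE2=P_lb / P_cell,
        V_V_mito_AE2=mito_fraction,
        V_V_nuc_AE2=P_nuc / P_cell,
        N_V_Lb_AE2=Q_em / (2.0 * dis_vol),
        S_V_lumen_AE2=surface_density(I_lum, L),
        S_V_cell_AE2=surface_density(I_cell, L),
        N_V_AE2_lung=estimate_N_V(Q_lm, P_lung, a_p, h_lm) * UM3_PER_CM3,
    )
    dens.validate()
    absolute = cascade_to_absolute(dens, V_lung_cm3, vbar_AE2)
    absolute.validate()
    return dens, absolute
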