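"""Virtual microtome: the sampling cascade from whole lung to section pairs.

Reproduces the laboratory cascade on the phantom: fluid-displacement
measurement of the reference volume (with configurable noise), systematic
uniform random slab cutting (random start, fixed period, every-other slab
kept), point-grid block sampling on the slab cut faces, and cutting of
parallel section pairs with isotropic (IUR) or axis-aligned orientation.
Sections are zero-thickness planes for counting purposes but carry a nominal
thickness; the electron-microscopic disector height is the section thickness,
optionally "measured" through the fold-thickness rule (half the thickness of
a fold, i.e. a noisy measurement of 2t).

Profiles are exact vector geometry: a sphere cut by a plane is a disc, an
ellipsoid cut by a plane is an ellipse in closed form; no pixel raster
appears anywhere. A solid tangent to the plane (a measure-zero event) counts
as non-intersecting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from . import geometry as geo
from .phantom import Phantom

__all__ = [
    "SamplingPlan",
    "Block",
    "SectionPair",
    "Section",
    "CountingFrame",
    "ProfileSet",
    "Profile",
    "sample_blocks",
    "cut_section_pair",
    "extract_profiles",
    "measure_reference_volume",
    "default_plan_for",
]

LM_THICKNESS = 1.0  # um, semithin sections
LM_DISECTOR_HEIGHT = 3.0  # um, first and fourth 1-um section of a row
EM_THICKNESS = 0.1  # um, ~100 nm ultrathin sections


@dataclass(frozen=True)
class SamplingPlan:
    """Parameters of the slab/block/section sampling cascade (lengths um)."""

    slab_thickness: float = 3000.0
    keep_rule: Literal["every-even", "every-uneven"] = "every-even"
    block_point_spacing: float = 1000.0
    block_size: float = 800.0
    blocks_min: int = 5
    blocks_max: int = 11
    frame_size: float = 600.0
    frame_guard: float = 0.0
    orientation_mode: Literal["IUR", "axis-aligned"] = "IUR"
    fold_noise_cv: float = 0.0
    strict: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.slab_thickness <= 0:
            raise ValueError("slab_thickness must be > 0")
        if self.blocks_min > self.blocks_max:
            raise ValueError("blocks_min must be <= blocks_max")
        if self.frame_size + 2 * self.frame_guard > self.block_size * 1.5:
            raise ValueError("counting frame does not fit the block window")


def default_plan_for(phantom: Phantom, seed: int = 0, **overrides) -> SamplingPlan:
    """A plan scaled to the phantom so that ~5-11 blocks are sampled per lung,
    mirroring the block yield of the laboratory cascade."""
    side = phantom.lung_side
    params = dict(
        slab_thickness=side / 2.1,
        block_point_spacing=side / 2.75,
        block_size=side / 2.6,
        frame_size=side / 3.4,
        blocks_max=36,  # ample: the spacing itself keeps the yield in range
        seed=seed,
    )
    params.update(overrides)
    return SamplingPlan(**params)


@dataclass(frozen=True)
class Block:
    id: int
    center: np.ndarray  # world um
    size: float


@dataclass(frozen=True)
class CountingFrame:
    """Unbiased 2D counting frame (Gundersen frame) in plane coordinates.

    The forbidden line runs from +inf down the left edge, along the bottom
    edge, then down from the bottom-right corner to -inf; the top and right
    edges are acceptance lines. A profile is counted if it intersects the
    open frame and does not touch the forbidden line.
    """

    center: np.ndarray
    side: float

    @property
    def x_left(self):
        return self.center[0] - self.side / 2.0

    @property
    def x_right(self):
        return self.center[0] + self.side / 2.0

    @property
    def y_bottom(self):
        return self.center[1] - self.side / 2.0

    @property
    def y_top(self):
        return self.center[1] + self.side / 2.0

    @property
    def area(self):
        return self.side * self.side

    def contains_points(self, pts: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(pts)
        return (
            (p[:, 0] > self.x_left)
            & (p[:, 0] < self.x_right)
            & (p[:, 1] > self.y_bottom)
            & (p[:, 1] < self.y_top)
        )

    def accepts_discs(self, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
        """Frame rule for disc profiles (vectorised)."""
        c = np.atleast_2d(centers)
        r = np.atleast_1d(radii)
        # intersects the open frame rectangle
        dx = np.maximum(np.maximum(self.x_left - c[:, 0], c[:, 0] - self.x_right), 0.0)
        dy = np.maximum(np.maximum(self.y_bottom - c[:, 1], c[:, 1] - self.y_top), 0.0)
        inter = np.hypot(dx, dy) < r
        # distance to the forbidden polyline
        d_left = np.where(
            c[:, 1] >= self.y_bottom,
            np.abs(c[:, 0] - self.x_left),
            np.hypot(c[:, 0] - self.x_left, c[:, 1] - self.y_bottom),
        )
        d_bottom = np.where(
            (c[:, 0] >= self.x_left) & (c[:, 0] <= self.x_right),
            np.abs(c[:, 1] - self.y_bottom),
            np.inf,
        )
        d_right = np.where(
            c[:, 1] <= self.y_bottom,
            np.abs(c[:, 0] - self.x_right),
            np.hypot(c[:, 0] - self.x_right, c[:, 1] - self.y_bottom),
        )
        d_forbidden = np.minimum(np.minimum(d_left, d_bottom), d_right)
        return inter & (d_forbidden >= r)


@dataclass(frozen=True)
class Section:
    """One zero-thickness plane with nominal thickness, in a shared frame."""

    origin: np.ndarray  # point on the plane, world um
    normal: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    thickness: float

    def to_world(self, pts2d: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(pts2d)
        return self.origin + p[:, :1] * self.e1 + p[:, 1:2] * self.e2

    def to_plane(self, pts3d: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(pts3d) - self.origin
        return np.stack([rel @ self.e1, rel @ self.e2], axis=1)


@dataclass(frozen=True)
class SectionPair:
    """Two parallel sections a known distance apart (the physical disector)."""

    block_id: int
    normal: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    anchor: np.ndarray  # world point with plane offsets measured along normal
    z1: float
    z2: float
    section_thickness: float
    mode: Literal["LM_semithin", "EM_ultrathin"]
    frame: CountingFrame
    disector_height_measured: float | None = None

    def __post_init__(self):
        if self.z2 <= self.z1:
            raise ValueError("disector height must be positive (z2 > z1)")

    @property
    def disector_height(self) -> float:
        """Centre-to-centre plane separation h, um (measured value if the
        fold-thickness rule was applied)."""
        if self.disector_height_measured is not None:
            return self.disector_height_measured
        return self.z2 - self.z1

    def section(self, which: int) -> Section:
        z = {1: self.z1, 2: self.z2}[which]
        return Section(
            origin=self.anchor + z * self.normal,
            normal=self.normal,
            e1=self.e1,
            e2=self.e2,
            thickness=self.section_thickness,
        )


@dataclass(frozen=True)
class Profile:
    """A 2D profile of a solid on a section (plane coordinates)."""

    structure: Literal["cell", "nucleus", "nucleolus", "lb"]
    cell_id: int
    center2d: np.ndarray
    # discs: (r, r) and angle 0; ellipses: semi-axes and major-axis angle
    semi_axes: np.ndarray
    angle: float

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])


@dataclass
class ProfileSet:
    """All profiles of one section, with the geometry needed for counting.

    Keeps packed arrays per structure for vectorised point/intersection
    counting, plus a reference to the phantom for exact 3D membership tests.
    """

    section: Section
    phantom: Phantom
    pk: dict = field(default_factory=dict, repr=False)
    cell_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    cell_orig: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    cell_shift: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    cell_center2d: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    cell_axes2d: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    cell_angle: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lb_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    lb_cell: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    lb_center2d: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    lb_radius: np.ndarray = field(default_factory=lambda: np.zeros(0))
    nuc_cell: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    nuc_center2d: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    nuc_radius: np.ndarray = field(default_factory=lambda: np.zeros(0))
    nll_cell: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    nll_center2d: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    nll_radius: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def profiles(self) -> list[Profile]:
        out = [
            Profile("cell", int(cid), c, ax.copy(), float(an))
            for cid, c, ax, an in zip(
                self.cell_orig, self.cell_center2d, self.cell_axes2d, self.cell_angle
            )
        ]
        for name, cells, cen, rad in (
            ("lb", self.lb_cell, self.lb_center2d, self.lb_radius),
            ("nucleus", self.nuc_cell, self.nuc_center2d, self.nuc_radius),
            ("nucleolus", self.nll_cell, self.nll_center2d, self.nll_radius),
        ):
            out.extend(
                Profile(name, int(cid), c, np.array([r, r]), 0.0)
                for cid, c, r in zip(cells, cen, rad)
            )
        return out

    def __len__(self):
        return (
            len(self.cell_ids) + len(self.lb_ids) + len(self.nuc_cell) + len(self.nll_cell)
        )


# ---------------------------------------------------------------------------


def sample_blocks(phantom: Phantom, plan: SamplingPlan,
                  rng: np.random.Generator | None = None) -> list[Block]:
    """Slab SURS followed by point-grid block sampling.

    Slabs are cut perpendicular to a fixed axis with a uniform random start;
    every other slab (per ``keep_rule``) is processed. A square point grid
    with uniform random offset is laid on each kept slab's cut face; each
    grid point hitting the lung cross-section yields one block centred at the
    hit, half a slab deep. Yields above ``blocks_max`` are subsampled
    systematically with a random phase.
    """
    plan.validate()
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    side = phantom.lung_side
    half = side / 2.0
    T = plan.slab_thickness
    # the random start spans one full period of the kept-slab pattern (2T,
    # since every other slab is processed), and exactly the cut faces whose
    # position falls within one period of the tissue are used: the tissue is
    # periodic, so extending the window would represent wrapped tissue twice
    # and break uniform z coverage
    start = -half - rng.uniform(0.0, 2.0 * T)
    cut_faces = []
    k = 0
    z = start
    while z < half:
        keep_parity = 0 if plan.keep_rule == "every-even" else 1
        if k % 2 == keep_parity and -half <= z < half:
            cut_faces.append((z, z + T))
        z += T
        k += 1

    blocks: list[Block] = []
    d = plan.block_point_spacing
    for lo, hi in cut_faces:
        off = rng.uniform(0.0, d, size=2)
        xs = np.arange(-half - d + off[0], half + d, d)
        ys = np.arange(-half - d + off[1], half + d, d)
        X, Y = np.meshgrid(xs, ys)
        pts = np.stack([X.ravel(), Y.ravel()], axis=1)
        hit = (np.abs(pts[:, 0]) < half) & (np.abs(pts[:, 1]) < half)
        zc = lo + plan.block_size / 2.0
        for p in pts[hit]:
            blocks.append(Block(id=len(blocks), center=np.array([p[0], p[1], zc]),
                                size=plan.block_size))
    if len(blocks) > plan.blocks_max:
        # uniform random subsample: a systematic fraction would alias with
        # the short (2-3 column) rows of the point grid and skew coverage
        idx = rng.choice(len(blocks), size=plan.blocks_max, replace=False)
        blocks = [Block(id=j, center=blocks[i].center, size=blocks[i].size)
                  for j, i in enumerate(sorted(idx))]
    if len(blocks) == 0:
        msg = "sampling cascade yielded zero blocks (spacing too coarse?)"
        if plan.strict:
            raise RuntimeError(msg)
        warnings.warn(msg)
    # randomise the processing order: downstream stages cycle the list and
    # would otherwise systematically overuse the first (low-slab, low-y)
    # blocks whenever the section count does not divide evenly
    order = rng.permutation(len(blocks))
    return [Block(id=j, center=blocks[i].center, size=blocks[i].size)
            for j, i in enumerate(order)]


def cut_section_pair(block: Block, mode: str, plan: SamplingPlan,
                     rng: np.random.Generator, phantom: Phantom | None = None,
                     max_retries: int = 20) -> SectionPair:
    """Cut a parallel section pair through a block.

    Orientation is isotropic (normal uniform on the sphere) in IUR mode, the
    z axis otherwise; the pair position is uniform random within the block.
    If a phantom is given, positions whose frame centre falls outside the
    lung region are re-drawn a bounded number of times.
    """
    if mode == "LM_semithin":
        thickness, h = LM_THICKNESS, LM_DISECTOR_HEIGHT
    elif mode == "EM_ultrathin":
        thickness, h = EM_THICKNESS, EM_THICKNESS
    else:
        raise ValueError(f"unknown section mode {mode!r}")

    for _ in range(max_retries):
        if plan.orientation_mode == "IUR":
            normal = geo.random_unit_vectors(rng)
        else:
            normal = np.array([0.0, 0.0, 1.0])
        e1, e2 = geo.plane_basis(normal, rng)
        z1 = rng.uniform(-block.size / 2.0, block.size / 2.0 - h)
        measured = None
        if mode == "EM_ultrathin" and plan.fold_noise_cv > 0:
            fold = 2.0 * thickness * (1.0 + rng.normal(0.0, plan.fold_noise_cv))
            measured = max(fold / 2.0, 0.1 * thickness)
        pair = SectionPair(
            block_id=block.id,
            normal=normal,
            e1=e1,
            e2=e2,
            anchor=block.center,
            z1=z1,
            z2=z1 + h,
            section_thickness=thickness,
            mode=mode,  # type: ignore[arg-type]
            frame=CountingFrame(center=np.zeros(2), side=plan.frame_size - 2 * plan.frame_guard),
            disector_height_measured=measured,
        )
        if phantom is None:
            return pair
        centre_world = pair.section(1).to_world(np.zeros((1, 2)))[0]
        if phantom.contains(centre_world[None, :])[0]:
            return pair
    raise RuntimeError(f"block {block.id}: section fell outside tissue {max_retries} times")


def extract_profiles(section: Section, phantom: Phantom,
                     window_radius: float | None = None,
                     probe_margin: float | None = None) -> ProfileSet:
    """All profiles of the section plane, optionally restricted to solids
    within ``window_radius`` of the plane origin (in-plane distance).

    ``probe_margin`` sets how far beyond the reference cube the counting
    probes may reach (periodic images are included up to that excursion);
    it defaults to the window radius plus the plane offset of the section.
    """
    if probe_margin is None:
        if window_radius is not None:
            half = phantom.lung_side / 2.0
            origin_out = float(np.max(np.maximum(np.abs(section.origin) - half, 0.0)))
            probe_margin = window_radius + origin_out
        else:
            probe_margin = 0.0
    pk = phantom.packed(probe_margin)
    ps = ProfileSet(section=section, phantom=phantom, pk=pk)
    n_vec = section.normal

    def near(centers, radii):
        signed = (centers - section.origin) @ n_vec
        sel = np.abs(signed) < radii
        if window_radius is not None and sel.any():
            inplane = np.linalg.norm(section.to_plane(centers[sel]), axis=1)
            sub = inplane < window_radius + radii[sel]
            idx = np.nonzero(sel)[0][sub]
            sel = np.zeros(len(radii), dtype=bool)
            sel[idx] = True
        return np.nonzero(sel)[0]

    # cells: ellipse sections
    ci = near(pk["cell_centers"], pk["cell_bound"])
    keep, cen2, ax2, ang = [], [], [], []
    for i in ci:
        res = geo.plane_ellipsoid_ellipse(
            pk["cell_centers"][i], pk["cell_M"][i], section.origin, section.e1, section.e2
        )
        if res is None:
            continue
        keep.append(i)
        cen2.append(res[0])
        ax2.append(res[1])
        ang.append(res[2])
    if keep:
        ps.cell_ids = np.array(keep, dtype=int)
        ps.cell_orig = pk["cell_orig"][ps.cell_ids]
        ps.cell_shift = pk["cell_shift"][ps.cell_ids]
        ps.cell_center2d = np.array(cen2)
        ps.cell_axes2d = np.array(ax2)
        ps.cell_angle = np.array(ang)

    def discs(centers, radii):
        idx = near(centers, radii)
        if len(idx) == 0:
            return idx, np.zeros((0, 2)), np.zeros(0)
        signed = (centers[idx] - section.origin) @ n_vec
        r2d = np.sqrt(radii[idx] ** 2 - signed**2)
        c2d = section.to_plane(centers[idx])
        return idx, c2d, r2d

    li, lc, lr = discs(pk["lb_centers"], pk["lb_radii"])
    ps.lb_ids, ps.lb_center2d, ps.lb_radius = li, lc, lr
    ps.lb_cell = pk["lb_cell"][li]
    ni, nc, nr = discs(pk["nuc_centers"], pk["nuc_radii"])
    ps.nuc_cell, ps.nuc_center2d, ps.nuc_radius = ni, nc, nr
    nl, nlc, nlr = discs(pk["nll_centers"], pk["nll_radii"])
    ps.nll_cell, ps.nll_center2d, ps.nll_radius = nl, nlc, nlr
    return ps


def measure_reference_volume(phantom: Phantom, noise_cv: float = 0.0,
                             rng: np.random.Generator | None = None,
                             max_retries: int = 100) -> float:
    """Fluid-displacement style measurement of the lung volume, cm^3.

    Returns ``V(lung) * (1 + eps)`` with ``eps ~ Normal(0, noise_cv)``;
    nonpositive draws are resampled a bounded number of times.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if noise_cv == 0:
        return phantom.lung_volume_cm3
    if rng is None:
        rng = np.random.default_rng()
    for _ in range(max_retries):
        v = phantom.lung_volume_cm3 * (1.0 + rng.normal(0.0, noise_cv))
        if v > 0:
            return v
    raise RuntimeError("reference volume measurement kept returning <= 0")
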