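"""Synthetic 3D lung-tissue phantom with analytic ground truth.

The phantom stands in for a fixed rat lung: a reference volume (a cube whose
volume equals the measured lung volume) containing a suspension of alveolar
epithelial type II (AE2) cells. Each cell is a near-spherical ellipsoid with
one nucleus, exactly one nucleolus (the unique counting unit of the light
microscopic disector), a set of non-overlapping spherical lamellar bodies
(Lb, the surfactant storage organelles) outside the nucleus, and a luminal
surface patch of configurable area fraction (the part of the cell membrane
facing the alveolar space). Every target quantity of the downstream
stereological estimators is computable in closed form from this geometry,
so estimator bias can be measured exactly.

Alveolar architecture (septa, capillaries) is deliberately not modelled:
the estimators only consume profiles and a reference volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import geometry as geo

__all__ = [
    "PhantomConfig",
    "Cell",
    "Phantom",
    "TruthRecord",
    "OverpackedCellError",
    "generate_phantom",
    "ground_truth",
    "make_group_configs",
    "SCENARIOS",
    "expected_cell_surface",
    "expected_lb_mean_volume",
]

UM3_PER_CM3 = 1.0e12


class OverpackedCellError(RuntimeError):
    """Raised when rejection sampling cannot place all organelles in a cell."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic lung.

    Volumes are um^3 except ``lung_volume_cm3``; lengths are um. The lamellar
    body count per cell is negative-binomially distributed with mean
    ``lb_count_mean`` and dispersion ``lb_count_dispersion`` (variance
    ``m + m^2/theta``; ``None`` gives Poisson counts). Individual Lb volumes
    are lognormal with log-space parameters ``lb_volume_logmu`` and
    ``lb_volume_logsigma``; draws are clipped below ``lb_radius_min`` so that
    every Lb is taller than the electron-microscopic disector.
    """

    group_label: str = "control"
    lung_volume_cm3: float = 1.5e-6
    n_cells: int = 300
    cell_volume_mean: float = 500.0
    cell_volume_cv: float = 0.15
    cell_axis_ratios: tuple[float, float, float] = (1.2, 1.0, 1.0 / 1.2)
    nucleus_fraction: float = 0.15
    mito_fraction: float = 0.10
    nucleolus_radius: float = 1.6
    lb_count_mean: float = 120.0
    lb_count_dispersion: Optional[float] = 50.0
    lb_volume_logmu: float = -1.7406
    lb_volume_logsigma: float = 0.6
    lb_radius_min: float = 0.08
    luminal_fraction: float = 0.49
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("luminal_fraction", "nucleus_fraction", "mito_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.luminal_fraction < 1.0:
            raise ValueError("luminal_fraction must lie strictly in (0, 1)")
        lb_frac = self.lb_count_mean * expected_lb_mean_volume(self) / self.cell_volume_mean
        if self.nucleus_fraction + self.mito_fraction + lb_frac >= 1.0:
            raise ValueError("nucleus + mitochondria + expected Lb fractions must be < 1")
        if self.lung_volume_um3 <= self.n_cells * self.cell_volume_mean:
            raise ValueError("lung volume must exceed the total cell volume")
        if self.lb_volume_logsigma < 0 or self.cell_volume_cv < 0:
            raise ValueError("spread parameters must be nonnegative")

    @property
    def lung_volume_um3(self) -> float:
        return self.lung_volume_cm3 * UM3_PER_CM3


def expected_lb_mean_volume(config: PhantomConfig) -> float:
    """Closed-form lognormal mean exp(mu + sigma^2/2) of individual Lb volume."""
    return float(np.exp(config.lb_volume_logmu + 0.5 * config.lb_volume_logsigma**2))


def _unit_shape(config: PhantomConfig):
    """Semi-axis ratios normalised to unit volume factor abc = product."""
    r = np.asarray(config.cell_axis_ratios, dtype=float)
    return r


def expected_cell_surface(config: PhantomConfig) -> float:
    """Expected cell surface area under the configured size distribution.

    Cells share one shape up to a lognormal scale; the surface is the
    unit-shape surface times E[s^2], evaluated with lognormal moments.
    """
    ratios = _unit_shape(config)
    abc = float(np.prod(ratios))
    s_unit = geo.ellipsoid_surface_area(ratios)
    sigma2 = np.log1p(config.cell_volume_cv**2)
    # E[v^(2/3)] for lognormal with mean m: m^(2/3) exp(-sigma2/9)
    ev23 = config.cell_volume_mean ** (2.0 / 3.0) * np.exp(-sigma2 / 9.0)
    es2 = (3.0 / (4.0 * np.pi * abc)) ** (2.0 / 3.0) * ev23
    return float(s_unit * es2)


@dataclass
class Cell:
    """One AE2-like cell: ellipsoid body, nucleus, nucleolus, Lb, luminal cap."""

    id: int
    center: np.ndarray
    axes: np.ndarray
    rotation: np.ndarray  # local -> world
    nucleus_center: np.ndarray
    nucleus_radius: float
    nucleolus_center: np.ndarray
    nucleolus_radius: float
    lb_centers: np.ndarray  # (k, 3) world coordinates
    lb_radii: np.ndarray  # (k,)
    luminal_cos_cap: float  # parameter-space cap around the local +z axis

    @property
    def volume(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.axes))

    @property
    def surface_area(self) -> float:
        ratios = self.axes / self.axes[1]
        return float(geo.ellipsoid_surface_area(ratios) * self.axes[1] ** 2)

    def quadric(self) -> np.ndarray:
        return geo.ellipsoid_quadric(self.axes, self.rotation)

    def local_direction(self, points: np.ndarray) -> np.ndarray:
        """Unit parameter directions u of world surface points."""
        loc = (np.atleast_2d(points) - self.center) @ self.rotation / self.axes
        return loc / np.linalg.norm(loc, axis=1, keepdims=True)

    def is_luminal(self, points: np.ndarray) -> np.ndarray:
        """Whether world points on the cell surface lie in the luminal patch."""
        u = self.local_direction(points)
        return u[:, 2] >= self.luminal_cos_cap


@dataclass
class Phantom:
    """A generated lung: cells plus the reference volume and provenance."""

    cells: list[Cell]
    lung_volume_cm3: float
    config: PhantomConfig
    seed: int
    _packed: dict | None = field(default=None, repr=False, compare=False)

    @property
    def lung_volume_um3(self) -> float:
        return self.lung_volume_cm3 * UM3_PER_CM3

    @property
    def lung_side(self) -> float:
        """Edge length of the cubic reference region, um."""
        return float(self.lung_volume_um3 ** (1.0 / 3.0))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Tissue membership of world points.

        The phantom tissue is periodic (solids crossing a face of the
        reference cube wrap around to the opposite face), so every point is
        tissue; the reference volume is the volume of one period. This keeps
        the content density exactly uniform with no boundary shell, the
        condition under which the sampling cascade is edge-effect free.
        """
        return np.ones(len(np.atleast_2d(points)), dtype=bool)

    def _images(self, centers: np.ndarray, reach: np.ndarray):
        """Periodic images: original rows plus shifted copies near faces.

        Returns (orig_index, shift) arrays covering every image whose
        bounding sphere can intersect the reference cube.
        """
        side = self.lung_side
        half = side / 2.0
        idx_out, shift_out = [], []
        n = len(centers)
        if n == 0:
            return np.zeros(0, dtype=int), np.zeros((0, 3))
        opts = []
        for ax in range(3):
            lo = centers[:, ax] >= half - reach  # near +face -> image at -side
            hi = centers[:, ax] <= -half + reach  # near -face -> image at +side
            opts.append((lo, hi))
        base_idx = np.arange(n)
        for sx in (-1, 0, 1):
            for sy in (-1, 0, 1):
                for sz in (-1, 0, 1):
                    if sx == sy == sz == 0:
                        mask = np.ones(n, dtype=bool)
                    else:
                        mask = np.ones(n, dtype=bool)
                        for ax, s in enumerate((sx, sy, sz)):
                            if s == -1:
                                mask &= opts[ax][0]
                            elif s == 1:
                                mask &= opts[ax][1]
                    if not mask.any():
                        continue
                    idx_out.append(base_idx[mask])
                    shift = np.array([sx, sy, sz], dtype=float) * side
                    shift_out.append(np.tile(shift, (int(mask.sum()), 1)))
        return np.concatenate(idx_out), np.concatenate(shift_out, axis=0)

    def packed(self, margin: float = 0.0) -> dict:
        """Stacked numpy arrays over all cells including periodic images.

        Rows are images (original solids plus wrapped copies near the cube
        faces); ``*_orig`` maps each row to its original cell index and
        ``*_shift`` carries the periodic offset of the image. ``margin`` is
        the maximal distance a sampling probe may reach beyond a face of the
        reference cube: every image that such a probe can touch is included,
        which keeps all counting operations exactly edge-free. Results are
        cached per margin.
        """
        if self._packed is None:
            self._packed = {}
        # quantise upwards so per-section margin jitter reuses one cache entry
        # (a larger margin only adds images and stays exact)
        key = float(np.ceil(float(margin) / 8.0) * 8.0) if margin > 0 else 0.0
        if key not in self._packed:
            self._packed[key] = self._build_packed(key)
        return self._packed[key]

    def _build_packed(self, margin: float) -> dict:
        cells = self.cells
        cc = np.array([c.center for c in cells])
        cb = np.array([c.axes.max() for c in cells])
        ci, cs = self._images(cc, cb + margin)
        nc = np.array([c.nucleus_center for c in cells])
        nr = np.array([c.nucleus_radius for c in cells])
        ni, ns = self._images(nc, nr + margin)
        lc = np.array([c.nucleolus_center for c in cells])
        lr = np.array([c.nucleolus_radius for c in cells])
        li, ls = self._images(lc, lr + margin)
        lbc = np.concatenate([c.lb_centers for c in cells])
        lbr = np.concatenate([c.lb_radii for c in cells])
        lb_cell = np.concatenate(
            [np.full(len(c.lb_radii), c.id, dtype=int) for c in cells]
        )
        bi, bs = self._images(lbc, lbr + margin)
        M = np.array([c.quadric() for c in cells])
        axes = np.array([c.axes for c in cells])
        return {
            "cell_centers": cc[ci] + cs,
            "cell_axes": axes[ci],
            "cell_M": M[ci],
            "cell_bound": cb[ci],
            "cell_orig": ci,
            "cell_shift": cs,
            "nuc_centers": nc[ni] + ns,
            "nuc_radii": nr[ni],
            "nll_centers": lc[li] + ls,
            "nll_radii": lr[li],
            "nll_orig": li,
            "nll_shift": ls,
            "lb_centers": lbc[bi] + bs,
            "lb_radii": lbr[bi],
            "lb_cell": lb_cell[bi],
            "lb_orig": bi,
            "n_lb_true": len(lbr),
        }

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": "lbstereo-phantom-v1",
            "seed": self.seed,
            "lung_volume_cm3": self.lung_volume_cm3,
            "config": asdict(self.config),
            "cells": [
                {
                    "id": c.id,
                    "center": c.center.tolist(),
                    "axes": c.axes.tolist(),
                    "rotation": c.rotation.tolist(),
                    "nucleus_center": c.nucleus_center.tolist(),
                    "nucleus_radius": c.nucleus_radius,
                    "nucleolus_center": c.nucleolus_center.tolist(),
                    "nucleolus_radius": c.nucleolus_radius,
                    "lb_centers": c.lb_centers.tolist(),
                    "lb_radii": c.lb_radii.tolist(),
                    "luminal_cos_cap": c.luminal_cos_cap,
                }
                for c in self.cells
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "Phantom":
        cfg = PhantomConfig(**{**d["config"], "cell_axis_ratios": tuple(d["config"]["cell_axis_ratios"])})
        cells = [
            Cell(
                id=cd["id"],
                center=np.array(cd["center"]),
                axes=np.array(cd["axes"]),
                rotation=np.array(cd["rotation"]),
                nucleus_center=np.array(cd["nucleus_center"]),
                nucleus_radius=cd["nucleus_radius"],
                nucleolus_center=np.array(cd["nucleolus_center"]),
                nucleolus_radius=cd["nucleolus_radius"],
                lb_centers=np.array(cd["lb_centers"]).reshape(-1, 3),
                lb_radii=np.array(cd["lb_radii"]),
                luminal_cos_cap=cd["luminal_cos_cap"],
            )
            for cd in d["cells"]
        ]
        return cls(cells=cells, lung_volume_cm3=d["lung_volume_cm3"], config=cfg, seed=d["seed"])


@dataclass(frozen=True)
class TruthRecord:
    """Analytic ground truth of every downstream estimand (units in names).

    ``vbar`` denotes number-weighted means; surfaces are per-cell means.
    """

    N_AE2_lung: float
    vbar_AE2: float  # um^3
    N_Lb_per_cell: float
    vbar_Lb: float  # um^3
    V_Lb_per_cell: float  # um^3
    V_Lb_lung: float  # um^3
    S_lumen_AE2: float  # um^2
    S_cell_AE2: float  # um^2
    S_Lb_AE2: float  # um^2
    V_V_Lb_AE2: float  # dimensionless
    N_V_Lb_AE2: float  # um^-3


# ---------------------------------------------------------------------------


def _sample_in_ellipsoid(rng, n, axes):
    """Uniform points in an axis-aligned ellipsoid (local coordinates)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(size=n) ** (1.0 / 3.0)
    return v * r[:, None] * np.asarray(axes)


def _inside_shrunk(points, axes, margin):
    """Sufficient containment test for a sphere of radius ``margin`` at each
    point: the point lies in the ellipsoid scaled by ``1 - margin/c`` with
    ``c`` the smallest semi-axis. Exactly sufficient by convexity
    (``sE + (1-s) B(0, c)`` is contained in ``E``)."""
    axes = np.asarray(axes, dtype=float)
    s = 1.0 - np.atleast_1d(margin) / axes.min()
    g = np.sqrt(np.sum((np.atleast_2d(points) / axes) ** 2, axis=1))
    return g <= s


def _greedy_nonoverlap(cand_pos, cand_r, kept_pos, kept_r, box: float | None = None):
    """Greedy maximal non-overlapping subset of candidates, in index order.

    Previously kept spheres always win. With ``box``, distances follow the
    minimum-image convention of a periodic cube of that side (coordinates
    centred on the origin). Returns indices of accepted candidates.
    """
    m = len(cand_r)
    if m == 0:
        return np.array([], dtype=int)
    all_pos = np.vstack([kept_pos, cand_pos]) if len(kept_r) else cand_pos
    all_r = np.concatenate([kept_r, cand_r]) if len(kept_r) else cand_r
    k0 = len(kept_r)
    if box is not None:
        tree = cKDTree(np.mod(all_pos + box / 2.0, box), boxsize=box)
    else:
        tree = cKDTree(all_pos)
    pairs = tree.query_pairs(2.0 * all_r.max(), output_type="ndarray")
    rejected = np.zeros(len(all_r), dtype=bool)
    if len(pairs):
        delta = all_pos[pairs[:, 0]] - all_pos[pairs[:, 1]]
        if box is not None:
            delta -= box * np.round(delta / box)
        d = np.linalg.norm(delta, axis=1)
        overlap = d < all_r[pairs[:, 0]] + all_r[pairs[:, 1]]
        pairs = pairs[overlap]
        pairs.sort(axis=1)
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        for i, j in pairs[order]:
            if j < k0:
                continue  # two kept spheres never overlap
            if not rejected[i]:
                rejected[j] = True
    return np.nonzero(~rejected[k0:])[0]


try:  # sequential-insertion kernel; the hot loop of phantom generation
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    raise


@njit(cache=True)
def _allowed_radius(pts, axes, nuc_center, nuc_radius):
    """Largest sphere radius placeable at each point: inside the cell by the
    scaled-ellipsoid criterion (sufficient by convexity: a sphere of radius
    ``(1 - s) c`` centred anywhere in ``s E`` lies in ``E``, with ``c`` the
    smallest semi-axis) and clear of the nucleus."""
    m = pts.shape[0]
    out = np.empty(m)
    amin = min(axes[0], min(axes[1], axes[2]))
    for i in range(m):
        s = 0.0
        for j in range(3):
            t = pts[i, j] / axes[j]
            s += t * t
        r_cell = amin * (1.0 - np.sqrt(s))
        dx = pts[i, 0] - nuc_center[0]
        dy = pts[i, 1] - nuc_center[1]
        dz = pts[i, 2] - nuc_center[2]
        r_nuc = np.sqrt(dx * dx + dy * dy + dz * dz) - nuc_radius
        out[i] = min(r_cell, r_nuc)
    return out

@njit(cache=True)
def _fill_kernel(cand, allowed, radii, out_pos, used):
    """Place spheres largest-first: for each radius take the first unused
    candidate that tolerates it and overlaps no already placed sphere.
    Returns the number of spheres placed (== len(radii) on success)."""
    k = radii.shape[0]
    m = cand.shape[0]
    n_placed = 0
    for i in range(k):
        r = radii[i]
        placed_here = -1
        for j in range(m):
            if used[j] or allowed[j] < r:
                continue
            ok = True
            for p in range(n_placed):
                dx = cand[j, 0] - out_pos[p, 0]
                dy = cand[j, 1] - out_pos[p, 1]
                dz = cand[j, 2] - out_pos[p, 2]
                rr = r + out_pos[p, 3]
                if dx * dx + dy * dy + dz * dz < rr * rr:
                    ok = False
                    break
            if ok:
                placed_here = j
                break
        if placed_here < 0:
            return n_placed
        used[placed_here] = True
        out_pos[n_placed, 0] = cand[placed_here, 0]
        out_pos[n_placed, 1] = cand[placed_here, 1]
        out_pos[n_placed, 2] = cand[placed_here, 2]
        out_pos[n_placed, 3] = r
        n_placed += 1
    return n_placed


def _place_lamellar_bodies(rng, cell_axes, nuc_center_local, nuc_radius, radii, cell_id,
                           max_rounds: int = 6):
    """Rejection-sample non-overlapping Lb spheres inside the cell, outside
    the nucleus. Radii are placed largest-first to ease packing."""
    radii = np.sort(np.asarray(radii, dtype=float))[::-1]
    k = len(radii)
    if k == 0:
        return np.zeros((0, 3)), np.zeros(0)
    m = max(6 * k, 64)
    for round_ in range(max_rounds):
        cand = np.ascontiguousarray(_sample_in_ellipsoid(rng, m, cell_axes))
        allowed = _allowed_radius(cand, np.asarray(cell_axes, dtype=float),
                                  np.asarray(nuc_center_local, dtype=float),
                                  float(nuc_radius))
        out = np.zeros((k, 4))
        used = np.zeros(m, dtype=np.bool_)
        n_placed = _fill_kernel(np.ascontiguousarray(cand), allowed, radii, out, used)
        if n_placed == k:
            return out[:, :3].copy(), out[:, 3].copy()
        m *= 3  # overpacked round: retry with a denser candidate pool
    raise OverpackedCellError(
        f"cell {cell_id}: could not place all {k} lamellar bodies "
        "(overpacked cell)"
    )


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Generate a phantom lung, bit-reproducible for a fixed config and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ratios = _unit_shape(config)
    abc = float(np.prod(ratios))
    n = config.n_cells
    half = config.lung_volume_um3 ** (1.0 / 3.0) / 2.0

    # cell sizes: lognormal volumes -> shared shape scaled per cell
    sigma2 = np.log1p(config.cell_volume_cv**2)
    mu = np.log(config.cell_volume_mean) - sigma2 / 2.0
    volumes = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    scales = (3.0 * volumes / (4.0 * np.pi * abc)) ** (1.0 / 3.0)
    bounds = scales * ratios.max()

    # cell centres: uniform over the whole (periodic) cube, pairwise
    # non-overlapping by bounding spheres under the minimum-image metric;
    # placed largest-first (cells are reordered; sizes stay exchangeable)
    side = 2.0 * half
    order = np.argsort(bounds)[::-1]
    volumes, scales, bounds = volumes[order], scales[order], bounds[order]
    centers = np.zeros((n, 3))
    open_slots = np.arange(n)
    kept_pos = np.zeros((0, 3))
    kept_r = np.zeros(0)
    for _ in range(400):
        if len(open_slots) == 0:
            break
        rem_b = bounds[open_slots]
        cand = rng.uniform(-half, half, size=(len(rem_b), 3))
        acc = _greedy_nonoverlap(cand, rem_b, kept_pos, kept_r, box=side)
        centers[open_slots[acc]] = cand[acc]
        kept_pos = np.vstack([kept_pos, cand[acc]])
        kept_r = np.concatenate([kept_r, rem_b[acc]])
        open_slots = np.delete(open_slots, acc)
    if len(open_slots):
        raise OverpackedCellError("lung volume too small to place all cells")

    # per-cell organelles
    lum_cos = float(np.cos(geo.solve_cap_angle(ratios, config.luminal_fraction)))
    counts = _draw_lb_counts(rng, config, n)
    cells: list[Cell] = []
    for i in range(n):
        axes = scales[i] * ratios
        R = geo.random_rotation_matrix(rng)
        nuc_r = geo.radius_from_volume(config.nucleus_fraction * volumes[i])
        if nuc_r >= axes.min():
            raise OverpackedCellError(f"cell {i}: nucleus does not fit")
        max_off = 0.5 * (axes.min() - nuc_r)
        nuc_local = geo.random_unit_vectors(rng) * rng.uniform(0.0, max_off)
        if not _inside_shrunk(nuc_local[None, :], axes, nuc_r)[0]:
            nuc_local = np.zeros(3)
        nll_r = config.nucleolus_radius
        if nll_r >= nuc_r:
            raise OverpackedCellError(
                f"cell {i}: nucleolus (r={nll_r}) does not fit in nucleus (r={nuc_r:.2f})"
            )
        nll_local = nuc_local + geo.random_unit_vectors(rng) * rng.uniform(
            0.0, 0.8 * (nuc_r - nll_r)
        )
        lb_vol = rng.lognormal(config.lb_volume_logmu, config.lb_volume_logsigma, counts[i])
        lb_r = np.maximum(geo.radius_from_volume(lb_vol), config.lb_radius_min)
        lb_local, lb_r = _place_lamellar_bodies(rng, axes, nuc_local, nuc_r, lb_r, i)
        cells.append(
            Cell(
                id=i,
                center=centers[i],
                axes=axes,
                rotation=R,
                nucleus_center=centers[i] + R @ nuc_local,
                nucleus_radius=float(nuc_r),
                nucleolus_center=centers[i] + R @ nll_local,
                nucleolus_radius=float(nll_r),
                lb_centers=centers[i] + lb_local @ R.T,
                lb_radii=lb_r,
                luminal_cos_cap=lum_cos,
            )
        )
    return Phantom(cells=cells, lung_volume_cm3=config.lung_volume_cm3, config=config,
                   seed=config.seed)


def _draw_lb_counts(rng, config, n):
    m = config.lb_count_mean
    theta = config.lb_count_dispersion
    if theta is None or not np.isfinite(theta):
        return rng.poisson(m, size=n)
    lam = rng.gamma(shape=theta, scale=m / theta, size=n)
    return rng.poisson(lam)


def ground_truth(phantom: Phantom) -> TruthRecord:
    """Every estimand computed analytically from the geometry; no sampling."""
    cells = phantom.cells
    n = len(cells)
    cell_vols = np.array([c.volume for c in cells])
    cell_surf = np.array([c.surface_area for c in cells])
    lb_r = np.concatenate([c.lb_radii for c in cells])  # originals, no images
    lb_vol_total = float(geo.sphere_volume(lb_r).sum())
    lb_n_total = len(lb_r)
    lb_surf_total = float(geo.sphere_surface(lb_r).sum())
    frac = phantom.config.luminal_fraction
    return TruthRecord(
        N_AE2_lung=float(n),
        vbar_AE2=float(cell_vols.mean()),
        N_Lb_per_cell=lb_n_total / n,
        vbar_Lb=lb_vol_total / lb_n_total if lb_n_total else 0.0,
        V_Lb_per_cell=lb_vol_total / n,
        V_Lb_lung=lb_vol_total,
        S_lumen_AE2=float(frac * cell_surf.mean()),
        S_cell_AE2=float(cell_surf.mean()),
        S_Lb_AE2=lb_surf_total / n,
        V_V_Lb_AE2=lb_vol_total / cell_vols.sum(),
        N_V_Lb_AE2=lb_n_total / cell_vols.sum(),
    )


# -- group scenarios ---------------------------------------------------------


def _scenario_ir_shift(base: PhantomConfig, seed_ctrl: int, seed_ir: int):
    """Ischemia/reperfusion-like effect: fewer but larger Lb (total Lb volume
    conserved), luminal surface raised by the expected sphere-model membrane
    shift; cell number and size identical across groups."""
    import dataclasses

    count_ratio = 80.0 / 120.0
    ctrl = dataclasses.replace(base, group_label="control", seed=seed_ctrl)
    vbar_c = expected_lb_mean_volume(ctrl)
    vbar_ir = vbar_c / count_ratio
    # sphere-model mean Lb surface from mean volume
    sbar = lambda v: float((36.0 * np.pi) ** (1.0 / 3.0) * v ** (2.0 / 3.0))
    s_lb_c = ctrl.lb_count_mean * sbar(vbar_c)
    s_lb_ir = ctrl.lb_count_mean * count_ratio * sbar(vbar_ir)
    delta = s_lb_c - s_lb_ir  # membrane released by exocytosis
    s_cell = expected_cell_surface(ctrl)
    lf_ir = ctrl.luminal_fraction + delta / s_cell
    if not 0.0 < lf_ir < 1.0:
        raise ValueError("luminal fraction shift leaves (0, 1); adjust base config")
    ir = dataclasses.replace(
        base,
        group_label="IR",
        seed=seed_ir,
        lb_count_mean=base.lb_count_mean * count_ratio,
        lb_volume_logmu=base.lb_volume_logmu + np.log(1.0 / count_ratio),
        luminal_fraction=lf_ir,
    )
    return ctrl, ir


def _scenario_null(base: PhantomConfig, seed_ctrl: int, seed_ir: int):
    """Negative control: both groups drawn from identical distributions."""
    import dataclasses

    return (
        dataclasses.replace(base, group_label="control", seed=seed_ctrl),
        dataclasses.replace(base, group_label="IR", seed=seed_ir),
    )


SCENARIOS = {"ir-shift": _scenario_ir_shift, "null": _scenario_null}


def make_group_configs(base: PhantomConfig, scenario_name: str = "ir-shift",
                       seed_ctrl: int | None = None, seed_ir: int | None = None):
    """Control and treated configs for a named two-group scenario."""
    if scenario_name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {scenario_name!r}; known: {sorted(SCENARIOS)}"
        )
    if seed_ctrl is None:
        seed_ctrl = base.seed
    if seed_ir is None:
        seed_ir = base.seed + 1
    return SCENARIOS[scenario_name](base, seed_ctrl, seed_ir)
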