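"""Sampling cascade: SURS uniformity, section geometry, profile extraction."""

import numpy as np
import pytest

from lbstereo import geometry as geo
from lbstereo.microtome import (CountingFrame, SamplingPlan, Section,
                                cut_section_pair, default_plan_for,
                                extract_profiles, measure_reference_volume,
                                sample_blocks)
from lbstereo.phantom import Phantom, PhantomConfig, generate_phantom

from conftest import sphere_cell


def test_plan_validation():
    with pytest.raises(ValueError):
        SamplingPlan(slab_thickness=0.0).validate()
    with pytest.raises(ValueError):
        SamplingPlan(blocks_min=8, blocks_max=3).validate()


def test_block_yield_matches_bench_range(small_phantom):
    """The scaled default plan yields about 5-11 blocks per lung."""
    counts = []
    for seed in range(40):
        plan = default_plan_for(small_phantom, seed=seed)
        counts.append(len(sample_blocks(small_phantom, plan)))
    counts = np.array(counts)
    assert 5 <= counts.mean() <= 11
    assert (counts <= plan.blocks_max).all()
    assert np.mean((counts >= 5) & (counts <= 11)) >= 0.8


def test_surs_block_positions_uniform(small_phantom):
    """Monte-Carlo over seeds: octant inclusion frequencies agree to 3 SE.

    Blocks within one lung are clustered (they share slab phases and grid
    offsets), so the standard error comes from the spread of per-seed octant
    proportions, not from a binomial on pooled blocks.
    """
    plan = default_plan_for(small_phantom)
    half = small_phantom.lung_side / 2.0
    props = []
    for seed in range(1500):
        rng = np.random.default_rng(seed)
        centers = np.asarray([b.center for b in sample_blocks(small_phantom, plan, rng)])
        # blocks near the top face extend past it into the periodic tissue;
        # wrap their centres into the reference period before classifying
        centers = (centers + half) % small_phantom.lung_side - half
        octant = (centers[:, 0] > 0) * 4 + (centers[:, 1] > 0) * 2 + (centers[:, 2] > 0)
        props.append(np.bincount(octant, minlength=8) / len(octant))
    props = np.asarray(props)
    mean = props.mean(axis=0)
    sem = props.std(axis=0, ddof=1) / np.sqrt(len(props))
    assert np.all(np.abs(mean - 0.125) < 3.5 * sem)


def test_degenerate_spacing_yields_few_blocks(small_phantom):
    plan = default_plan_for(
        small_phantom, block_point_spacing=10 * small_phantom.lung_side,
        slab_thickness=4 * small_phantom.lung_side,
    )
    got_zero = False
    import warnings as _w
    for seed in range(60):
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            blocks = sample_blocks(small_phantom, plan, np.random.default_rng(seed))
        assert len(blocks) <= 1
        if not blocks:
            got_zero = True
            strict = default_plan_for(
                small_phantom, block_point_spacing=10 * small_phantom.lung_side,
                slab_thickness=4 * small_phantom.lung_side, strict=True,
            )
            with pytest.raises(RuntimeError):
                sample_blocks(small_phantom, strict, np.random.default_rng(seed))
    assert got_zero


def test_iur_normals_uniform_on_sphere(small_phantom, rng):
    plan = default_plan_for(small_phantom)
    blocks = sample_blocks(small_phantom, plan, rng)
    normals = np.array([
        cut_section_pair(blocks[0], "EM_ultrathin", plan, rng).normal
        for _ in range(4000)
    ])
    assert np.allclose(np.linalg.norm(normals, axis=1), 1.0)
    assert np.all(np.abs(normals.mean(axis=0)) < 3.0 / np.sqrt(len(normals)))
    octant = (normals[:, 0] > 0) * 4 + (normals[:, 1] > 0) * 2 + (normals[:, 2] > 0)
    counts = np.bincount(octant, minlength=8)
    from scipy.stats import chisquare

    assert chisquare(counts).pvalue > 1e-4


def test_section_pair_heights(small_phantom, rng):
    plan = default_plan_for(small_phantom)
    blocks = sample_blocks(small_phantom, plan, rng)
    lm = cut_section_pair(blocks[0], "LM_semithin", plan, rng)
    assert lm.disector_height == pytest.approx(3.0)
    assert lm.section_thickness == pytest.approx(1.0)
    em = cut_section_pair(blocks[0], "EM_ultrathin", plan, rng)
    assert em.disector_height == pytest.approx(0.1)
    assert em.section(2).origin == pytest.approx(
        em.section(1).origin + em.disector_height * em.normal
    )


def test_axis_aligned_fixed_seed_reproducible(small_phantom):
    plan = default_plan_for(small_phantom, orientation_mode="axis-aligned")
    blocks = sample_blocks(small_phantom, plan, np.random.default_rng(0))
    a = cut_section_pair(blocks[0], "LM_semithin", plan, np.random.default_rng(5))
    b = cut_section_pair(blocks[0], "LM_semithin", plan, np.random.default_rng(5))
    assert np.allclose(a.normal, [0, 0, 1])
    assert a.z1 == b.z1 and np.allclose(a.e1, b.e1)


def test_fold_rule_height(small_phantom):
    """Zero fold-measurement noise gives h equal to the true thickness; with
    noise the measured heights scatter with the configured CV."""
    plan = default_plan_for(small_phantom, fold_noise_cv=0.0)
    rng = np.random.default_rng(2)
    blocks = sample_blocks(small_phantom, plan, rng)
    pair = cut_section_pair(blocks[0], "EM_ultrathin", plan, rng)
    assert pair.disector_height == pytest.approx(pair.section_thickness)
    noisy = default_plan_for(small_phantom, fold_noise_cv=0.05)
    hs = np.array([
        cut_section_pair(blocks[0], "EM_ultrathin", noisy, rng).disector_height
        for _ in range(3000)
    ])
    assert hs.mean() == pytest.approx(0.1, rel=0.01)
    cv = hs.std(ddof=1) / hs.mean()
    assert cv == pytest.approx(0.05, rel=0.15)


def _central_section(normal=(0.0, 0.0, 1.0), z=0.0):
    n = np.asarray(normal, dtype=float)
    e1, e2 = geo.plane_basis(n)
    return Section(origin=z * n, normal=n, e1=e1, e2=e2, thickness=0.0)


def test_profile_of_sphere_through_center():
    cell = sphere_cell(radius=5.0, lb_radii=[1.0])
    # put one Lb exactly at a known offset
    cell.lb_centers = np.array([[0.0, 0.0, 0.8]])
    cell.lb_radii = np.array([1.0])
    ph = Phantom(cells=[cell], lung_volume_cm3=1e-7, config=PhantomConfig(n_cells=1),
                 seed=0)
    ps = extract_profiles(_central_section(), ph)
    assert len(ps.cell_ids) == 1
    assert ps.cell_axes2d[0] == pytest.approx([5.0, 5.0])
    assert ps.lb_radius[0] == pytest.approx(0.6)  # sqrt(1 - 0.8^2)


def test_tangent_solids_do_not_profile():
    cell = sphere_cell(radius=5.0)
    ph = Phantom(cells=[cell], lung_volume_cm3=1e-7, config=PhantomConfig(n_cells=1),
                 seed=0)
    ps = extract_profiles(_central_section(z=5.0), ph)
    assert len(ps.cell_ids) == 0


def test_profile_area_matches_voxel_oracle(small_phantom):
    """Ellipse profile area vs 2D voxelisation of the cut at 0.05 um."""
    sec = _central_section(normal=(0.3, -0.5, 0.81))
    ps = extract_profiles(sec, small_phantom)
    assert len(ps.cell_ids) > 0
    i = int(np.argmax(ps.cell_axes2d[:, 0]))
    area_closed = np.pi * ps.cell_axes2d[i, 0] * ps.cell_axes2d[i, 1]
    h = 0.05
    c2, a2 = ps.cell_center2d[i], ps.cell_axes2d[i, 0] + h
    xs = np.arange(c2[0] - a2, c2[0] + a2, h)
    ys = np.arange(c2[1] - a2, c2[1] + a2, h)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts2 = np.stack([X.ravel(), Y.ravel()], axis=1)
    world = sec.to_world(pts2)
    row = ps.cell_ids[i]
    pk = small_phantom.packed()
    M = pk["cell_M"][row]
    rel = world - pk["cell_centers"][row]
    inside = np.einsum("ij,jk,ik->i", rel, M, rel) <= 1.0
    assert inside.sum() * h * h == pytest.approx(area_closed, rel=0.01)


def test_reference_volume_measurement(small_phantom, rng):
    assert measure_reference_volume(small_phantom, 0.0) == pytest.approx(
        small_phantom.lung_volume_cm3
    )
    draws = np.array([
        measure_reference_volume(small_phantom, 0.02, rng) for _ in range(4000)
    ])
    cv = draws.std(ddof=1) / draws.mean()
    se = 0.02 / np.sqrt(2 * len(draws))
    assert abs(cv - 0.02) < 3 * se
    with pytest.raises(ValueError):
        measure_reference_volume(small_phantom, -0.1)


# -- the unbiased counting frame --------------------------------------------


def test_frame_tiling_counts_each_disc_exactly_once(rng):
    """Any disc is accepted by exactly one frame of a tessellation."""
    side = 10.0
    frames = [
        CountingFrame(center=np.array([i * side, j * side]), side=side)
        for i in range(-2, 3) for j in range(-2, 3)
    ]
    for _ in range(300):
        c = rng.uniform(-side, side, size=2)
        r = rng.uniform(0.05, 3.0)
        hits = sum(bool(f.accepts_discs(c[None, :], np.array([r]))[0]) for f in frames)
        assert hits == 1, (c, r)


def test_frame_effective_area_equals_frame_area(rng):
    """The frame rule's acceptance region has exactly the frame's area."""
    frame = CountingFrame(center=np.zeros(2), side=8.0)
    r = 2.5
    span = frame.side / 2 + 2 * r  # acceptance region is contained well inside
    n = 200_000
    centers = rng.uniform(-span, span, size=(n, 2))
    acc = frame.accepts_discs(centers, np.full(n, r))
    est_area = acc.mean() * (2 * span) ** 2
    se_area = np.sqrt(acc.mean() * (1 - acc.mean()) / n) * (2 * span) ** 2
    assert abs(est_area - frame.area) < 3 * se_area
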