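"""Estimators against closed-form and Monte-Carlo oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lbstereo import geometry as geo
from lbstereo import stereology as ste
from lbstereo.microtome import (CountingFrame, Section, SectionPair,
                                extract_profiles)
from lbstereo.phantom import Phantom, PhantomConfig, generate_phantom

from conftest import sphere_cell


def _single_cell_phantom(radius=5.0, luminal_fraction=0.5, lb_radii=()):
    cell = sphere_cell(radius=radius, lb_radii=lb_radii,
                       luminal_fraction=luminal_fraction)
    cfg = PhantomConfig(n_cells=1, luminal_fraction=luminal_fraction)
    return Phantom(cells=[cell], lung_volume_cm3=1.0e-7, config=cfg, seed=0)


def _section(normal, origin):
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    e1, e2 = geo.plane_basis(n)
    return Section(origin=np.asarray(origin, dtype=float), normal=n,
                   e1=e1, e2=e2, thickness=0.0)


# -- point counting ----------------------------------------------------------


def test_count_points_empty_section(rng):
    ph = _single_cell_phantom()
    sec = _section([0, 0, 1], [0, 0, 20.0])  # far above the cell
    ps = extract_profiles(sec, ph)
    frame = CountingFrame(center=np.zeros(2), side=10.0)
    grid = ste.TestSystem(spacing=1.0).realize(rng)
    p_struct, p_ref = ste.count_points(ps, grid, frame, "cell", "lung")
    assert p_struct == 0 and p_ref > 0


def test_count_points_disc_area_ratio(rng):
    """Fine grid: P(cell)/P(lung) approaches (pi r^2) / frame area."""
    ph = _single_cell_phantom(radius=5.0)
    sec = _section([0, 0, 1], [0, 0, 0])
    ps = extract_profiles(sec, ph)
    frame = CountingFrame(center=np.zeros(2), side=16.0)
    ratios = []
    gs = ste.TestSystem(spacing=0.2)
    for _ in range(30):
        grid = gs.realize(rng)
        p_struct, p_ref = ste.count_points(ps, grid, frame, "cell", "lung")
        ratios.append(p_struct / p_ref)
    expect = np.pi * 25.0 / frame.area
    assert np.mean(ratios) == pytest.approx(expect, rel=0.02)


def test_count_points_rejects_non_nested_pair(rng):
    ph = _single_cell_phantom()
    ps = extract_profiles(_section([0, 0, 1], [0, 0, 0]), ph)
    frame = CountingFrame(center=np.zeros(2), side=10.0)
    grid = ste.TestSystem(spacing=1.0).realize(rng)
    with pytest.raises(ValueError):
        ste.count_points(ps, grid, frame, "cell", "lb")
    with pytest.raises(RuntimeError):
        ste.count_points(ps, ste.TestSystem(spacing=1.0).fixed(), frame,
                         "cell", "lung", strict=True)


# -- intersection counting ---------------------------------------------------


def test_count_intersections_empty(rng):
    ph = _single_cell_phantom()
    ps = extract_profiles(_section([0, 0, 1], [0, 0, 20.0]), ph)
    frame = CountingFrame(center=np.zeros(2), side=10.0)
    grid = ste.TestSystem(spacing=1.0).realize(rng)
    assert ste.count_intersections(ps, grid, frame, "cell") == 0


def test_count_intersections_circle_buffon(rng):
    """E[I] for a circle of circumference L under a line grid of spacing d
    with random rotation and offset is 2 L / (pi d)."""
    ph = _single_cell_phantom(radius=5.0)
    sec = _section([0, 0, 1], [0, 0, 0])
    ps = extract_profiles(sec, ph)
    frame = CountingFrame(center=np.zeros(2), side=16.0)
    gs = ste.TestSystem(spacing=1.0)
    counts = [
        ste.count_intersections(ps, gs.realize(rng), frame, "cell")
        for _ in range(600)
    ]
    counts = np.array(counts, dtype=float)
    expect = 2.0 * (2 * np.pi * 5.0) / (np.pi * gs.spacing)
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - expect) <= 3 * se
    assert counts.mean() == pytest.approx(expect, rel=0.03)


def test_intersections_scale_with_grid_density(rng):
    ph = _single_cell_phantom(radius=5.0)
    ps = extract_profiles(_section([0, 0, 1], [0, 0, 0]), ph)
    frame = CountingFrame(center=np.zeros(2), side=16.0)
    coarse = np.mean([
        ste.count_intersections(ps, ste.TestSystem(2.0).realize(rng), frame, "cell")
        for _ in range(300)
    ])
    fine = np.mean([
        ste.count_intersections(ps, ste.TestSystem(1.0).realize(rng), frame, "cell")
        for _ in range(300)
    ])
    assert fine / coarse == pytest.approx(2.0, rel=0.1)


# -- physical disector -------------------------------------------------------


def _pair(z1, h, frame_side=40.0):
    return SectionPair(
        block_id=0, normal=np.array([0.0, 0.0, 1.0]),
        e1=np.array([1.0, 0.0, 0.0]), e2=np.array([0.0, 1.0, 0.0]),
        anchor=np.zeros(3), z1=z1, z2=z1 + h, section_thickness=0.1,
        mode="EM_ultrathin", frame=CountingFrame(center=np.zeros(2), side=frame_side),
    )


def test_disector_no_event_when_present_in_both():
    ph = _single_cell_phantom(lb_radii=[0.5])
    ph.cells[0].lb_centers = np.array([[0.0, 0.0, 0.0]])
    ph.cells[0].lb_radii = np.array([0.5])
    ph._packed = None
    res = ste.physical_disector(_pair(-0.1, 0.2), ph, "lb")
    assert res.Q_total == 0


def test_disector_constructed_single_event():
    """Sphere intersecting only the reference plane counts once, one way."""
    ph = _single_cell_phantom(lb_radii=[0.3])
    ph.cells[0].lb_centers = np.array([[0.0, 0.0, 0.0]])
    ph.cells[0].lb_radii = np.array([0.3])
    ph._packed = None
    res = ste.physical_disector(_pair(-0.1, 0.5), ph, "lb")
    assert (res.Q_dir1, res.Q_dir2) == (1, 0)
    res2 = ste.physical_disector(_pair(-0.4, 0.5), ph, "lb")
    assert (res2.Q_dir1, res2.Q_dir2) == (0, 1)


def test_disector_errors():
    ph = _single_cell_phantom()
    with pytest.raises(ValueError):
        ste.physical_disector(_pair(0.0, 0.1), ph, "mitochondrion")


def test_disector_counts_number_not_size(rng):
    """Doubling every Lb radius leaves the expected event count unchanged."""
    cfg = PhantomConfig(n_cells=30, lung_volume_cm3=1.5e-7,
                        lb_count_mean=40.0, seed=9)
    ph = generate_phantom(cfg)
    import copy

    big = copy.deepcopy(ph)
    for c in big.cells:
        c.lb_radii = c.lb_radii * 2.0  # overlap is irrelevant for counting
    big._packed = None

    def mean_q(phantom):
        qs = []
        side = phantom.lung_side
        for _ in range(500):
            z = rng.uniform(-side / 2, side / 2)
            pair = _pair(z, 0.1, frame_side=side / 2)
            qs.append(ste.physical_disector(pair, phantom, "lb").Q_total)
        return np.array(qs, dtype=float)

    qa, qb = mean_q(ph), mean_q(big)
    se = np.sqrt(qa.var(ddof=1) / len(qa) + qb.var(ddof=1) / len(qb))
    assert abs(qa.mean() - qb.mean()) < 3 * se


def test_estimate_N_V_formula_and_errors():
    # 10 events, both directions, h = 3 um, a(p) = 100 um^2, 50 points
    got = ste.estimate_N_V(10, 50, 100.0, 3.0, both_directions=True)
    assert got == pytest.approx(10 / (2 * 3 * 100 * 50), rel=1e-12)
    assert got == pytest.approx(3.33e-4, rel=2e-3)
    assert ste.estimate_N_V(0, 50, 100.0, 3.0) == 0.0
    with pytest.raises(ZeroDivisionError):
        ste.estimate_N_V(10, 0, 100.0, 3.0)


# -- planar rotator ----------------------------------------------------------


def test_rotator_sphere_through_center_analytic():
    """Fine spacing on a central section recovers (4/3) pi R^3 to 0.5%."""
    cell = sphere_cell(radius=2.0)
    sec = _section([0, 0, 1], [0, 0, 0])
    v = ste.planar_rotator(sec, cell, np.zeros(2), axis_angle=0.7,
                           line_spacing=0.01, start=0.25)
    assert v == pytest.approx(4 / 3 * np.pi * 8.0, rel=0.005)


def test_rotator_ellipsoid_iur_mean_matches_volume(rng):
    """Mean over IUR sections through the centroid equals (4/3) pi abc."""
    from lbstereo.phantom import Cell

    cell = Cell(id=0, center=np.zeros(3), axes=np.array([2.0, 3.0, 4.0]),
                rotation=np.eye(3), nucleus_center=np.zeros(3), nucleus_radius=0.5,
                nucleolus_center=np.zeros(3), nucleolus_radius=0.1,
                lb_centers=np.zeros((0, 3)), lb_radii=np.zeros(0),
                luminal_cos_cap=0.0)
    vols = []
    for _ in range(4000):
        n = geo.random_unit_vectors(rng)
        sec = _section(n, [0, 0, 0])
        vols.append(ste.planar_rotator(sec, cell, np.zeros(2),
                                       rng.uniform(0, np.pi), 0.4, rng=rng))
    vols = np.array(vols)
    truth = 4 / 3 * np.pi * 24.0
    se = vols.std(ddof=1) / np.sqrt(len(vols))
    assert abs(vols.mean() - truth) < 3 * se
    assert vols.mean() == pytest.approx(truth, rel=0.03)


def test_rotator_off_center_reference_unbiased(rng):
    """A fixed off-centre reference point in a sphere still gives the volume
    in the mean over isotropic sections through that point."""
    cell = sphere_cell(radius=3.0)
    ref3d = np.array([0.8, -0.4, 0.5])
    vols = []
    for _ in range(4000):
        n = geo.random_unit_vectors(rng)
        sec = _section(n, ref3d)
        vols.append(ste.planar_rotator(sec, cell, np.zeros(2),
                                       rng.uniform(0, np.pi), 0.3, rng=rng))
    vols = np.array(vols)
    truth = 4 / 3 * np.pi * 27.0
    se = vols.std(ddof=1) / np.sqrt(len(vols))
    assert abs(vols.mean() - truth) < 3 * se


def test_rotator_reference_outside_profile_errors():
    cell = sphere_cell(radius=2.0)
    sec = _section([0, 0, 1], [0, 0, 0])
    with pytest.raises(ValueError):
        ste.planar_rotator(sec, cell, np.array([5.0, 0.0]), 0.0, 0.1, start=0.5)


# -- surfaces ----------------------------------------------------------------


def test_surface_density_zero_and_errors():
    assert ste.surface_density(0, 100.0) == 0.0
    with pytest.raises(ZeroDivisionError):
        ste.surface_density(5, 0.0)


def test_sphere_surface_density_recovered(rng):
    """A spherical cell has S_V = 3/R; the 2I/L estimator over random
    sections matches within 2%. Per-cell surfaces follow with vbar."""
    R = 5.0
    ph = _single_cell_phantom(radius=R, luminal_fraction=0.4)
    frame = CountingFrame(center=np.zeros(2), side=14.0)
    gs = ste.TestSystem(spacing=1.0)
    I_cell = I_lum = P_cell = 0
    for _ in range(800):
        n = geo.random_unit_vectors(rng)
        z = rng.uniform(-R, R)
        sec = _section(n, z * n)
        ps = extract_profiles(sec, ph)
        grid = gs.realize(rng)
        p_lb, p_cell = ste.count_points(ps, grid, frame, "lb", "cell")
        I_cell += ste.count_intersections(ps, grid, frame, "cell")
        I_lum += ste.count_intersections(ps, grid, frame, "lumen")
        P_cell += p_cell
    L = ste.line_length_in_reference(P_cell, gs.length_per_point)
    s_v = ste.surface_density(I_cell, L)
    assert s_v == pytest.approx(3.0 / R, rel=0.02)
    # luminal fraction of the surface is recovered
    assert I_lum / I_cell == pytest.approx(0.4, rel=0.05)
    s_lum, s_cell = ste.estimate_surface_per_cell(
        I_lum, I_cell, L, vbar_AE2=4 / 3 * np.pi * R**3)
    assert s_cell == pytest.approx(4 * np.pi * R**2, rel=0.02)
    assert s_lum / s_cell == pytest.approx(0.4, rel=0.05)


# -- cascade and sphere model ------------------------------------------------


def test_cascade_arithmetic_examples():
    dens = ste.DensityEstimates(
        V_V_Lb_AE2=0.08, V_V_mito_AE2=0.1, V_V_nuc_AE2=0.15,
        N_V_Lb_AE2=0.2, S_V_lumen_AE2=0.3, S_V_cell_AE2=0.6,
        N_V_AE2_lung=2.0e8,
    )
    absolute = ste.cascade_to_absolute(dens, V_lung_cm3=1.0e-6, vbar_AE2=500.0)
    assert absolute.N_AE2_lung == pytest.approx(200.0)
    assert absolute.N_Lb_AE2 == pytest.approx(100.0)
    assert absolute.V_Lb_AE2 == pytest.approx(40.0)
    assert absolute.vbar_Lb == pytest.approx(0.4)
    assert absolute.V_Lb_lung == pytest.approx(8000.0)
    absolute.validate()
    with pytest.raises(ZeroDivisionError):
        ste.cascade_to_absolute(dens, 0.0, 500.0)
    with pytest.raises(ZeroDivisionError):
        ste.cascade_to_absolute(dens, 1e-6, -1.0)


@settings(deadline=None, max_examples=60)
@given(
    n_v=st.floats(0.01, 1.0), v_v=st.floats(0.001, 0.3),
    vbar=st.floats(100.0, 2000.0), n_cells=st.floats(10.0, 1e4),
)
def test_cascade_identity_property(n_v, v_v, vbar, n_cells):
    """vbar_Lb * N_Lb * N_AE2 always reproduces V_Lb_lung."""
    dens = ste.DensityEstimates(
        V_V_Lb_AE2=v_v, V_V_mito_AE2=0.0, V_V_nuc_AE2=0.0,
        N_V_Lb_AE2=n_v, S_V_lumen_AE2=0.1, S_V_cell_AE2=0.2,
        N_V_AE2_lung=n_cells / 1e-6,
    )
    absolute = ste.cascade_to_absolute(dens, 1e-6, vbar)
    assert absolute.vbar_Lb * absolute.N_Lb_AE2 * absolute.N_AE2_lung == \
        pytest.approx(absolute.V_Lb_lung, rel=1e-9)


def test_lb_sphere_surface_examples():
    rbar, sbar, total = ste.lb_sphere_surface(4 * np.pi / 3, 1.0)
    assert rbar == pytest.approx(1.0, rel=1e-12)
    assert sbar == pytest.approx(4 * np.pi, rel=1e-12)
    rbar, sbar, total = ste.lb_sphere_surface(0.5, 100.0)
    assert rbar == pytest.approx(0.492373, rel=1e-5)
    assert total == pytest.approx(304.646, rel=1e-4)
    assert ste.lb_sphere_surface(0.5, 0.0)[2] == 0.0
    with pytest.raises(ValueError):
        ste.lb_sphere_surface(-1.0, 10.0)


def test_membrane_balance_bookkeeping():
    mb = ste.membrane_balance(
        {"S_lumen_AE2": 149.0, "S_Lb_AE2": 204.0},
        {"S_lumen_AE2": 227.0, "S_Lb_AE2": 141.0},
    )
    assert mb.sum_control == pytest.approx(353.0)
    assert mb.sum_ir == pytest.approx(368.0)
    assert mb.delta_S_Lb == pytest.approx(63.0)
    assert mb.delta_S_lumen == pytest.approx(78.0)


def test_units_cover_every_estimate_field():
    import dataclasses

    for f in dataclasses.fields(ste.AbsoluteEstimates):
        assert f.name in ste.UNITS
    for f in dataclasses.fields(ste.DensityEstimates):
        assert f.name in ste.UNITS


def test_count_record_rejects_negative_or_fractional_counts():
    with pytest.raises(ValueError):
        ste.CountRecord(P_struct=-1)
    with pytest.raises(ValueError):
        ste.CountRecord(Q_dir1=1.5)
    rec = ste.CountRecord(P_struct=3, P_ref=10, Q_dir1=2, h=0.1, a_p=1.5625)
    assert rec.P_struct <= rec.P_ref


def test_counts_to_estimates_reduces_an_external_table():
    """An externally supplied count table reduces through the same cascade
    arithmetic as the virtual session."""
    records = [
        {"P_struct": 5, "P_ref": 100, "I_lumen": 12, "I_cell": 30,
         "Q_dir1": 3, "Q_dir2": 2, "h": 0.1},
        {"P_struct": 3, "P_ref": 80, "I_lumen": 10, "I_cell": 26,
         "Q_dir1": 2, "Q_dir2": 3, "h": 0.1},
        {"lm": True, "Q_dir1": 4, "Q_dir2": 4, "P_ref": 500},
    ]
    dens, absolute = ste.counts_to_estimates(
        records, a_p=1.0, l_p=1.0, h_lm=3.0, V_lung_cm3=1e-6, vbar_AE2=500.0)
    assert dens.V_V_Lb_AE2 == pytest.approx(8 / 180)
    assert dens.N_V_Lb_AE2 == pytest.approx(10 / (2 * 0.1 * 180))
    assert dens.S_V_lumen_AE2 == pytest.approx(2 * 22 / 180)
    assert dens.N_V_AE2_lung == pytest.approx(8 / (2 * 3 * 500) * 1e12)
    assert absolute.N_Lb_AE2 == pytest.approx(dens.N_V_Lb_AE2 * 500.0)
    assert absolute.vbar_Lb * absolute.N_Lb_AE2 == pytest.approx(absolute.V_Lb_AE2)
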