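"""Flow-field statistics: analytic identities, moments, invariances."""

import numpy as np
import pytest

from matperc import TrajectorySet, simulate_material
from matperc.motion import (
    GridSpec,
    MOTION_COLUMNS,
    flow_curl,
    flow_divergence,
    flow_laplacian,
    flow_speed,
    flowfield_from_arrays,
    motion_feature_matrix,
    point_displacements,
    rasterize_flow,
    speed_gradient,
)
from matperc.stats import moments


def _grid_field(fn, n=11):
    xs = np.arange(float(n))
    gx, gy = np.meshgrid(xs, xs)
    u, v = fn(gx, gy)
    return flowfield_from_arrays(u, v)


# --- displacements ----------------------------------------------------------

def test_displacements_static_and_uniform():
    pos = np.zeros((5, 3, 2))
    t = TrajectorySet(pos, "t", "jelly", "t-e0")
    assert not point_displacements(t).any()
    pos2 = pos + np.arange(5)[:, None, None] * np.array([1.0, 0.0])
    t2 = TrajectorySet(pos2, "t", "jelly", "t-e0")
    d = point_displacements(t2)
    assert d.shape == (4, 3, 2)
    assert np.allclose(d, [1.0, 0.0])


def test_displacements_zero_amplitude_jelly():
    t = simulate_material("jelly", n_frames=6, n_points=30, params={"amplitude": 0.0})
    assert np.allclose(point_displacements(t), 0.0)


def test_displacements_single_frame_raises():
    t = TrajectorySet(np.zeros((2, 3, 2)), "t", "jelly", "t-e0")
    t.positions = t.positions[:1]
    with pytest.raises(ValueError):
        point_displacements(t)


# --- rasterization ----------------------------------------------------------

def test_rasterize_single_point_exact_at_its_cell():
    xs = np.arange(5.0)
    field = rasterize_flow(
        np.array([[0.7, -0.3]]), np.array([[2.0, 2.0]]), xs, xs, 1.0, 1.0, bandwidth=1.0
    )
    assert field.valid[2, 2]
    assert field.u[2, 2] == pytest.approx(0.7)
    assert field.v[2, 2] == pytest.approx(-0.3)


def test_rasterize_uniform_translation_recovers_field():
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 10, (500, 2))
    disp = np.tile([1.0, 0.0], (500, 1))
    xs = np.linspace(0, 10, 11)
    field = rasterize_flow(disp, pts, xs, xs, 1.0, 1.0, bandwidth=1.5)
    assert field.valid.all()
    assert np.allclose(field.u[field.valid], 1.0)
    assert np.allclose(field.v[field.valid], 0.0)


def test_rasterize_no_points_all_invalid():
    xs = np.arange(4.0)
    field = rasterize_flow(np.zeros((0, 2)), np.zeros((0, 2)), xs, xs, 1.0, 1.0, 1.0)
    assert not field.valid.any()


# --- differential operators -------------------------------------------------

def test_divergence_analytic_identities():
    div, ok = flow_divergence(_grid_field(lambda x, y: (x, y)))
    assert np.allclose(div[ok], 2.0, atol=1e-6)
    div, ok = flow_divergence(_grid_field(lambda x, y: (-y, x)))
    assert np.allclose(div[ok], 0.0, atol=1e-6)
    div, ok = flow_divergence(_grid_field(lambda x, y: (np.ones_like(x), np.ones_like(y))))
    assert np.allclose(div[ok], 0.0, atol=1e-6)


def test_curl_analytic_identities():
    curl, ok = flow_curl(_grid_field(lambda x, y: (-y, x)))
    assert np.allclose(curl[ok], 2.0, atol=1e-6)
    curl, ok = flow_curl(_grid_field(lambda x, y: (x, y)))
    assert np.allclose(curl[ok], 0.0, atol=1e-6)
    curl, ok = flow_curl(_grid_field(lambda x, y: (np.zeros_like(x), x)))
    assert np.allclose(curl[ok], 1.0, atol=1e-6)


def test_speed_identities():
    sp, ok = flow_speed(_grid_field(lambda x, y: (np.full_like(x, 3.0), np.full_like(y, 4.0))))
    assert np.allclose(sp[ok], 5.0)
    sp, ok = flow_speed(_grid_field(lambda x, y: (x, np.zeros_like(y))))
    xs = np.arange(11.0)
    assert np.allclose(sp[ok], np.abs(np.meshgrid(xs, xs)[0][ok]))


def test_speed_gradient_identities():
    g, ok = speed_gradient(_grid_field(lambda x, y: (np.full_like(x, 2.0), np.zeros_like(y))))
    assert np.allclose(g[ok], 0.0, atol=1e-6)
    g, ok = speed_gradient(_grid_field(lambda x, y: (x + 5.0, np.zeros_like(y))))
    assert np.allclose(g[ok], 1.0, atol=1e-6)
    # speed = x + 2y -> |grad| = sqrt(5); build it directly as a field with v = 0
    xs = np.arange(11.0)
    gx, gy = np.meshgrid(xs, xs)
    g, ok = speed_gradient(flowfield_from_arrays(gx + 2 * gy + 1.0, np.zeros_like(gx)))
    assert np.allclose(g[ok], np.sqrt(5.0), atol=1e-6)


def test_laplacian_identities():
    lap, ok = flow_laplacian(_grid_field(lambda x, y: (x + 5.0, np.zeros_like(y))))
    assert np.allclose(lap[ok], 0.0, atol=1e-6)  # affine speed annihilated
    xs = np.arange(11.0)
    gx, gy = np.meshgrid(xs, xs)
    lap, ok = flow_laplacian(flowfield_from_arrays(gx**2, np.zeros_like(gx)))
    assert np.allclose(lap[ok], 2.0, atol=1e-6)
    lap, ok = flow_laplacian(
        _grid_field(lambda x, y: (np.full_like(x, 7.0), np.zeros_like(y)))
    )
    assert np.allclose(lap[ok], 0.0, atol=1e-6)


def test_operator_linearity_on_random_fields(rng):
    shape = (9, 9)
    u1, v1, u2, v2 = rng.normal(size=(4,) + shape)
    a, b = 1.7, -0.6
    fsum = flowfield_from_arrays(a * u1 + b * u2, a * v1 + b * v2)
    f1 = flowfield_from_arrays(u1, v1)
    f2 = flowfield_from_arrays(u2, v2)
    for op in (flow_divergence, flow_curl):
        s, ok = op(fsum)
        x1, _ = op(f1)
        x2, _ = op(f2)
        assert np.allclose(s[ok], (a * x1 + b * x2)[ok], atol=1e-9)


def test_rotation_and_reflection_equivariance(rng):
    """A proper 90-deg rotation of positions + displacements preserves the
    speed, divergence and curl statistics (curl is a proper-rotation
    invariant); a mirror reflection negates curl's odd moments while
    leaving its even moments and the speed/divergence statistics intact."""
    pts = rng.uniform(0, 8, (300, 2))
    disp = rng.normal(0, 0.3, (300, 2))
    xs = np.linspace(0, 8, 9)
    f = rasterize_flow(disp, pts, xs, xs, 1.0, 1.0, bandwidth=1.2)
    # proper rotation by 90 deg: (x, y) -> (-y, x)
    rot = np.array([[0.0, -1.0], [1.0, 0.0]])
    ys = np.linspace(-8, 0, 9)
    f_rot = rasterize_flow(disp @ rot.T, pts @ rot.T, ys, xs, 1.0, 1.0, bandwidth=1.2)
    for op in (flow_speed, flow_divergence, flow_curl):
        a, ok_a = op(f)
        b, ok_b = op(f_rot)
        assert np.allclose(moments(a[ok_a]), moments(b[ok_b]), atol=1e-6)
    # reflection about the y axis: (x, y) -> (-x, y)
    refl = np.diag([-1.0, 1.0])
    f_ref = rasterize_flow(disp @ refl, pts @ refl, ys, xs, 1.0, 1.0, bandwidth=1.2)
    for op in (flow_speed, flow_divergence):
        a, ok_a = op(f)
        b, ok_b = op(f_ref)
        assert np.allclose(moments(a[ok_a]), moments(b[ok_b]), atol=1e-6)
    c, ok_c = flow_curl(f)
    cr, ok_cr = flow_curl(f_ref)
    mc, mcr = moments(c[ok_c]), moments(cr[ok_cr])
    assert mcr[0] == pytest.approx(-mc[0], abs=1e-6)  # mean negated
    assert mcr[2] == pytest.approx(-mc[2], abs=1e-6)  # skewness negated
    assert mcr[1] == pytest.approx(mc[1], abs=1e-6)
    assert mcr[3] == pytest.approx(mc[3], abs=1e-6)


def test_validity_monotonicity(rng):
    """Shrinking the valid mask never changes statistics on surviving cells."""
    u, v = rng.normal(size=(2, 9, 9))
    full = flowfield_from_arrays(u, v)
    sub_valid = np.ones((9, 9), dtype=bool)
    sub_valid[0:3, 0:3] = False
    sub = flowfield_from_arrays(u, v, valid=sub_valid)
    for op in (flow_speed, flow_divergence, flow_curl, speed_gradient, flow_laplacian):
        a, ok_a = op(full)
        b, ok_b = op(sub)
        assert np.all(ok_b <= ok_a)
        assert np.allclose(a[ok_b], b[ok_b], equal_nan=True)


# --- moments ----------------------------------------------------------------

def test_moments_degenerate_and_hand_computed():
    assert np.allclose(moments(np.full(5, 3.3)), [3.3, 0, 0, 0])
    m = moments(np.array([0.0, 0.0, 1.0, 1.0]))
    assert m[0] == pytest.approx(0.5)
    assert m[1] == pytest.approx(np.sqrt(1 / 3))
    with pytest.raises(ValueError):
        moments(np.array([]))


def test_moments_symmetric_sample_skew_near_zero(rng):
    x = rng.normal(size=200_000)
    m = moments(x)
    assert abs(m[2]) < 0.02
    assert abs(m[3]) < 0.05


# --- feature matrix ---------------------------------------------------------

def test_motion_matrix_shape_and_static_case():
    t = simulate_material("fabric", n_frames=48, n_points=200, seed=1)
    m = motion_feature_matrix(t)
    assert m.shape == (47, 20)
    assert list(m.columns) == list(MOTION_COLUMNS)

    static = simulate_material("jelly", n_frames=10, n_points=100, params={"amplitude": 0.0})
    ms = motion_feature_matrix(static)
    valid = ms.dropna()
    assert np.allclose(valid.to_numpy(), 0.0, atol=1e-12)


def test_motion_matrix_translation_invariance():
    t = simulate_material("smoke", n_frames=10, n_points=150, seed=2)
    shifted = TrajectorySet(
        t.positions + np.array([123.0, -45.0]), "t2", t.material, t.exemplar
    )
    a = motion_feature_matrix(t, grid=GridSpec(shape=(24, 24)))
    b = motion_feature_matrix(shifted, grid=GridSpec(shape=(24, 24)))
    assert np.allclose(a.to_numpy(), b.to_numpy(), equal_nan=True, atol=1e-9)


def test_kinematic_signatures_across_classes():
    """Smoke expands (positive mean divergence) more than jelly; fabric's
    speed varies across space while a rigid translation's does not."""
    feats = {}
    for cls in ("smoke", "jelly", "fabric"):
        t = simulate_material(cls, n_frames=24, n_points=250, seed=4)
        feats[cls] = motion_feature_matrix(t)
    rigid = simulate_material(
        "rigid_breakable", n_frames=24, n_points=250, seed=4, params={"t_break": 1e9}
    )
    feats["rigid"] = motion_feature_matrix(rigid)
    assert feats["smoke"]["divergence_mean"].mean() > feats["jelly"]["divergence_mean"].mean()
    assert feats["fabric"]["speed_sd"].mean() > feats["rigid"]["speed_sd"].mean()
    assert feats["rigid"]["speed_sd"].abs().max() < 1e-10
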