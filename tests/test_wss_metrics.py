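"""Hemodynamic index computations against analytic and quadrature oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thrombomap.wss import (
    IndexConfig,
    WSSField,
    compute_all_indices,
    compute_ecap,
    compute_osi,
    compute_rrt,
    compute_tawss,
    compute_transwss,
    normalize_transwss,
    time_average_vector,
)

from conftest import flat_patch_mesh, harmonic_field, random_harmonic_field

TWO_OVER_PI = 2.0 / np.pi


def uniaxial_field(patch, magnitudes, direction=(1.0, 0.0, 0.0), period=1.0):
    """wss(t) = magnitudes[k] * direction at uniform times."""
    k = len(magnitudes)
    t = np.linspace(0, period, k, endpoint=False)
    d = np.asarray(direction, float)
    vec = np.einsum("k,j->kj", np.asarray(magnitudes, float), d)
    vectors = np.repeat(vec[:, None, :], patch.n_vertices, axis=1)
    return WSSField(mesh=patch, times=t, period=period, vectors=vectors)


# -- time averaging -----------------------------------------------------------


def test_constant_field_mean_is_the_constant(patch):
    fld = uniaxial_field(patch, np.full(16, 2.5), direction=(0.6, 0.8, 0.0))
    mean = time_average_vector(fld)
    np.testing.assert_allclose(mean, np.tile([1.5, 2.0, 0.0], (patch.n_vertices, 1)),
                               atol=1e-14)


def test_zero_mean_cosine_averages_to_zero(patch):
    t = np.linspace(0, 1, 360, endpoint=False)
    fld = uniaxial_field(patch, 3.0 * np.cos(2 * np.pi * t))
    assert np.abs(time_average_vector(fld)).max() < 1e-10 * 3.0


def test_two_harmonic_mean_matches_refined_quadrature(patch):
    # oracle: the same integrand on a 10^5-point grid
    def f(t):
        return np.stack([1.0 + 0.5 * np.cos(2 * np.pi * t) + 0.3 * np.sin(4 * np.pi * t),
                         0.4 * np.sin(2 * np.pi * t),
                         np.zeros_like(t)], axis=-1)

    t = np.linspace(0, 1, 72, endpoint=False)
    vectors = np.repeat(f(t)[:, None, :], patch.n_vertices, axis=1)
    fld = WSSField(mesh=patch, times=t, period=1.0, vectors=vectors)
    tf = np.linspace(0, 1, 100_000, endpoint=False)
    oracle_mean = f(tf).mean(axis=0)
    oracle_tawss = np.linalg.norm(f(tf), axis=-1).mean()
    np.testing.assert_allclose(time_average_vector(fld)[0], oracle_mean, rtol=1e-6,
                               atol=1e-9)
    assert compute_tawss(fld)[0] == pytest.approx(oracle_tawss, rel=1e-6)


def test_nonuniform_sampling_matches_uniform_for_band_limited_field(patch):
    # periodic trapezoid handles arbitrary strictly increasing times
    rng = np.random.default_rng(7)
    def f(t):
        return 1.0 + 0.4 * np.cos(2 * np.pi * t)
    dense = np.sort(rng.uniform(0, 1, 4000))
    vec = np.zeros((len(dense), patch.n_vertices, 3))
    vec[:, :, 0] = f(dense)[:, None]
    fld = WSSField(mesh=patch, times=dense, period=1.0, vectors=vec)
    assert time_average_vector(fld)[0, 0] == pytest.approx(1.0, rel=1e-4)


def test_single_sample_rejected(patch):
    with pytest.raises(ValueError):
        WSSField(mesh=patch, times=np.array([0.0]), period=1.0,
                 vectors=np.zeros((1, patch.n_vertices, 3)))


# -- TAWSS --------------------------------------------------------------------


def test_tawss_constant_magnitude(patch):
    fld = uniaxial_field(patch, np.full(24, 0.7))
    np.testing.assert_allclose(compute_tawss(fld), 0.7, atol=1e-14)


def test_tawss_of_rectified_cosine(patch):
    t = np.linspace(0, 1, 2000, endpoint=False)
    fld = uniaxial_field(patch, 2.0 * np.cos(2 * np.pi * t))
    assert compute_tawss(fld)[0] == pytest.approx(2.0 * TWO_OVER_PI, rel=1e-4)


def test_tawss_of_sign_reversing_square_wave(patch):
    mags = np.concatenate([np.full(50, 1.3), np.full(50, -1.3)])
    fld = uniaxial_field(patch, mags)
    np.testing.assert_allclose(compute_tawss(fld), 1.3, atol=1e-14)


# -- OSI ----------------------------------------------------------------------


def test_osi_zero_for_unidirectional_field(patch):
    t = np.linspace(0, 1, 100, endpoint=False)
    fld = uniaxial_field(patch, 1.0 + 0.5 * np.cos(2 * np.pi * t))
    osi, deg = compute_osi(fld)
    np.testing.assert_allclose(osi, 0.0, atol=1e-12)
    assert not deg.any()


def test_osi_half_for_zero_mean_field(patch):
    t = np.linspace(0, 1, 360, endpoint=False)
    fld = uniaxial_field(patch, np.cos(2 * np.pi * t))
    osi, _ = compute_osi(fld)
    np.testing.assert_allclose(osi, 0.5, atol=1e-9)


def test_osi_one_third_for_asymmetric_square_wave(patch):
    # +A for half the cycle, -A/2 for the other half:
    # |mean| = A/4, TAWSS = 3A/4, OSI = (1 - 1/3)/2 = 1/3
    A = 2.0
    mags = np.concatenate([np.full(60, A), np.full(60, -A / 2)])
    fld = uniaxial_field(patch, mags)
    osi, _ = compute_osi(fld)
    np.testing.assert_allclose(osi, 1.0 / 3.0, atol=1e-14)


def test_osi_degenerate_zero_field_flagged(patch):
    fld = uniaxial_field(patch, np.zeros(16))
    osi, deg = compute_osi(fld)
    assert deg.all()
    np.testing.assert_array_equal(osi, 0.0)


# -- RRT / ECAP ---------------------------------------------------------------


@pytest.mark.parametrize("osi_v, tawss_v, expected", [
    (0.0, 0.4, 2.5),
    (0.25, 1.0, 2.0),
])
def test_rrt_direct_substitution(osi_v, tawss_v, expected):
    rrt, capped = compute_rrt(np.array([tawss_v]), np.array([osi_v]))
    assert rrt[0] == pytest.approx(expected, rel=1e-12)
    assert not capped.any()


def test_rrt_equals_inverse_mean_magnitude(patch, rng):
    fld = random_harmonic_field(rng, patch, n_times=64)
    tawss = compute_tawss(fld)
    osi, _ = compute_osi(fld)
    rrt, capped = compute_rrt(tawss, osi)
    mean_mag = np.linalg.norm(time_average_vector(fld), axis=1)
    ok = ~capped
    np.testing.assert_allclose(rrt[ok], 1.0 / mean_mag[ok], rtol=1e-9)


def test_rrt_caps_degenerate_denominator():
    cfg = IndexConfig(cap=1e6)
    rrt, capped = compute_rrt(np.array([0.0, 1.0]), np.array([0.0, 0.5]), cfg)
    assert capped.tolist() == [True, True]
    np.testing.assert_array_equal(rrt, 1e6)


@pytest.mark.parametrize("osi_v, tawss_v, expected", [
    (0.3, 0.4, 0.75),
    (0.0, 5.0, 0.0),
])
def test_ecap_direct_substitution(osi_v, tawss_v, expected):
    ecap, _ = compute_ecap(np.array([tawss_v]), np.array([osi_v]))
    assert ecap[0] == pytest.approx(expected, rel=1e-12)


def test_ecap_elementwise_on_random_fields(patch, rng):
    fld = random_harmonic_field(rng, patch, n_times=48)
    tawss = compute_tawss(fld)
    osi, _ = compute_osi(fld)
    ecap, capped = compute_ecap(tawss, osi)
    ok = ~capped
    np.testing.assert_allclose(ecap[ok], osi[ok] / tawss[ok], rtol=1e-12)


# -- TransWSS -----------------------------------------------------------------


def test_transwss_zero_for_fixed_direction(patch):
    t = np.linspace(0, 1, 90, endpoint=False)
    fld = uniaxial_field(patch, 1.0 + 0.3 * np.cos(2 * np.pi * t),
                         direction=(0.6, 0.8, 0.0))
    trans, undef = compute_transwss(fld)
    np.testing.assert_allclose(trans, 0.0, atol=1e-12)
    assert not undef.any()


def test_transwss_analytic_sine_transverse_component(patch):
    # wss = A e1 + B sin e2 with e1 perp e2 in the tangent plane:
    # mean direction is e1, so TransWSS = (2/pi) B
    A, B = 0.5, 0.3
    t = np.linspace(0, 1, 3000, endpoint=False)
    vec = np.zeros((len(t), patch.n_vertices, 3))
    vec[:, :, 0] = A
    vec[:, :, 1] = (B * np.sin(2 * np.pi * t))[:, None]
    fld = WSSField(mesh=patch, times=t, period=1.0, vectors=vec)
    trans, _ = compute_transwss(fld)
    np.testing.assert_allclose(trans, TWO_OVER_PI * B, rtol=1e-4)


def test_transwss_never_exceeds_tawss(patch, rng):
    fld = random_harmonic_field(rng, patch, n_times=48)
    trans, _ = compute_transwss(fld)
    assert np.all(trans <= compute_tawss(fld) + 1e-9)


def test_transwss_undefined_mean_flagged(patch):
    t = np.linspace(0, 1, 64, endpoint=False)
    fld = uniaxial_field(patch, np.cos(2 * np.pi * t))  # zero mean
    trans, undef = compute_transwss(fld)
    assert undef.all()
    np.testing.assert_array_equal(trans, 0.0)


# -- normalisation ------------------------------------------------------------


def test_normalize_maps_max_to_one():
    trans = np.array([0.05, 0.2, 0.1])
    out = normalize_transwss(trans)
    assert out.max() == 1.0 and out[1] == 1.0


def test_normalize_uniform_field_all_ones():
    np.testing.assert_array_equal(normalize_transwss(np.full(5, 0.3)), 1.0)


def test_normalize_scale_invariance(rng):
    trans = rng.uniform(0.01, 1.0, 20)
    np.testing.assert_allclose(normalize_transwss(trans),
                               normalize_transwss(7.3 * trans), rtol=1e-12)


def test_normalize_respects_region_and_rejects_zero():
    trans = np.array([1.0, 0.2, 0.4])
    region = np.array([False, True, True])
    out = normalize_transwss(trans, region)
    assert out[2] == 1.0 and out[0] == pytest.approx(2.5)
    with pytest.raises(ValueError):
        normalize_transwss(np.zeros(3))


# -- bundle -------------------------------------------------------------------


def test_bundle_deterministic(patch, rng):
    fld = random_harmonic_field(rng, patch, n_times=32)
    a = compute_all_indices(fld)
    b = compute_all_indices(fld)
    for k in a.as_dict():
        np.testing.assert_array_equal(a.as_dict()[k], b.as_dict()[k])


def test_indices_are_local_under_submesh_restriction(rng):
    mesh = flat_patch_mesh(5)
    fld = random_harmonic_field(rng, mesh, n_times=32)
    full = compute_all_indices(fld)
    keep = np.zeros(mesh.n_vertices, dtype=bool)
    keep[:15] = True
    sub, orig = mesh.submesh(keep)
    sub_fld = WSSField(mesh=sub, times=fld.times, period=fld.period,
                       vectors=fld.vectors[:, orig])
    restricted = compute_all_indices(sub_fld)
    for key in ("tawss", "osi", "transwss", "rrt", "ecap"):
        np.testing.assert_allclose(getattr(restricted, key),
                                   getattr(full, key)[orig], rtol=1e-12)


def test_quadrature_convergence_doubling_samples(patch):
    def make(k):
        t = np.linspace(0, 1, k, endpoint=False)
        vec = np.zeros((k, patch.n_vertices, 3))
        vec[:, :, 0] = (0.8 + 0.5 * np.cos(2 * np.pi * t)
                        + 0.2 * np.sin(6 * np.pi * t))[:, None]
        vec[:, :, 1] = (0.3 * np.sin(2 * np.pi * t))[:, None]
        return WSSField(mesh=patch, times=t, period=1.0, vectors=vec)

    coarse = compute_all_indices(make(180))
    fine = compute_all_indices(make(360))
    for key in ("tawss", "osi", "transwss"):
        a, b = getattr(coarse, key), getattr(fine, key)
        assert np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-12)) < 1e-3


def test_tangency_warning_for_non_tangent_field(patch):
    t = np.linspace(0, 1, 16, endpoint=False)
    vec = np.zeros((16, patch.n_vertices, 3))
    vec[:, :, 2] = 1.0  # purely normal: 100% residual
    fld = WSSField(mesh=patch, times=t, period=1.0, vectors=vec)
    with pytest.warns(UserWarning, match="tangency"):
        compute_all_indices(fld)


# -- property-based invariants ------------------------------------------------


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_osi_bounds_and_triangle_inequality_hold(seed):
    rng = np.random.default_rng(seed)
    mesh = flat_patch_mesh(3)
    fld = random_harmonic_field(rng, mesh, n_harmonics=rng.integers(1, 4),
                                n_times=int(rng.integers(16, 64)))
    tawss = compute_tawss(fld)
    osi, _ = compute_osi(fld)
    mean_mag = np.linalg.norm(time_average_vector(fld), axis=1)
    assert np.all(osi >= 0) and np.all(osi <= 0.5)
    # TAWSS >= ||mean|| (triangle inequality), equality iff OSI = 0
    assert np.all(tawss >= mean_mag - 1e-12)
    trans, _ = compute_transwss(fld)
    assert np.all(trans <= tawss + 1e-9)
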