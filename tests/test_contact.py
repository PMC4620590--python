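import numpy as np
import pytest

from paramhip.contact import (ContactConfig, MaterialConfig, contact_area,
                              foundation_oracle_peak_pressure, foundation_stiffness,
                              gap_function, run_activity, small_angle_peak_pressure,
                              solve_equilibrium)
from paramhip.errors import DomainError, NoEquilibriumError
from paramhip.loading import discretise, load_activity
from paramhip.meshing import vertex_areas


def _lunate_centroid_direction(geo):
    va = vertex_areas(geo.articular.vertices, geo.articular.faces)
    c = (geo.articular.vertices * va[:, None]).sum(axis=0) / va.sum()
    return c / np.linalg.norm(c)


def _contact_force_on_femur(geo, field, K):
    v = geo.articular.vertices
    va = vertex_areas(v, geo.articular.faces)
    w = (geo.femoral_head.center + field.displacement) - v
    s = np.linalg.norm(w, axis=1)
    return ((field.pressure * va)[:, None] * (w / s[:, None])).sum(axis=0)


# -- foundation stiffness -----------------------------------------------------

def test_foundation_stiffness_of_the_two_layer_cartilage_bed():
    K = foundation_stiffness(12.0, 0.45, 4.0)
    assert K == pytest.approx(12.0 * 0.55 / (1.45 * 0.10 * 4.0), rel=1e-12)
    assert K == pytest.approx(11.379, abs=5e-4)


def test_foundation_stiffness_limits():
    assert foundation_stiffness(10.0, 0.0, 4.0) == pytest.approx(10.0 / 4.0)
    K1 = foundation_stiffness(12.0, 0.45, 2.0)
    assert foundation_stiffness(12.0, 0.45, 4.0) == pytest.approx(K1 / 2.0)
    with pytest.raises(DomainError):
        foundation_stiffness(12.0, 0.5, 4.0)
    with pytest.raises(DomainError):
        foundation_stiffness(12.0, 0.3, 0.0)


# -- gap function -------------------------------------------------------------

def test_concentric_gap_equals_clearance_everywhere(geo_p1):
    gap = gap_function(geo_p1, np.zeros(3))
    assert np.allclose(gap, 0.5, atol=1e-9)


def test_collinear_displacement_reduces_gap_at_that_vertex(geo_p1):
    v = geo_p1.articular.vertices[100]
    inward = -v / np.linalg.norm(v)
    gap = gap_function(geo_p1, -0.2 * inward)
    # displacement of 0.2 mm toward this vertex leaves 0.3 mm there
    assert gap[100] == pytest.approx(0.3, abs=1e-9)


def test_minimum_gap_matches_concentric_sphere_oracle(geo_p1, rng):
    u = rng.normal(size=3)
    u *= 0.3 / np.linalg.norm(u)
    gap = gap_function(geo_p1, u)
    # analytic minimum c - |u| is attained along u (up to mesh resolution)
    assert gap.min() >= 0.5 - 0.3 - 1e-9
    assert gap.min() == pytest.approx(0.2, abs=0.01)


# -- equilibrium solve --------------------------------------------------------

def test_zero_load_gives_zero_pressure_and_displacement(geo_p1, material):
    K = material.stiffness(2.0)
    field = solve_equilibrium(geo_p1, K, np.zeros(3))
    assert field.max_pressure == 0.0
    assert np.all(field.displacement == 0.0)
    assert contact_area(field, geo_p1.articular) == 0.0


def test_force_balance_at_every_converged_step(geo_p1, material):
    K = material.stiffness(2.0)
    sched = discretise(load_activity("walking", 80.0), 13)
    res = run_activity(geo_p1, material, sched)
    for F, field in zip(sched.forces, res.fields):
        residual = np.linalg.norm(F + _contact_force_on_femur(geo_p1, field, K))
        assert residual <= max(1e-3 * np.linalg.norm(F), 1e-3)


def test_centred_load_matches_small_angle_closed_form(geo_p1, material):
    """In the small-angle regime (patch colatitude ~20 degrees, far from all
    cartilage edges) the solved peak pressure agrees with
    p0 = sqrt(F c K / (pi R^2)) within 5%; the formula's own truncation
    error grows with penetration, reaching ~5% already by 100 N."""
    K = material.stiffness(2.0)
    direction = _lunate_centroid_direction(geo_p1)
    field = solve_equilibrium(geo_p1, K, 75.0 * direction)
    p0 = small_angle_peak_pressure(75.0, 0.5, K,
                                   geo_p1.femoral_head.articular_radius)
    assert field.max_pressure == pytest.approx(p0, rel=0.05)
    field100 = solve_equilibrium(geo_p1, K, 100.0 * direction)
    p0_100 = small_angle_peak_pressure(100.0, 0.5, K,
                                       geo_p1.femoral_head.articular_radius)
    assert field100.max_pressure == pytest.approx(p0_100, rel=0.10)


def test_high_load_matches_exact_foundation_integral(geo_p1, material):
    """The small-angle form breaks down at physiological loads; the solver is
    checked against the exact 1-D foundation integral instead."""
    K = material.stiffness(2.0)
    direction = _lunate_centroid_direction(geo_p1)
    for F, tol in ((1000.0, 0.03), (2000.0, 0.10)):
        field = solve_equilibrium(geo_p1, K, F * direction)
        oracle = foundation_oracle_peak_pressure(F, 0.5, K,
                                                 geo_p1.params.articular_radius)
        assert field.max_pressure == pytest.approx(oracle, rel=tol)


def test_peak_pressure_and_area_monotone_in_load(geo_p1, material):
    K = material.stiffness(2.0)
    direction = _lunate_centroid_direction(geo_p1)
    peaks, areas = [], []
    for F in (50.0, 200.0, 800.0, 1600.0):
        field = solve_equilibrium(geo_p1, K, F * direction)
        peaks.append(field.max_pressure)
        areas.append(contact_area(field, geo_p1.articular))
    assert np.all(np.diff(peaks) > 0)
    assert np.all(np.diff(areas) > 0)


def test_peak_pressure_scales_as_sqrt_of_stiffness(geo_p1, material):
    K = material.stiffness(2.0)
    direction = _lunate_centroid_direction(geo_p1)
    p1 = solve_equilibrium(geo_p1, K, 100.0 * direction).max_pressure
    p2 = solve_equilibrium(geo_p1, 2.0 * K, 100.0 * direction).max_pressure
    assert p2 / p1 == pytest.approx(np.sqrt(2.0), rel=0.03)


def test_unsupported_load_direction_raises_no_equilibrium(geo_p1, material):
    K = material.stiffness(2.0)
    # straight out of the cup opening: no cartilage support
    with pytest.raises(NoEquilibriumError):
        solve_equilibrium(geo_p1, K, 1500.0 * geo_p1.cup_axis)


# -- contact area -------------------------------------------------------------

def test_uniform_pressure_area_is_total_lunate_area(geo_p1):
    n = len(geo_p1.articular.vertices)
    assert contact_area(np.zeros(n), geo_p1.articular) == 0.0
    full = contact_area(np.full(n, 0.2), geo_p1.articular)
    assert full == pytest.approx(geo_p1.articular.area, rel=1e-9)
    assert contact_area(np.full(n, 0.2), geo_p1.articular, rule="any") == \
        pytest.approx(full, rel=1e-9)
    with pytest.raises(DomainError):
        contact_area(np.zeros(n), geo_p1.articular, rule="most")


def test_thresholded_area_matches_spherical_cap_oracle(geo_p1, material):
    """The 0.1 MPa contour of a centred small-angle patch encloses the spherical
    cap of colatitude psi with cos psi = (c + p_thr/K) / w; the facet-rule
    area agrees with 2 pi R^2 (1 - cos psi) within 5%."""
    K = material.stiffness(2.0)
    direction = _lunate_centroid_direction(geo_p1)
    field = solve_equilibrium(geo_p1, K, 75.0 * direction)
    Ra = geo_p1.params.articular_radius
    w = 0.5 + small_angle_peak_pressure(75.0, 0.5, K,
                                        geo_p1.femoral_head.articular_radius) / K
    cos_psi = (0.5 + 0.1 / K) / w
    oracle = 2.0 * np.pi * Ra ** 2 * (1.0 - cos_psi)
    measured = contact_area(field, geo_p1.articular)
    assert measured == pytest.approx(oracle, rel=0.05)


def test_all_vertex_rule_is_conservative(geo_p1, material):
    K = material.stiffness(2.0)
    field = solve_equilibrium(geo_p1, K, 800.0 * _lunate_centroid_direction(geo_p1))
    a_all = contact_area(field, geo_p1.articular, rule="all")
    a_any = contact_area(field, geo_p1.articular, rule="any")
    assert 0.0 < a_all < a_any


# -- activity runs ------------------------------------------------------------

def test_constant_schedule_gives_identical_steps(geo_p1, material):
    from paramhip.loading import LoadProfile

    direction = _lunate_centroid_direction(geo_p1)
    F = 900.0 * direction
    samples = np.array([[0.0, *F], [1.0, *F]])
    sched = discretise(LoadProfile("const", samples, 80.0), 13)
    res = run_activity(geo_p1, material, sched)
    assert len(res.fields) == 13
    assert np.allclose(res.max_pressure, res.max_pressure[0], rtol=1e-6)
    assert np.allclose(res.contact_area, res.contact_area[0], rtol=1e-6)


@pytest.mark.parametrize("geo_fixture", ["geo_p1_mirrored", "geo_p2"])
def test_notch_region_carries_no_pressure_in_any_activity(geo_fixture, request,
                                                          material):
    geo = request.getfixturevalue(geo_fixture)
    notch_idx = geo.labels["articular"]["notch_edge"]
    from paramhip.loading import bundled_activities

    for activity in bundled_activities():
        prof = load_activity(activity, 80.0, side=geo.params.side)
        res = run_activity(geo, material, discretise(prof, 13))
        worst = max(f.pressure[notch_idx].max(initial=0.0) for f in res.fields)
        assert worst == 0.0, f"pressure at notch during {activity}"
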