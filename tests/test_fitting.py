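import numpy as np
import pytest

from paramhip.errors import DomainError, LabelledInputError, SingularConfigurationError
from paramhip.fitting import extract_parameters, fit_circle2d, fit_plane, fit_sphere
from paramhip.geometry import LabelledSurface, labelled_surface
from paramhip.synthetic import CirclePrimitive, PlanePrimitive, SpherePrimitive, sample_primitive


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# -- sphere -------------------------------------------------------------------

def test_sphere_exact_through_five_points():
    R = 7.3
    pts = np.array([[R, 0, 0], [-R, 0, 0], [0, R, 0], [0, -R, 0], [0, 0, R]])
    fit = fit_sphere(pts)
    assert np.allclose(fit.parameters["center"], 0.0, atol=1e-12)
    assert fit.parameters["radius"] == pytest.approx(R, abs=1e-12)
    assert fit.rms_residual < 1e-12


def test_sphere_monte_carlo_radius_within_three_sigma():
    """Over 100 replicate noisy clouds the radius estimate stays within the
    3 sigma/sqrt(n) Monte-Carlo band of the truth in >= 97 cases."""
    R, sigma, n = 28.0, 0.1, 1000
    band = 3.0 * sigma / np.sqrt(n)
    sphere = SpherePrimitive(center=(1.0, -2.0, 3.0), radius=R)
    hits = 0
    for seed in range(100):
        pts = sample_primitive(sphere, n, sigma, seed=42 + seed)
        if abs(fit_sphere(pts).parameters["radius"] - R) <= band:
            hits += 1
    assert hits >= 97


def test_sphere_rejects_coplanar_points(rng):
    pts = np.column_stack([rng.normal(size=(40, 2)), np.zeros(40)])
    with pytest.raises(SingularConfigurationError):
        fit_sphere(pts)
    with pytest.raises(DomainError):
        fit_sphere(pts[:3])


# -- plane --------------------------------------------------------------------

def test_plane_interpolates_three_points():
    pts = np.array([[0.0, 0, 1], [1, 0, 1], [0, 1, 1]])
    fit = fit_plane(pts, orient_toward=[0, 0, 1])
    assert np.allclose(np.abs(fit.parameters["normal"]), [0, 0, 1], atol=1e-12)
    assert fit.parameters["offset"] == pytest.approx(1.0, abs=1e-12)
    assert fit.rms_residual < 1e-12


def test_plane_offset_recovered_from_noisy_samples():
    # TLS oracle: plane z = 5 with sigma = 0.05 noise, n = 500
    plane = PlanePrimitive(point=(0, 0, 5.0), normal=(0, 0, 1), extent=30.0)
    pts = sample_primitive(plane, 500, 0.05, seed=1)
    fit = fit_plane(pts, orient_toward=[0, 0, 1])
    assert fit.parameters["normal"] @ [0, 0, 1] > 0.999
    assert abs(fit.parameters["offset"] - 5.0) < 0.01


def test_plane_rejects_collinear_points():
    pts = np.outer(np.linspace(0, 1, 30), [1.0, 2.0, 3.0])
    with pytest.raises(SingularConfigurationError):
        fit_plane(pts)


# -- circle -------------------------------------------------------------------

def test_circle_circumscribes_three_points():
    pts = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]])
    fit = fit_circle2d(pts)
    assert np.allclose(fit.parameters["center"], 0.0, atol=1e-12)
    assert fit.parameters["radius"] == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("plane", ["coronal", "sagittal"])
def test_circle_projection_conventions(plane, rng):
    circle = CirclePrimitive(center=(4.0, -2.0), radius=9.0, plane=plane, offset=3.0)
    pts = sample_primitive(circle, 200, 0.0, seed=5)
    fit = fit_circle2d(pts, plane)
    assert np.allclose(fit.parameters["center"], [4.0, -2.0], atol=1e-9)
    assert fit.parameters["radius"] == pytest.approx(9.0, abs=1e-9)
    assert fit.rms_residual < 1e-9


def test_circle_rejects_collinear_projections():
    pts = np.column_stack([np.linspace(0, 1, 20), np.linspace(0, 2, 20)])
    with pytest.raises(SingularConfigurationError):
        fit_circle2d(pts)


# -- noiseless exactness across all primitives --------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_noiseless_fits_have_zero_residual(seed):
    sphere = SpherePrimitive(center=(2.0, 1.0, -3.0), radius=27.0)
    pts = sample_primitive(sphere, 300, 0.0, seed=seed)
    assert fit_sphere(pts).rms_residual < 1e-9
    plane = PlanePrimitive(point=(1, 2, 3), normal=(1, 1, 1))
    assert fit_plane(sample_primitive(plane, 200, 0.0, seed=seed)).rms_residual < 1e-9
    circ = CirclePrimitive(center=(5.6, -2.3), radius=16.9)
    assert fit_circle2d(sample_primitive(circ, 100, 0.0, seed=seed),
                        "sagittal").rms_residual < 1e-9


# -- rigid-motion equivariance -------------------------------------------------

def test_sphere_and_plane_fits_are_rigid_motion_equivariant(rng):
    sphere = SpherePrimitive(center=(1.0, 2.0, 3.0), radius=12.0)
    pts = sample_primitive(sphere, 400, 0.02, seed=9)
    Q = _random_rotation(rng)
    t = rng.normal(scale=10.0, size=3)
    base = fit_sphere(pts)
    moved = fit_sphere(pts @ Q.T + t)
    assert np.abs(moved.parameters["center"] - (Q @ base.parameters["center"] + t)).max() < 1e-8
    assert moved.parameters["radius"] == pytest.approx(base.parameters["radius"], abs=1e-8)

    plane_pts = sample_primitive(PlanePrimitive((0, 0, 5), (0, 0, 1)), 300, 0.02, seed=9)
    base = fit_plane(plane_pts)
    moved = fit_plane(plane_pts @ Q.T + t, orient_toward=Q @ base.parameters["normal"])
    assert np.abs(moved.parameters["normal"] - Q @ base.parameters["normal"]).max() < 1e-8
    # signed offset of the transformed centroid matches
    expected = moved.parameters["normal"] @ (Q @ base.parameters["point"] + t)
    assert moved.parameters["offset"] == pytest.approx(expected, abs=1e-8)


# -- full extraction ----------------------------------------------------------

@pytest.mark.parametrize("geo_fixture", ["geo_p1_mirrored", "geo_p2"])
def test_extraction_round_trips_generated_geometry(geo_fixture, request):
    """Fitting the labelled edges of generated geometry recovers every
    parameter to well within 0.05 mm (machine precision on noiseless data),
    including for mirrored left hips."""
    geo = request.getfixturevalue(geo_fixture)
    truth = geo.params
    res = extract_parameters(labelled_surface(geo), truth.cartilage_thickness_t,
                             truth.radial_clearance)
    q = res.params
    assert q.depth_d == pytest.approx(truth.depth_d, abs=0.05)
    assert q.anterior_cut_radius_r1 == pytest.approx(truth.anterior_cut_radius_r1, abs=0.05)
    assert np.abs(np.subtract(q.anterior_cut_center_o1,
                              truth.anterior_cut_center_o1)).max() < 0.05
    assert q.fossa_radius_r2 == pytest.approx(truth.fossa_radius_r2, abs=0.05)
    assert np.abs(np.subtract(q.fossa_center_o2, truth.fossa_center_o2)).max() < 0.05
    assert q.cavity_radius == pytest.approx(truth.cavity_radius, abs=0.05)
    assert q.inclination_deg == pytest.approx(truth.inclination_deg, abs=1e-6)
    assert q.anteversion_deg == pytest.approx(truth.anteversion_deg, abs=1e-6)
    assert q.side == truth.side
    for fit in res.fits.values():
        assert fit.rms_residual < 1e-9


def test_extraction_requires_all_labels(geo_p2):
    surf = labelled_surface(geo_p2)
    broken = LabelledSurface(points=surf.points,
                             labels={k: v for k, v in surf.labels.items()
                                     if k != "fossa_edge"},
                             side=surf.side)
    with pytest.raises(LabelledInputError):
        extract_parameters(broken)
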