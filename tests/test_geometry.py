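import dataclasses

import numpy as np
import pytest

from paramhip.errors import DomainError
from paramhip.geometry import (apply_anterior_cut, apply_fossa_and_notch_cut,
                               build_bone_block, build_femoral_head, build_model,
                               extrude_cartilage, labelled_surface, solid_angle)


def test_zero_depth_cavity_is_a_hemisphere(p1):
    params = dataclasses.replace(p1, depth_d=0.0)
    geo = build_bone_block(params, n_rings=48)
    assert solid_angle(geo) == pytest.approx(2.0 * np.pi, rel=0.01)


def test_cavity_solid_angle_increases_with_depth(p1):
    omegas = [solid_angle(build_bone_block(dataclasses.replace(p1, depth_d=d),
                                           n_rings=32))
              for d in (-2.0, 0.0, 1.2, 3.0)]
    assert np.all(np.diff(omegas) > 0)


def test_rim_ring_lies_on_plane_at_signed_depth(geo_p1, p1):
    idx = geo_p1.labels["bone_cavity"]["posterior_rim"]
    pts = geo_p1.bone_cavity.vertices[idx]
    assert len(pts) > 50
    assert np.abs(pts @ geo_p1.cup_axis - p1.depth_d).max() < 1e-9


def test_edge_rings_lie_exactly_on_their_cut_primitives(geo_p2, p2):
    bone = geo_p2.bone_cavity.vertices
    ant = bone[geo_p2.labels["bone_cavity"]["anterior_edge"]]
    o1 = p2.anterior_cut_center_o1
    assert np.abs(np.hypot(ant[:, 1] - o1[0], ant[:, 2] - o1[1])
                  - p2.anterior_cut_radius_r1).max() < 1e-9
    art = geo_p2.articular.vertices
    fossa = art[geo_p2.labels["articular"]["fossa_edge"]]
    o2 = p2.fossa_center_o2
    assert np.abs(np.hypot(fossa[:, 0] - o2[0], fossa[:, 1] - o2[1])
                  - p2.fossa_radius_r2).max() < 1e-9


def test_cuts_preserve_articular_sphere_radius(geo_p1, geo_p2):
    for geo in (geo_p1, geo_p2):
        r = np.linalg.norm(geo.articular.vertices, axis=1)
        assert np.abs(r - geo.params.articular_radius).max() < 1e-9


def test_cartilage_shell_volume_matches_spherical_shell(geo_p1, p1):
    Ra, R = p1.articular_radius, p1.cavity_radius
    omega = geo_p1.articular.area / Ra ** 2
    expected = omega * (R ** 3 - Ra ** 3) / 3.0
    assert geo_p1.cartilage.is_watertight
    assert abs(geo_p1.cartilage.volume) == pytest.approx(expected, rel=0.02)


def test_lunate_area_strictly_decreases_with_fossa_radius(p1):
    areas = []
    for r2 in (12.0, 16.9, 21.0):
        params = dataclasses.replace(p1, fossa_radius_r2=r2)
        areas.append(build_model(params, n_rings=24, mirror=False).lunate_area())
    assert areas[0] > areas[1] > areas[2]


def test_missing_cylinder_is_a_warned_no_op(p1):
    geo = build_bone_block(p1, n_rings=16)
    before = geo.bone_cavity.vertices.copy()
    with pytest.warns(UserWarning):
        out = apply_anterior_cut(geo, o1=(500.0, 500.0), r1=5.0)
    assert np.array_equal(out.bone_cavity.vertices, before)
    # enormous cylinder containing the whole block: also unchanged
    with pytest.warns(UserWarning):
        out = apply_anterior_cut(geo, o1=(0.0, 0.0), r1=1e4)
    assert np.array_equal(out.bone_cavity.vertices, before)


def test_zero_fossa_radius_leaves_cartilage_unchanged(p1):
    geo = extrude_cartilage(apply_anterior_cut(build_bone_block(p1, n_rings=16)))
    out = apply_fossa_and_notch_cut(geo, r2=0.0)
    assert out.articular.area == pytest.approx(geo.articular.area, abs=1e-9)


def test_mirrored_left_model_is_sagittal_reflection(geo_p1, geo_p1_mirrored):
    v = geo_p1.articular.vertices.copy()
    v[:, 2] *= -1.0
    assert np.abs(geo_p1_mirrored.articular.vertices - v).max() < 1e-9
    assert geo_p1_mirrored.mirrored


def test_femoral_head_clearance_bookkeeping():
    head = build_femoral_head(30.0, 2.0, 0.5)
    assert head.articular_radius == pytest.approx(27.5)
    assert head.bone_radius == pytest.approx(25.5)
    conformal = build_femoral_head(30.0, 2.0, 0.0)
    assert conformal.articular_radius == pytest.approx(28.0)
    with pytest.raises(DomainError):
        build_femoral_head(3.0, 2.0, 0.5)


@pytest.mark.parametrize("field,value", [
    ("cartilage_thickness_t", 31.0),
    ("fossa_radius_r2", 30.5),
    ("depth_d", 30.0),
])
def test_degenerate_cut_configurations_rejected(p1, field, value):
    with pytest.raises(DomainError):
        build_model(dataclasses.replace(p1, **{field: value}), n_rings=12)


def test_labelled_surface_carries_required_regions(geo_p2):
    surf = labelled_surface(geo_p2)
    for name in ("articular", "posterior_rim", "anterior_edge", "fossa_edge"):
        assert len(surf.labels[name]) >= 3
    assert len(surf.points) == len(surf.labels["articular"]) \
        + len(surf.labels["posterior_rim"]) + len(surf.labels["anterior_edge"])
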