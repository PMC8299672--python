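import json

import numpy as np
import pytest

from orthoplan import (
    MissingStage,
    PivotMismatch,
    PlannedMove,
    Pivot,
    SyntheticCaseConfig,
    UnknownPivot,
    clone_jaw,
    detect_contacts,
    export_splint_set,
    generate_synthetic_case,
    measure_displacements,
    move_jaw,
    open_rotation,
    write_planning_sheet,
)
from orthoplan.mounting import JawModel
from orthoplan.stl import read_stl
from conftest import box_signed_distance, build_scene, unit_cube


# ---------------------------------------------------------------------
# clone_jaw
# ---------------------------------------------------------------------

def test_clone_is_identical_but_postop(default_case):
    clone = clone_jaw(default_case.maxilla)
    assert clone.stage == "postop"
    assert np.array_equal(clone.mesh.vertices, default_case.maxilla.mesh.vertices)
    assert set(clone.pivots) == set(default_case.maxilla.pivots)


def test_clone_isolation(default_case):
    original = default_case.maxilla
    before = original.mesh.vertices.copy()
    clone = clone_jaw(original)
    clone.mesh.vertices += 5.0
    clone.pivots["Ie"].position[:] = 99.0  # in-place array mutation
    assert np.array_equal(original.mesh.vertices, before)
    assert np.allclose(original.pivot("Ie").position, [0, 0, 0])


def test_clone_of_clone(default_case):
    c2 = clone_jaw(clone_jaw(default_case.maxilla))
    assert np.array_equal(c2.mesh.vertices, default_case.maxilla.mesh.vertices)


# ---------------------------------------------------------------------
# move_jaw
# ---------------------------------------------------------------------

def test_pure_translation_shifts_all_pivots(default_case):
    jaw = clone_jaw(default_case.maxilla)
    moved = move_jaw(jaw, PlannedMove(jaw="maxilla", translation=(5.0, 0.0, 0.0)))
    for name in jaw.pivots:
        assert np.allclose(
            moved.pivot(name).position - jaw.pivot(name).position, [5, 0, 0]
        )


def test_rotation_fixes_center_pivot(default_case):
    jaw = clone_jaw(default_case.maxilla)
    moved = move_jaw(
        jaw,
        PlannedMove(
            jaw="maxilla", rotation_axis=(0.0, 1.0, 0.0), rotation_angle_deg=12.0,
            center="Ie",
        ),
    )
    assert np.abs(moved.pivot("Ie").position - jaw.pivot("Ie").position).max() < 1e-12


def test_rotation_chord_closed_form(default_case, mounted_scene):
    """10 deg about the hinge pivot moves Ie by 2 r sin(5 deg)."""
    scene = mounted_scene
    jaw = clone_jaw(scene.maxilla)
    jaw.add_pivot(Pivot("hinge_axis", scene.hinge_pivot.position))
    r = np.linalg.norm(jaw.pivot("Ie").position - jaw.pivot("hinge_axis").position)
    moved = move_jaw(
        jaw,
        PlannedMove(
            jaw="maxilla", rotation_axis=(1.0, 0.0, 0.0), rotation_angle_deg=10.0,
            center="hinge_axis",
        ),
    )
    chord = np.linalg.norm(moved.pivot("Ie").position - jaw.pivot("Ie").position)
    assert chord == pytest.approx(2 * r * np.sin(np.radians(5.0)), abs=1e-9)


def test_move_unknown_pivot(default_case):
    with pytest.raises(UnknownPivot):
        move_jaw(
            clone_jaw(default_case.maxilla),
            PlannedMove(
                jaw="maxilla", rotation_axis=(0, 0, 1.0), rotation_angle_deg=3.0,
                center="nope",
            ),
        )


def test_move_requires_unit_axis():
    with pytest.raises(ValueError):
        PlannedMove(jaw="maxilla", rotation_axis=(0, 0, 2.0), rotation_angle_deg=3.0)


# ---------------------------------------------------------------------
# measure_displacements
# ---------------------------------------------------------------------

def test_identical_jaws_zero_deltas(default_case):
    report = measure_displacements(default_case.maxilla, clone_jaw(default_case.maxilla))
    for row in report.rows:
        assert row.euclidean == 0.0
        assert row.delta_xyz == (0.0, 0.0, 0.0)


def test_translation_deltas(default_case):
    post = move_jaw(
        clone_jaw(default_case.maxilla),
        PlannedMove(jaw="maxilla", translation=(5.0, 0.0, 0.0)),
    )
    report = measure_displacements(default_case.maxilla, post)
    for row in report.rows:
        assert row.delta_xyz == pytest.approx((5.0, 0.0, 0.0), abs=1e-12)
        assert row.euclidean == pytest.approx(5.0, abs=1e-12)


def test_rows_sorted_and_euclidean_consistent(default_case):
    post = move_jaw(
        clone_jaw(default_case.maxilla),
        PlannedMove(
            jaw="maxilla", translation=(1.0, -2.0, 0.5),
            rotation_axis=(0.0, 1.0, 0.0), rotation_angle_deg=4.0, center="Ie",
        ),
    )
    report = measure_displacements(default_case.maxilla, post)
    names = [r.name for r in report.rows]
    assert names == sorted(names)
    for row in report.rows:
        assert row.euclidean == pytest.approx(
            np.linalg.norm(row.delta_xyz), abs=1e-12
        )


def test_pivot_mismatch(default_case):
    post = clone_jaw(default_case.maxilla)
    post.pivots.pop("raphe_ant")
    with pytest.raises(PivotMismatch):
        measure_displacements(default_case.maxilla, post)


def test_inverse_move_returns_zero_deltas(default_case):
    jaw = clone_jaw(default_case.maxilla)
    fwd = PlannedMove(
        jaw="maxilla", translation=(2.0, 1.0, -3.0),
        rotation_axis=(0.0, 0.0, 1.0), rotation_angle_deg=7.0, center="Ie",
    )
    moved = move_jaw(jaw, fwd)
    # undo: inverse rotation about the *moved* center, inverse translation first
    undone = move_jaw(
        move_jaw(moved, PlannedMove(jaw="maxilla", translation=(-2.0, -1.0, 3.0))),
        PlannedMove(
            jaw="maxilla", rotation_axis=(0.0, 0.0, 1.0), rotation_angle_deg=-7.0,
            center="Ie",
        ),
    )
    report = measure_displacements(jaw, undone)
    for row in report.rows:
        assert row.euclidean < 1e-9


# ---------------------------------------------------------------------
# detect_contacts
# ---------------------------------------------------------------------

def _cube_jaw(label, center, half=0.5, stage="preop"):
    return JawModel(label=label, mesh=unit_cube(center, half), stage=stage)


def test_separated_meshes_empty_report():
    up = _cube_jaw("maxilla", (0, 10, 0))
    lo = _cube_jaw("mandible", (0, 0, 0))
    assert detect_contacts(up, lo, 0.1).empty


def test_coincident_meshes_all_reported():
    up = _cube_jaw("maxilla", (0, 0, 0))
    lo = _cube_jaw("mandible", (0, 0, 0))
    report = detect_contacts(up, lo, 0.1)
    assert len(report.upper_indices) == len(up.mesh.vertices)
    assert all(d <= 0.0 for d in report.upper_distances)


def test_overlapping_cubes_match_brute_force_oracle():
    """Two unit cubes overlapping by 0.5 mm: the contact set must equal
    the closed-form box signed-distance oracle exactly."""
    up = _cube_jaw("maxilla", (0.0, 0.5, 0.0))
    lo = _cube_jaw("mandible", (0.0, 0.0, 0.0))
    tol = 0.25
    report = detect_contacts(up, lo, tol)
    oracle_up = box_signed_distance(up.mesh.vertices, (0.0, 0.0, 0.0), 0.5)
    oracle_lo = box_signed_distance(lo.mesh.vertices, (0.0, 0.5, 0.0), 0.5)
    assert list(report.upper_indices) == list(np.flatnonzero(oracle_up <= tol))
    assert list(report.lower_indices) == list(np.flatnonzero(oracle_lo <= tol))
    for i, d in zip(report.upper_indices, report.upper_distances):
        assert d == pytest.approx(oracle_up[i], abs=1e-9)


def test_contacts_monotone_in_tolerance():
    up = _cube_jaw("maxilla", (0.0, 0.9, 0.2))
    lo = _cube_jaw("mandible", (0.0, 0.0, 0.0))
    small = detect_contacts(up, lo, 0.05)
    large = detect_contacts(up, lo, 0.5)
    assert set(small.upper_indices) <= set(large.upper_indices)
    assert set(small.lower_indices) <= set(large.lower_indices)


def test_contacts_symmetric_roles():
    up = _cube_jaw("maxilla", (0.0, 0.8, 0.0))
    lo = _cube_jaw("mandible", (0.0, 0.0, 0.0))
    a = detect_contacts(up, lo, 0.3)
    b = detect_contacts(lo, up, 0.3)
    assert a.upper_indices == b.lower_indices
    assert a.lower_indices == b.upper_indices


def test_synthetic_gap_thresholds():
    near = generate_synthetic_case(SyntheticCaseConfig(seed=1, interocclusal_gap=0.05))
    far = generate_synthetic_case(SyntheticCaseConfig(seed=1, interocclusal_gap=1.0))
    assert not detect_contacts(near.maxilla, near.mandible, 0.1).empty
    assert detect_contacts(far.maxilla, far.mandible, 0.1).empty


def test_tolerance_must_be_positive(default_case):
    with pytest.raises(ValueError):
        detect_contacts(default_case.maxilla, default_case.mandible, 0.0)


# ---------------------------------------------------------------------
# open_rotation
# ---------------------------------------------------------------------

def test_open_rotation_zero_identity(mounted_scene):
    out = open_rotation(mounted_scene.mandible, mounted_scene.hinge_pivot, 0.0)
    assert np.array_equal(out.mesh.vertices, mounted_scene.mandible.mesh.vertices)


def test_open_rotation_hinge_displacement_zero(mounted_scene):
    jaw = mounted_scene.mandible.copy()
    jaw.add_pivot(Pivot("hinge_axis", mounted_scene.hinge_pivot.position))
    out = open_rotation(jaw, mounted_scene.hinge_pivot, 15.0)
    assert np.abs(
        out.pivot("hinge_axis").position - jaw.pivot("hinge_axis").position
    ).max() < 1e-12


def test_open_rotation_chord_and_sense(mounted_scene):
    hinge = mounted_scene.hinge_pivot
    jaw = mounted_scene.mandible
    out = open_rotation(jaw, hinge, 2.0)
    r = np.linalg.norm(jaw.pivot("Ie").position - hinge.position)
    chord = np.linalg.norm(out.pivot("Ie").position - jaw.pivot("Ie").position)
    assert chord == pytest.approx(2 * r * np.sin(np.radians(1.0)), abs=1e-9)
    delta = out.pivot("Ie").position - jaw.pivot("Ie").position
    assert delta[1] < 0  # incisor moves inferiorly
    assert delta[2] < 0  # and posteriorly


def test_open_rotation_negative_angle_rejected(mounted_scene):
    with pytest.raises(ValueError):
        open_rotation(mounted_scene.mandible, mounted_scene.hinge_pivot, -1.0)


# ---------------------------------------------------------------------
# splint export & planning sheet
# ---------------------------------------------------------------------

def _planned_scene(case):
    scene = build_scene(case)
    scene.postop_maxilla = move_jaw(
        clone_jaw(scene.maxilla), PlannedMove(jaw="maxilla", translation=(0, 0, 4.0))
    )
    scene.postop_mandible = move_jaw(
        clone_jaw(scene.mandible), PlannedMove(jaw="mandible", translation=(0, 0, -3.0))
    )
    return scene


def test_bimaxillary_export_three_files(default_case, tmp_path):
    scene = _planned_scene(default_case)
    export = export_splint_set(scene, "bimaxillary", tmp_path / "splints")
    assert len(export.members) == 3
    kinds = {(m["jaw"], m["stage"], m["open_rotated"]) for m in export.members}
    assert kinds == {
        ("maxilla", "postop", False),
        ("mandible", "preop", False),
        ("mandible", "postop", True),
    }
    for m in export.members:
        assert (tmp_path / "splints" / m["file"]).exists()


@pytest.mark.parametrize("scenario,n", [("upper_only", 2), ("lower_only", 2)])
def test_single_jaw_exports_two_files(default_case, tmp_path, scenario, n):
    scene = _planned_scene(default_case)
    export = export_splint_set(scene, scenario, tmp_path / scenario)
    assert len(export.members) == n


def test_export_missing_stage(default_case, tmp_path):
    scene = build_scene(default_case)  # no postop jaws
    with pytest.raises(MissingStage):
        export_splint_set(scene, "bimaxillary", tmp_path / "x")


def test_export_roundtrip_preserves_scene_frame(default_case, tmp_path):
    scene = _planned_scene(default_case)
    export = export_splint_set(scene, "bimaxillary", tmp_path / "s")
    by_kind = {(m["jaw"], m["stage"], m["open_rotated"]): m["file"] for m in export.members}
    back = read_stl(tmp_path / "s" / by_kind[("maxilla", "postop", False)])
    v0 = np.sort(scene.postop_maxilla.mesh.vertices, axis=0)
    v1 = np.sort(back.vertices, axis=0)
    assert np.abs(v0 - v1).max() < 1e-4  # STL float32, coords ~ 100 mm


def test_planning_sheet_full_and_roundtrip(default_case, tmp_path):
    import csv

    scene = _planned_scene(default_case)
    reports = [
        measure_displacements(scene.maxilla, scene.postop_maxilla),
        measure_displacements(scene.mandible, scene.postop_mandible),
    ]
    contact = detect_contacts(scene.postop_maxilla, scene.postop_mandible, 0.1)
    export = export_splint_set(scene, "bimaxillary", tmp_path / "spl")
    sheet = write_planning_sheet(
        tmp_path / "sheet",
        mounting_params=default_case.truth,
        displacement_reports=reports,
        contact_report=contact,
        splint_set=export,
        lambda_applied=scene.lambda_applied,
    )
    doc = json.loads((tmp_path / "sheet" / "planning_sheet.json").read_text())
    for key in ("mounting_parameters", "displacements", "contacts", "splint_manifest"):
        assert key in doc

    with (tmp_path / "sheet" / "displacements.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    by_key = {(r["jaw"], r["pivot"]): r for r in rows}
    for report in reports:
        for row in report.rows:
            parsed = by_key[(report.jaw, row.name)]
            assert float(parsed["dz"]) == pytest.approx(row.delta_xyz[2], abs=1e-6)
            assert float(parsed["euclidean"]) == pytest.approx(row.euclidean, abs=1e-6)


def test_planning_sheet_mounting_only(default_case, tmp_path):
    sheet = write_planning_sheet(tmp_path / "min", mounting_params=default_case.truth)
    assert "mounting_parameters" in sheet
    assert "displacements" not in sheet


def test_preop_jaws_immutable_through_planning(default_case, tmp_path):
    scene = build_scene(default_case)
    digest = scene.maxilla.mesh.vertices.tobytes()
    clones = [clone_jaw(scene.maxilla) for _ in range(4)]
    for i, c in enumerate(clones):
        move_jaw(c, PlannedMove(jaw="maxilla", translation=(i, 0, 0)))
    scene.postop_mandible = move_jaw(
        clone_jaw(scene.mandible), PlannedMove(jaw="mandible", translation=(0, 1, 0))
    )
    export_splint_set(scene, "lower_only", tmp_path / "e")
    assert scene.maxilla.mesh.vertices.tobytes() == digest
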