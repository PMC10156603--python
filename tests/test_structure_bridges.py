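"""Bridge contacts, formation/change reports, SASA/BSA on toy structures."""

import math

import numpy as np
import pytest

from smdecode.structure_bridges import (
    BridgeDefinition,
    MissingResidueError,
    StructureError,
    bridge_change,
    bridge_formation,
    buried_surface_area,
    contact_formed,
    load_bridge_definitions,
    load_model,
    shrake_rupley_sasa,
    write_fixture,
)


def _atom(chain, resid, x, y, z, name="CA", element="C", resname="GLY"):
    return dict(chain=chain, resid=resid, resname=resname, name=name,
                element=element, x=x, y=y, z=z)


def _pair_model(tmp_path, dx, fname="pair.pdb"):
    atoms = [_atom("S", 1, 0, 0, 0), _atom("L", 1, dx, 0, 0)]
    return load_model(write_fixture(atoms, tmp_path / fname))


@pytest.fixture()
def bridge_fixture_pair(tmp_path):
    """Two conformations of a toy ribosome with four bridges.

    State A: B8 fully broken, B2b fully formed, 'swap' has points {1,2}
    formed; state B: B8 fully formed, B2b broken, 'swap' has points {3,4}
    formed (same total, every individual point changed).
    """
    def build(formed_map, fname):
        atoms = []
        i = 0
        for bridge, points in formed_map.items():
            for resid, formed in points:
                y = 10.0 * i
                atoms.append(_atom("S", resid, 0, y, 0))
                atoms.append(_atom("L", resid, 3.5 if formed else 8.0, y, 0))
                i += 1
        return load_model(write_fixture(atoms, fname))

    defs = [
        BridgeDefinition("B8", tuple((("S", str(r)), ("L", str(r))) for r in (1, 2, 3, 4))),
        BridgeDefinition("B2b", tuple((("S", str(r)), ("L", str(r))) for r in (11, 12))),
        BridgeDefinition("swap", tuple((("S", str(r)), ("L", str(r))) for r in (21, 22, 23, 24))),
    ]
    a = build({"B8": [(r, False) for r in (1, 2, 3, 4)],
               "B2b": [(r, True) for r in (11, 12)],
               "swap": [(21, True), (22, True), (23, False), (24, False)]},
              tmp_path / "a.pdb")
    b = build({"B8": [(r, True) for r in (1, 2, 3, 4)],
               "B2b": [(r, False) for r in (11, 12)],
               "swap": [(21, False), (22, False), (23, True), (24, True)]},
              tmp_path / "b.pdb")
    return a, b, defs


def test_fixture_roundtrips_through_pdb_and_mmcif(tmp_path):
    atoms = [_atom("A", 1, 1.234, -2.5, 3.75), _atom("A", 2, 0, 0, 0, name="N", element="N"),
             _atom("B", 5, 9.0, 8.0, 7.0)]
    m_pdb = load_model(write_fixture(atoms, tmp_path / "f.pdb"))
    m_cif = load_model(write_fixture(atoms, tmp_path / "f.cif", fmt="mmcif"), fmt="mmcif")
    assert m_pdb.n_atoms == 3
    assert np.allclose(m_pdb.xyz[0], [1.234, -2.5, 3.75], atol=1e-3)
    assert np.allclose(m_pdb.xyz, m_cif.xyz, atol=1e-3)
    assert list(m_pdb.chain) == list(m_cif.chain)


def test_malformed_file_raises_parse_error(tmp_path):
    bad = tmp_path / "bad.cif"
    bad.write_text("this is not a structure\n")
    with pytest.raises(StructureError):
        load_model(bad, fmt="mmcif")


@pytest.mark.parametrize(
    "dx,expected", [(3.9, True), (4.0, True), (4.1, False)]
)
def test_contact_threshold_boundary(tmp_path, dx, expected):
    m = _pair_model(tmp_path, dx, f"p{dx}.pdb")
    formed, dmin = contact_formed(m, (("S", "1"), ("L", "1")))
    assert formed is expected
    assert dmin == pytest.approx(dx)


def test_contact_is_symmetric_and_rigid_invariant(tmp_path):
    m = _pair_model(tmp_path, 3.9)
    f1, d1 = contact_formed(m, (("S", "1"), ("L", "1")))
    f2, d2 = contact_formed(m, (("L", "1"), ("S", "1")))
    assert f1 == f2 and d1 == pytest.approx(d2)
    theta = 0.7
    rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                    [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
    moved = m.transformed(rot, np.array([10.0, -3.0, 5.0]))
    f3, d3 = contact_formed(moved, (("S", "1"), ("L", "1")))
    assert f3 == f1 and d3 == pytest.approx(d1)


def test_missing_residue_reported(tmp_path):
    m = _pair_model(tmp_path, 3.9)
    with pytest.raises(MissingResidueError):
        contact_formed(m, (("S", "1"), ("L", "99")))


def test_bridge_formation_percentages(bridge_fixture_pair):
    a, b, defs = bridge_fixture_pair
    rep_a = bridge_formation(a, defs).set_index("bridge")
    assert rep_a.loc["B8", "percent_formed"] == 0.0
    assert rep_a.loc["B2b", "percent_formed"] == 100.0
    assert rep_a.loc["swap", "percent_formed"] == 50.0
    rep_b = bridge_formation(b, defs).set_index("bridge")
    assert rep_b.loc["B8", "percent_formed"] == 100.0
    with pytest.raises(StructureError):
        bridge_formation(a, [])


def test_quarter_formed_bridge(tmp_path):
    atoms = []
    for r, formed in [(1, True), (2, False), (3, False), (4, False)]:
        y = 10.0 * r
        atoms.append(_atom("S", r, 0, y, 0))
        atoms.append(_atom("L", r, 3.0 if formed else 9.0, y, 0))
    m = load_model(write_fixture(atoms, tmp_path / "q.pdb"))
    d = [BridgeDefinition("toy", tuple((("S", str(r)), ("L", str(r))) for r in (1, 2, 3, 4)))]
    assert bridge_formation(m, d)["percent_formed"].item() == 25.0


def test_bridge_change_identity_swap_and_sign(bridge_fixture_pair):
    a, b, defs = bridge_fixture_pair
    same = bridge_change(a, a, defs).set_index("bridge")
    assert (same["individual_change_percent"] == 0).all()

    ab = bridge_change(a, b, defs).set_index("bridge")
    # same total percentage, 100% individual change for the swap bridge
    assert ab.loc["swap", "percent_a"] == ab.loc["swap", "percent_b"] == 50.0
    assert abs(ab.loc["swap", "individual_change_percent"]) == 100.0
    assert ab.loc["B8", "individual_change_percent"] == 100.0   # gained
    assert ab.loc["B2b", "individual_change_percent"] == -100.0  # lost

    ba = bridge_change(b, a, defs).set_index("bridge")
    assert ba.loc["B8", "individual_change_percent"] == -100.0
    assert ba.loc["B2b", "individual_change_percent"] == 100.0


def test_unresolved_points_excluded_with_warning(bridge_fixture_pair, tmp_path):
    a, _, defs = bridge_fixture_pair
    defs2 = defs + [BridgeDefinition("ghost", ((("S", "999"), ("L", "999")),))]
    with pytest.warns(UserWarning, match="unresolved"):
        rep = bridge_formation(a, defs2).set_index("bridge")
    assert rep.loc["ghost", "n_unresolved"] == 1
    assert np.isnan(rep.loc["ghost", "percent_formed"])


def test_packaged_bridge_definitions_load():
    defs = load_bridge_definitions()
    names = {d.name for d in defs}
    assert {"B2b", "B2e", "B7a", "B8", "eB8", "eB13"} <= names
    assert all(len(d.points) >= 1 for d in defs)


# -- SASA / BSA ------------------------------------------------------------


def test_isolated_sphere_sasa_is_analytic():
    sasa = shrake_rupley_sasa(np.zeros((1, 3)), np.array(["C"]))
    R = 1.70 + 1.4
    assert sasa.sum() == pytest.approx(4 * math.pi * R * R, rel=1e-6)


def test_two_sphere_bsa_matches_spherical_cap(tmp_path):
    """Two overlapping equal spheres: buried area is two spherical caps,
    2 x 2 pi R (R - d/2)."""
    d = 2.0
    atoms = [_atom("A", 1, 0, 0, 0, resname="LIG"), _atom("B", 1, d, 0, 0, resname="REC")]
    m = load_model(write_fixture(atoms, tmp_path / "s.pdb"))
    bsa = buried_surface_area(m, m.chain == "A")
    R = 1.70 + 1.4
    analytic = 2 * 2 * math.pi * R * (R - d / 2)
    assert abs(bsa - analytic) / analytic < 0.02


def test_far_ligand_buries_nothing(tmp_path):
    atoms = [_atom("A", 1, 0, 0, 0), _atom("B", 1, 50, 0, 0)]
    m = load_model(write_fixture(atoms, tmp_path / "far.pdb"))
    assert abs(buried_surface_area(m, m.chain == "A")) < 1.0


def test_bsa_monotone_in_separation_and_rigid_invariant(tmp_path):
    values = []
    for d in (1.5, 2.5, 3.5, 5.0, 7.0):
        atoms = [_atom("A", 1, 0, 0, 0), _atom("B", 1, d, 0, 0)]
        m = load_model(write_fixture(atoms, tmp_path / f"m{d}.pdb"))
        values.append(buried_surface_area(m, m.chain == "A"))
    assert all(a >= b - 1e-6 for a, b in zip(values[:-1], values[1:]))
    assert values[-1] == pytest.approx(0.0, abs=1e-6)
    atoms = [_atom("A", 1, 0, 0, 0), _atom("B", 1, 2.5, 0, 0)]
    m = load_model(write_fixture(atoms, tmp_path / "ri.pdb"))
    rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
    moved = m.transformed(rot, np.array([5.0, 5.0, 5.0]))
    assert buried_surface_area(moved, moved.chain == "A") == pytest.approx(
        buried_surface_area(m, m.chain == "A"), rel=0.02
    )


def test_sasa_point_count_convergence(tmp_path):
    """Doubling the sphere sampling changes the BSA by < 1%."""
    atoms = [
        _atom("A", 1, 0, 0, 0), _atom("A", 1, 1.4, 0.3, 0, name="CB"),
        _atom("B", 1, 3.2, 0, 0), _atom("B", 1, 4.0, 1.0, 0.5, name="CB"),
    ]
    m = load_model(write_fixture(atoms, tmp_path / "c.pdb"))
    b1 = buried_surface_area(m, m.chain == "A", n_points=960)
    b2 = buried_surface_area(m, m.chain == "A", n_points=1920)
    assert abs(b1 - b2) / b2 < 0.01


def test_empty_ligand_selection_rejected(tmp_path):
    m = _pair_model(tmp_path, 3.0)
    with pytest.raises(StructureError):
        buried_surface_area(m, np.zeros(m.n_atoms, dtype=bool))
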