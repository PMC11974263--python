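"""Geometry module: XYZ I/O, ring torsions, planarity metrics, HOMA."""

import math

import numpy as np
import pytest

from tsqscreen import (
    ConfigurationError,
    DegenerateGeometryError,
    HomaParameters,
    PairingError,
    PlanaritySummary,
    RingIndexError,
    StateGeometry,
    StateLabel,
    UnknownElementError,
    XYZParseError,
    delta_phi,
    generate_ring_geometry,
    homa,
    mean_abs_dihedral,
    read_xyz,
    ring_torsions,
    write_xyz,
)

from conftest import dihedral_oracle


def octagon(radius=1.83):
    theta = 2 * np.pi * np.arange(8) / 8
    coords = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(8)])
    return StateGeometry("oct", StateLabel.S0, ("C",) * 8, coords, tuple(range(8)))


class TestXYZ:
    def test_roundtrip_preserves_coordinates(self, tmp_path):
        geom = generate_ring_geometry(8, 0.3, "tub", jitter=0.02, seed=3)
        path = tmp_path / "ring.xyz"
        write_xyz(geom, path)
        back = read_xyz(path)
        assert back.compound_id == geom.compound_id
        assert back.state_label == geom.state_label
        assert back.elements == geom.elements
        assert back.ring_atoms == geom.ring_atoms
        np.testing.assert_allclose(back.coords, geom.coords, atol=1e-6)

    def test_explicit_ring_atoms_override_sidecar(self, tmp_path):
        geom = octagon()
        path = tmp_path / "oct.xyz"
        write_xyz(geom, path)
        back = read_xyz(path, ring_atoms=range(8))
        assert back.ring_atoms == tuple(range(8))

    def test_count_line_mismatch_raises(self, tmp_path):
        path = tmp_path / "bad.xyz"
        lines = ["10", "comment"] + [f"C {i:.1f} 0.0 0.0" for i in range(8)]
        path.write_text("\n".join(lines))
        with pytest.raises(XYZParseError):
            read_xyz(path, ring_atoms=range(6))

    def test_unknown_element_raises(self, tmp_path):
        geom = octagon()
        path = tmp_path / "oct.xyz"
        write_xyz(geom, path)
        text = path.read_text().replace("C ", "Qq ", 1)
        path.write_text(text)
        with pytest.raises(UnknownElementError):
            read_xyz(path, ring_atoms=range(8))

    def test_ring_index_out_of_range_raises(self, tmp_path):
        geom = octagon()
        path = tmp_path / "oct.xyz"
        write_xyz(geom, path)
        with pytest.raises(RingIndexError):
            read_xyz(path, ring_atoms=[0, 1, 2, 3, 4, 5, 6, 99])

    def test_missing_ring_spec_raises(self, tmp_path):
        geom = octagon()
        path = tmp_path / "oct.xyz"
        write_xyz(geom, path, sidecar=False)
        with pytest.raises(RingIndexError):
            read_xyz(path)


class TestStateGeometry:
    def test_ring_size_must_be_6_to_8(self):
        theta = 2 * np.pi * np.arange(5) / 5
        coords = np.column_stack(
            [1.2 * np.cos(theta), 1.2 * np.sin(theta), np.zeros(5)]
        )
        with pytest.raises(RingIndexError):
            StateGeometry("x", "S0", ("C",) * 5, coords, tuple(range(5)))

    def test_nonbonded_ring_sequence_rejected(self):
        geom = octagon()
        # skipping every other atom doubles the consecutive distances
        with pytest.raises(RingIndexError):
            StateGeometry(
                "x", "S0", geom.elements, geom.coords * 2.0, tuple(range(8))
            )


class TestTorsions:
    def test_planar_octagon_all_zero(self):
        np.testing.assert_allclose(ring_torsions(octagon()), 0.0, atol=1e-10)

    def test_chair_hexagon_alternates_in_sign(self):
        geom = generate_ring_geometry(6, 0.25, "chair-like")
        tors = ring_torsions(geom)
        assert len(tors) == 6
        mags = np.abs(tors)
        np.testing.assert_allclose(mags, mags[0], rtol=1e-8)
        assert np.all(np.sign(tors[:-1]) == -np.sign(tors[1:]))
        # each torsion equals the independent vector-algebra oracle
        ring = geom.coords[list(geom.ring_atoms)]
        for i, t in enumerate(tors):
            expect = dihedral_oracle(
                ring[i], ring[(i + 1) % 6], ring[(i + 2) % 6], ring[(i + 3) % 6]
            )
            assert t == pytest.approx(expect, abs=1e-8)

    def test_matches_oracle_on_random_geometries(self, puckered_octagon):
        ring = puckered_octagon.coords[list(puckered_octagon.ring_atoms)]
        tors = ring_torsions(puckered_octagon)
        for i in range(8):
            expect = dihedral_oracle(
                ring[i], ring[(i + 1) % 8], ring[(i + 2) % 8], ring[(i + 3) % 8]
            )
            assert tors[i] == pytest.approx(expect, abs=1e-8)

    def test_reversed_ring_order_same_magnitudes(self, puckered_octagon):
        fwd = np.sort(np.abs(ring_torsions(puckered_octagon)))
        rev_geom = StateGeometry(
            puckered_octagon.compound_id,
            puckered_octagon.state_label,
            puckered_octagon.elements,
            puckered_octagon.coords,
            tuple(reversed(puckered_octagon.ring_atoms)),
        )
        rev = np.sort(np.abs(ring_torsions(rev_geom)))
        np.testing.assert_allclose(fwd, rev, atol=1e-10)

    def test_collinear_triple_raises(self):
        coords = np.array(
            [[float(i), 0.0, 0.0] for i in range(3)]
            + [[2.0, 1.0, 0.0], [1.5, 2.0, 0.0], [0.0, 1.0, 0.0]]
        )
        geom = StateGeometry("lin", "S0", ("C",) * 6, coords, tuple(range(6)))
        with pytest.raises(DegenerateGeometryError):
            ring_torsions(geom)


class TestPlanarity:
    def test_mean_abs_dihedral_planar_is_zero(self):
        assert mean_abs_dihedral(octagon()) == pytest.approx(0.0, abs=1e-10)

    def test_mean_abs_dihedral_equals_brute_force(self, puckered_octagon):
        ring = puckered_octagon.coords[list(puckered_octagon.ring_atoms)]
        brute = np.mean(
            [
                abs(
                    dihedral_oracle(
                        ring[i], ring[(i + 1) % 8], ring[(i + 2) % 8], ring[(i + 3) % 8]
                    )
                )
                for i in range(8)
            ]
        )
        assert mean_abs_dihedral(puckered_octagon) == pytest.approx(brute, abs=1e-8)

    def test_phi_invariant_under_rigid_motion_and_relabeling(self, puckered_octagon):
        phi = mean_abs_dihedral(puckered_octagon)
        # rigid rotation + translation
        ang = 0.7
        rot = np.array(
            [
                [math.cos(ang), -math.sin(ang), 0],
                [math.sin(ang), math.cos(ang), 0],
                [0, 0, 1],
            ]
        )
        moved = StateGeometry(
            "oct",
            "S0",
            puckered_octagon.elements,
            puckered_octagon.coords @ rot.T + np.array([1.0, -2.0, 3.0]),
            puckered_octagon.ring_atoms,
        )
        assert mean_abs_dihedral(moved) == pytest.approx(phi, abs=1e-9)
        # cyclic relabeling of the ring
        ring = puckered_octagon.ring_atoms
        for shift in (1, 3, 5):
            cyc = StateGeometry(
                "oct",
                "S0",
                puckered_octagon.elements,
                puckered_octagon.coords,
                ring[shift:] + ring[:shift],
            )
            assert mean_abs_dihedral(cyc) == pytest.approx(phi, abs=1e-9)

    @pytest.mark.parametrize(
        "amp_t1, amp_s0, sign",
        [(0.0, 0.3, -1), (0.3, 0.0, +1), (0.2, 0.2, 0)],
    )
    def test_delta_phi_sign_convention(self, amp_t1, amp_s0, sign):
        t1 = generate_ring_geometry(8, amp_t1, "tub" if amp_t1 else "planar",
                                    compound_id="c", state_label="T1")
        s0 = generate_ring_geometry(8, amp_s0, "tub" if amp_s0 else "planar",
                                    compound_id="c", state_label="S0")
        summary = delta_phi(t1, s0)
        assert summary.delta_phi == summary.phi_t1 - summary.phi_s0
        if sign < 0:
            assert summary.delta_phi < 0 and summary.planarizes_in_t1
        elif sign > 0:
            assert summary.delta_phi > 0 and not summary.planarizes_in_t1
        else:
            assert summary.delta_phi == pytest.approx(0.0, abs=1e-9)

    def test_delta_phi_antisymmetric_under_state_swap(self):
        t1 = generate_ring_geometry(8, 0.1, "tub", compound_id="c", state_label="T1")
        s0 = generate_ring_geometry(8, 0.4, "tub", compound_id="c", state_label="S0")
        assert delta_phi(t1, s0).delta_phi == pytest.approx(
            -delta_phi(s0, t1).delta_phi, abs=1e-12
        )

    def test_mismatched_compound_or_ring_raises(self):
        a = generate_ring_geometry(8, 0.1, "tub", compound_id="a", state_label="T1")
        b = generate_ring_geometry(8, 0.2, "tub", compound_id="b", state_label="S0")
        with pytest.raises(PairingError):
            delta_phi(a, b)
        c = generate_ring_geometry(6, 0.2, "tub", compound_id="a", state_label="S0")
        with pytest.raises(PairingError):
            delta_phi(a, c)

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            PlanaritySummary(phi_s0=-1.0, phi_t1=0.0)


def hexagon_with_bonds(lengths):
    """Planar all-carbon 6-ring with prescribed consecutive bond lengths."""
    # walk the perimeter with exterior turns of 60 degrees; for equal
    # lengths this closes exactly, for alternating lengths the ring stays
    # near-closed and only consecutive distances matter to HOMA
    pts = [np.zeros(2)]
    ang = 0.0
    for L in lengths[:-1]:
        pts.append(pts[-1] + L * np.array([math.cos(ang), math.sin(ang)]))
        ang += math.pi / 3
    coords = np.column_stack([np.array(pts), np.zeros(len(pts))])
    return StateGeometry("hex", "S0", ("C",) * 6, coords, tuple(range(6)))


class TestHoma:
    def test_equal_bonds_at_r_opt_give_one(self):
        geom = hexagon_with_bonds([1.388] * 6)
        assert homa(geom) == pytest.approx(1.0, abs=1e-9)

    def test_alternating_bond_hand_value(self):
        # 1 - 257.7 * mean((1.388-1.330)^2, (1.388-1.450)^2) = 0.07125
        geom = hexagon_with_bonds([1.330, 1.450] * 3)
        hand = 1 - 257.7 * (3 * 0.058**2 + 3 * 0.062**2) / 6
        assert hand == pytest.approx(0.0712, abs=5e-4)
        assert homa(geom) == pytest.approx(hand, abs=1e-6)

    def test_uniformly_stretched_ring_negative(self):
        geom = hexagon_with_bonds([1.60] * 6)
        assert homa(geom) < 0

    def test_strictly_decreases_with_single_bond_deviation(self):
        values = [
            homa(hexagon_with_bonds([1.388 + d] + [1.388] * 5))
            for d in (0.0, 0.02, 0.05, 0.1)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[0] == pytest.approx(1.0, abs=1e-9)

    def test_missing_bond_type_raises(self):
        geom = StateGeometry(
            "hetero",
            "S0",
            ("C", "C", "C", "C", "C", "P"),
            hexagon_with_bonds([1.388] * 6).coords,
            tuple(range(6)),
        )
        with pytest.raises(ConfigurationError):
            homa(geom)

    def test_heteroatom_bond_typing_is_unordered(self):
        coords = hexagon_with_bonds([1.388] * 6).coords
        cn = StateGeometry("a", "S0", ("C", "N", "C", "N", "C", "N"), coords, tuple(range(6)))
        nc = StateGeometry(
            "a", "S0", ("N", "C", "N", "C", "N", "C"), coords, tuple(range(6))
        )
        assert homa(cn) == pytest.approx(homa(nc), abs=1e-12)

    def test_json_override(self, tmp_path):
        path = tmp_path / "homa.json"
        path.write_text('{"CC": [100.0, 1.40]}')
        params = HomaParameters.from_json(path)
        assert params.lookup("C", "C") == (100.0, 1.40)
        # untouched entries keep the Krygowski defaults
        assert params.lookup("C", "N") == (93.52, 1.334)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            HomaParameters({frozenset({"C"}): (-1.0, 1.388)})
        with pytest.raises(ConfigurationError):
            HomaParameters({frozenset({"C"}): (257.7, 2.5)})
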