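"""Geometry QC: clashes, bond perception, valence audit, reference-geometry
deviations, connectivity diffs, property outliers, electronic flags."""

import itertools

import numpy as np
import pytest

import ligdyn as ld
from ligdyn.structure_qc import BondTable


def brute_force_clashes(coords, elements, fraction=0.5):
    from ligdyn.config import COVALENT_RADII

    out = []
    for i, j in itertools.combinations(range(len(elements)), 2):
        cutoff = fraction * (COVALENT_RADII[elements[i]] + COVALENT_RADII[elements[j]])
        if np.linalg.norm(coords[i] - coords[j]) < cutoff:
            out.append((i, j))
    return out


class TestClashes:
    def test_separated_carbons_clean(self):
        coords = np.array([[0, 0, 0], [3.0, 0, 0]], float)
        assert ld.detect_clashes(coords, ["C", "C"]) == []

    def test_overlapping_carbons_flagged(self):
        coords = np.array([[0, 0, 0], [0.3, 0, 0]], float)
        findings = ld.detect_clashes(coords, ["C", "C"])
        assert len(findings) == 1
        assert findings[0].kind == "clash"
        assert findings[0].atom_indices == (0, 1)

    def test_grid_equals_brute_force_on_random_atoms(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 12, (300, 3))
        elements = rng.choice(["C", "N", "O", "S"], 300).tolist()
        found = [
            f.atom_indices for f in ld.detect_clashes(coords, elements)
        ]
        assert found == brute_force_clashes(coords, elements)

    def test_bonded_pairs_exempt(self):
        coords = np.array([[0, 0, 0], [0.5, 0, 0]], float)
        bonds = BondTable(bonds={(0, 1): 1.0}, hybridization=["sp3", "sp3"])
        assert ld.detect_clashes(coords, ["C", "C"], bonds=bonds) == []


class TestPerceiveBonds:
    def test_ethane_like_single_bond_sp3(self):
        # staggered CH3-CH3 heavy skeleton: two carbons at 1.54 Å
        coords = np.array([[0, 0, 0], [1.54, 0, 0]], float)
        table, findings = ld.perceive_bonds(coords, ["C", "C"])
        assert table.bonds == {(0, 1): 1.0}
        assert findings == []
        assert table.hybridization == ["sp3", "sp3"]

    def test_ethene_like_double_bond_sp2(self):
        # C=C at 1.34 Å, each with 2 planar substituents
        coords = np.array(
            [
                [0.0, 0.0, 0.0], [1.34, 0.0, 0.0],
                [-0.77, 1.12, 0.0], [-0.77, -1.12, 0.0],
                [2.11, 1.12, 0.0], [2.11, -1.12, 0.0],
            ]
        )
        elements = ["C", "C", "C", "C", "C", "C"]
        table, _ = ld.perceive_bonds(coords, elements)
        assert table.bonds[(0, 1)] == 2.0
        assert table.hybridization[0] == "sp2"
        assert table.hybridization[1] == "sp2"

    def test_distant_atoms_not_bonded(self):
        coords = np.array([[0, 0, 0], [10.0, 0, 0]], float)
        table, _ = ld.perceive_bonds(coords, ["C", "C"])
        assert table.bonds == {}

    def test_overbonded_atom_embedded_finding(self):
        # 6 carbons crowded around one: degree 6 > allowed 4
        center = np.zeros(3)
        shell = 1.5 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            float,
        )
        coords = np.vstack([center, shell])
        _, findings = ld.perceive_bonds(coords, ["C"] * 7)
        kinds = [f.kind for f in findings if 0 in f.atom_indices]
        assert "valence_violation" in kinds


def guanidinium(planar=True, nh_charge=0):
    """Central C with three N at 1.33 Å; optionally pyramidalized."""
    angles = np.deg2rad([90, 210, 330])
    n_pos = 1.33 * np.column_stack(
        [np.cos(angles), np.sin(angles), np.zeros(3)]
    )
    center = np.zeros(3)
    if not planar:
        center = np.array([0.0, 0.0, 0.5])
    coords = np.vstack([center, n_pos])
    elements = ["C", "N", "N", "N"]
    charges = [0, nh_charge, nh_charge, nh_charge]
    return coords, elements, charges


class TestValenceAudit:
    def test_methane_connectivity_clean(self):
        bonds = BondTable(
            bonds={(0, i): 1.0 for i in range(1, 5)},
            hybridization=["sp3", "other", "other", "other", "other"],
        )
        assert ld.audit_valence(["C", "H", "H", "H", "H"], bonds) == []

    def test_tetravalent_neutral_nitrogen_flagged(self):
        bonds = BondTable(
            bonds={(0, i): 1.0 for i in range(1, 5)},
            hybridization=["sp3"] * 5,
        )
        findings = ld.audit_valence(["N", "C", "C", "C", "C"], bonds)
        assert any(
            f.kind == "valence_violation" and f.atom_indices == (0,)
            for f in findings
        )

    def test_charged_nitrogen_four_bonds_allowed(self):
        bonds = BondTable(
            bonds={(0, i): 1.0 for i in range(1, 5)},
            hybridization=["sp3"] * 5,
        )
        findings = ld.audit_valence(
            ["N", "C", "C", "C", "C"], bonds, formal_charges=[1, 0, 0, 0, 0]
        )
        assert not any(f.kind == "valence_violation" for f in findings)

    def test_overprotonated_guanidinium_local_charge_excess(self):
        """Three positively charged NH2 groups around a central carbon put
        +3 within one bond of it."""
        coords, elements, charges = guanidinium(nh_charge=1)
        table, _ = ld.perceive_bonds(coords, elements)
        findings = ld.audit_valence(elements, table, charges)
        excess = [f for f in findings if f.kind == "local_charge_excess"]
        assert excess
        central = [f for f in excess if f.atom_indices[0] == 0]
        assert central and central[0].measured == 3.0


def ideal_amide():
    """Planar HN-C(=O)-C fragment at reference geometry (heavy atoms)."""
    coords = np.array(
        [
            [0.000, 0.000, 0.0],    # C (carbonyl)
            [0.617, 1.045, 0.0],    # O, C=O 1.214 at 120.5 deg
            [0.672, -1.166, 0.0],   # N, C-N 1.346 at 120 deg
            [-1.518, -0.060, 0.0],  # C (alpha), C-C 1.519
            [2.132, -1.166, 0.0],   # C on N, N-C 1.46 at 120 deg
        ]
    )
    return coords, ["C", "O", "N", "C", "C"]


class TestGeometry:
    def test_ideal_amide_clean(self):
        coords, elements = ideal_amide()
        table, perception = ld.perceive_bonds(coords, elements)
        findings = ld.check_geometry(coords, elements, table)
        assert perception == []
        assert [f for f in findings if f.severity != "info"] == []

    def test_elongated_nitro_bonds_flagged(self):
        """N-O bonds 17% over the nitro reference are length deviations."""
        stretch = 1.17
        d = 1.212 * stretch
        angles = np.deg2rad([60, -60])
        o_pos = d * np.column_stack(
            [np.cos(angles), np.sin(angles), np.zeros(2)]
        )
        coords = np.vstack([[0, 0, 0], o_pos, [[-1.47, 0, 0]]])
        elements = ["N", "O", "O", "C"]
        # connectivity from chemistry (nitro: two N=O), geometry as deposited
        table = BondTable(
            bonds={(0, 1): 2.0, (0, 2): 2.0, (0, 3): 1.0},
            hybridization=["sp2", "sp2", "sp2", "sp3"],
        )
        findings = ld.check_geometry(coords, elements, table)
        long_bonds = [
            f for f in findings
            if f.kind == "bond_length_deviation" and f.severity == "warn"
        ]
        assert len(long_bonds) == 2
        assert {f.atom_indices for f in long_bonds} == {(0, 1), (0, 2)}

    def test_opened_ether_angle_flagged(self):
        """A C-O-C angle opened ~20 degrees beyond tetrahedral."""
        angle = np.deg2rad(109.47 + 20)
        coords = np.array(
            [
                [0, 0, 0],
                [1.43, 0, 0],
                [1.43 * np.cos(angle), 1.43 * np.sin(angle), 0],
            ]
        )
        elements = ["O", "C", "C"]
        table = BondTable(
            bonds={(0, 1): 1.0, (0, 2): 1.0},
            hybridization=["sp3", "sp3", "sp3"],
        )
        findings = ld.check_geometry(coords, elements, table)
        assert any(
            f.kind == "angle_deviation" and f.atom_indices[1] == 0
            for f in findings
        )

    def test_pyramidalized_sp2_center_flagged(self):
        coords, elements, _ = guanidinium(planar=False)
        table = BondTable(
            bonds={(0, 1): 1.5, (0, 2): 1.5, (0, 3): 1.5},
            hybridization=["sp2", "sp2", "sp2", "sp2"],
        )
        findings = ld.check_geometry(coords, elements, table)
        planarity = [f for f in findings if f.kind == "planarity_deviation"]
        assert planarity and planarity[0].atom_indices[0] == 0
        assert planarity[0].measured == pytest.approx(0.5, abs=1e-6)


class TestConnectivityDiff:
    def test_identical_tables_empty(self):
        t = BondTable(bonds={(0, 1): 1.0}, hybridization=["sp3", "sp3"])
        assert ld.compare_connectivity(t, t) == []

    def test_one_bond_broken(self):
        before = BondTable(
            bonds={(0, 1): 1.0, (1, 2): 1.0}, hybridization=["sp3"] * 3
        )
        after = BondTable(bonds={(0, 1): 1.0}, hybridization=["sp3"] * 3)
        findings = ld.compare_connectivity(before, after)
        assert len(findings) == 1
        assert findings[0].atom_indices == (1, 2)
        assert "broken" in findings[0].detail

    def test_random_edit_script_counted_exactly(self):
        rng = np.random.default_rng(1)
        n = 12
        pairs = list(itertools.combinations(range(n), 2))
        rng.shuffle(pairs)
        before = BondTable(
            bonds={p: 1.0 for p in pairs[:15]}, hybridization=["sp3"] * n
        )
        after_bonds = dict(before.bonds)
        k = 0
        for p in pairs[:5]:        # break 5
            del after_bonds[p]
            k += 1
        for p in pairs[15:19]:     # create 4
            after_bonds[p] = 1.0
            k += 1
        for p in pairs[5:8]:       # change order of 3
            after_bonds[p] = 2.0
            k += 1
        after = BondTable(bonds=after_bonds, hybridization=["sp3"] * n)
        assert len(ld.compare_connectivity(before, after)) == k

    def test_atom_count_mismatch_rejected(self):
        a = BondTable(bonds={}, hybridization=["sp3"] * 3)
        b = BondTable(bonds={}, hybridization=["sp3"] * 4)
        with pytest.raises(ld.ValidationError):
            ld.compare_connectivity(a, b)


class TestPropertyOutliers:
    def test_collinear_group_clean(self):
        x = np.linspace(-0.3, -0.1, 20)
        y = 2.0 - 3.0 * x
        findings = ld.flag_property_outliers(x, y, ["F"] * 20)
        assert [f for f in findings if f.severity == "warn"] == []

    def test_planted_point_flagged(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-0.35, -0.05, 51)
        y = 2.4 - 3.5 * x + rng.normal(0, 0.02, 51)
        y[17] += 10 * 0.02 * 12   # far off the line
        findings = ld.flag_property_outliers(x, y, ["Cl"] * 51)
        warned = [f for f in findings if f.severity == "warn"]
        assert len(warned) == 1 and warned[0].atom_indices == (17,)

    def test_small_group_skipped_with_info(self):
        findings = ld.flag_property_outliers(
            np.arange(3.0), np.arange(3.0), ["Br"] * 3
        )
        assert len(findings) == 1 and findings[0].severity == "info"

    def test_constant_x_falls_back_to_univariate(self):
        y = np.zeros(20)
        y[4] = 50.0
        findings = ld.flag_property_outliers(
            np.ones(20), y, ["I"] * 20
        )
        warned = [f for f in findings if f.severity == "warn"]
        assert len(warned) == 1 and warned[0].atom_indices == (4,)


class TestElectronicFlags:
    def test_healthy_record_clean(self):
        qm = ld.QMRecord(
            entry_id="Q", molecular={
                "homo_lumo_gap": 3.2, "n_electrons": 42, "closed_shell": 1,
            },
        )
        assert ld.screen_electronic_flags(qm) == []

    def test_vanishing_gap_warned(self):
        qm = ld.QMRecord(
            entry_id="Q", molecular={
                "homo_lumo_gap": 0.01, "n_electrons": 42, "closed_shell": 1,
            },
        )
        findings = ld.screen_electronic_flags(qm)
        assert len(findings) == 1 and findings[0].severity == "warn"

    def test_odd_electron_closed_shell_fails(self):
        qm = ld.QMRecord(
            entry_id="Q", molecular={
                "homo_lumo_gap": 3.0, "n_electrons": 41, "closed_shell": 1,
            },
        )
        findings = ld.screen_electronic_flags(qm)
        assert any(f.severity == "fail" for f in findings)

    def test_missing_fields_info_only(self):
        findings = ld.screen_electronic_flags(ld.QMRecord(entry_id="Q"))
        assert findings and all(f.severity == "info" for f in findings)


def test_checks_are_permutation_covariant():
    """Permuting atom order permutes finding indices identically."""
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 6, (25, 3))
    elements = rng.choice(["C", "N", "O"], 25).tolist()
    perm = rng.permutation(25)
    inverse = np.argsort(perm)
    direct = ld.detect_clashes(coords, elements)
    permuted = ld.detect_clashes(coords[perm], [elements[i] for i in perm])
    direct_pairs = {f.atom_indices for f in direct}
    mapped_back = {
        tuple(sorted((int(perm[a]), int(perm[b])))) for (a, b) in
        (f.atom_indices for f in permuted)
    }
    assert direct_pairs == mapped_back
    table_direct, _ = ld.perceive_bonds(coords, elements)
    table_perm, _ = ld.perceive_bonds(coords[perm], [elements[i] for i in perm])
    bonds_mapped = {
        tuple(sorted((int(perm[a]), int(perm[b])))) for (a, b) in table_perm.bonds
    }
    assert set(table_direct.bonds) == bonds_mapped
    assert [table_perm.hybridization[int(inverse[i])] for i in range(25)] == (
        table_direct.hybridization
    )


def test_generated_ligand_verdict_clean(toy_complex):
    lig = toy_complex.ligand_indices
    report = ld.run_qc(
        toy_complex.coordinates[lig], toy_complex.elements[lig], "LIG1"
    )
    assert report.verdict == "clean"
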