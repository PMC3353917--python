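"""Structural descriptor extraction: parsing, DSSP-style states, SASA, features."""

import numpy as np
import pytest

from randnat.sasa import atom_radii, compute_sasa, sasa_from_coords, sphere_points
from randnat.secondary import SecondaryStructureError, assign_secondary_structure
from randnat.structure_features import (
    PDBParseError,
    StructureModel,
    compute_net_charge,
    compute_volume,
    extract_features,
    parse_structure,
    surface_hydrophobicity,
    _residue_volumes,
)

from conftest import build_backbone, model_from_backbone, pdb_text_from_model

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       9.000   9.000   9.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       9.000   9.000  10.458  1.00  0.00           C
ATOM      3  C   ALA A   1       9.000  10.000  10.458  1.00  0.00           C
ENDMDL
END
"""

HETATM_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   2       1.000   0.000   0.000  0.30  0.00           C
ATOM      3  CA BSER A   2       5.000   0.000   0.000  0.70  0.00           C
END
"""


class TestParseStructure:
    def test_minimal_one_residue_two_atoms(self):
        model = parse_structure(MINIMAL_PDB)
        assert model.n_residues == 1
        assert model.n_atoms == 2
        assert model.sequence == "A"
        assert model.residue_serials == [1]

    def test_first_model_only(self):
        model = parse_structure(TWO_MODEL_PDB)
        assert model.n_atoms == 2
        assert np.allclose(model.atom_coords[0], [0.0, 0.0, 0.0])

    def test_hetatm_only_is_parse_error(self):
        with pytest.raises(PDBParseError):
            parse_structure(HETATM_ONLY_PDB)

    def test_no_atom_records_is_parse_error(self):
        with pytest.raises(PDBParseError):
            parse_structure("REMARK nothing here\nEND\n")

    def test_absent_chain_error_names_available(self):
        with pytest.raises(PDBParseError, match="A"):
            parse_structure(MINIMAL_PDB, chain="Q")

    def test_altloc_keeps_highest_occupancy(self):
        model = parse_structure(ALTLOC_PDB)
        ca = model.atom_coords[model.atom_res_index == 1]
        assert ca.shape == (1, 3)
        assert ca[0, 0] == pytest.approx(5.0)  # occupancy 0.70 conformer

    def test_hetatm_tail_ignored(self, helix_model):
        text = pdb_text_from_model(helix_model, het_tail=True)
        model = parse_structure(text)
        assert model.n_residues == helix_model.n_residues

    def test_roundtrip_preserves_geometry(self, helix_model):
        model = parse_structure(pdb_text_from_model(helix_model))
        assert model.n_atoms == helix_model.n_atoms
        assert np.allclose(model.atom_coords, helix_model.atom_coords, atol=1e-3)


class TestSecondaryStructure:
    def test_ideal_helix_mostly_H(self, helix_model):
        labels = assign_secondary_structure(helix_model)
        assert (labels == "H").mean() >= 0.80

    def test_antiparallel_sheet_mostly_E(self, sheet_model):
        labels = assign_secondary_structure(sheet_model)
        assert (labels == "E").mean() >= 0.60

    def test_isolated_strand_no_H_no_E(self, strand_model):
        labels = assign_secondary_structure(strand_model)
        assert (labels == "H").sum() == 0
        assert (labels == "E").sum() == 0

    def test_states_are_exclusive_and_exhaustive(self, helix_model, sheet_model):
        for model in (helix_model, sheet_model):
            labels = assign_secondary_structure(model)
            assert len(labels) == model.n_residues
            assert set(labels) <= {"H", "E", "T", "C"}

    def test_too_few_residues_is_error(self):
        model = model_from_backbone(build_backbone(4, phi=-57.0, psi=-47.0))
        with pytest.raises(SecondaryStructureError):
            assign_secondary_structure(model)


def _single_atom_model(radius_element="C"):
    return StructureModel(
        chain_id="A",
        sequence="G",
        residue_names=["GLY"],
        atom_elements=[radius_element],
        atom_names=["CA"],
        atom_res_index=np.array([0]),
        atom_coords=np.array([[0.0, 0.0, 0.0]]),
    )


def _mc_sasa(coords, radii, probe, n_points=20000, seed=0):
    """Independent Monte-Carlo surface-point oracle (random directions)."""
    rng = np.random.default_rng(seed)
    expanded = np.asarray(radii) + probe
    total = 0.0
    for i in range(len(coords)):
        u = rng.normal(size=(n_points, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * u
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            exposed &= ((pts - coords[j]) ** 2).sum(1) >= expanded[j] ** 2
        total += 4.0 * np.pi * expanded[i] ** 2 * exposed.mean()
    return total


class TestSASA:
    @pytest.mark.parametrize("r,probe", [(1.9, 1.4), (1.52, 1.4), (1.0, 0.5), (2.5, 2.0)])
    def test_isolated_sphere_closed_form(self, r, probe):
        area = sasa_from_coords(np.zeros((1, 3)), np.array([r]), probe)
        assert area[0] == pytest.approx(4 * np.pi * (r + probe) ** 2, rel=0.01)

    def test_two_distant_atoms_additive(self):
        coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        radii = np.array([1.7, 1.55])
        areas = sasa_from_coords(coords, radii, 1.4)
        expected = 4 * np.pi * (radii + 1.4) ** 2
        assert np.allclose(areas, expected, rtol=0.01)

    def test_two_overlapping_atoms_match_mc_oracle(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        radii = np.array([1.7, 1.7])
        total = sasa_from_coords(coords, radii, 1.4).sum()
        oracle = _mc_sasa(coords, radii, 1.4)
        assert total == pytest.approx(oracle, rel=0.02)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_cluster_matches_mc_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-2.5, 2.5, size=(5, 3))
        radii = rng.uniform(1.4, 1.9, size=5)
        total = sasa_from_coords(coords, radii, 1.4).sum()
        oracle = _mc_sasa(coords, radii, 1.4, seed=seed)
        assert total == pytest.approx(oracle, rel=0.02)

    def test_adding_atom_never_increases_others(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-2.0, 2.0, size=(4, 3))
        radii = np.full(4, 1.7)
        before = sasa_from_coords(coords, radii, 1.4)
        coords5 = np.vstack([coords, [[0.5, 0.5, 0.5]]])
        after = sasa_from_coords(coords5, np.full(5, 1.7), 1.4)[:4]
        assert (after <= before + 1e-9).all()

    def test_nonpositive_probe_is_error(self):
        with pytest.raises(ValueError):
            sasa_from_coords(np.zeros((1, 3)), np.array([1.7]), 0.0)

    def test_compute_sasa_residue_sums(self, helix_model):
        res = compute_sasa(helix_model, n_points=240)
        assert res.total == pytest.approx(res.residue_area.sum())
        assert res.total == pytest.approx(res.atom_area.sum())
        assert (res.residue_area >= 0).all()

    def test_against_biopython_shrake_rupley(self, helix_model):
        """Independent implementation cross-check on the same radii set."""
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley
        import io

        ours = compute_sasa(helix_model, probe_radius=1.4, n_points=960).total
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("m", io.StringIO(pdb_text_from_model(helix_model)))
        sr = ShrakeRupley(
            probe_radius=1.4,
            n_points=960,
            radii_dict={"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80},
        )
        sr.compute(structure, level="S")
        theirs = sum(a.sasa for a in structure.get_atoms())
        assert ours == pytest.approx(theirs, rel=0.02)

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(960)
        assert pts.shape == (960, 3)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_unknown_element_gets_default_radius(self):
        assert atom_radii(["ZZ"])[0] == pytest.approx(1.70)


class TestSequenceDescriptors:
    @pytest.mark.parametrize(
        "seq,expected", [("DEKKR", 1), ("GGGGG", 0), ("HHHH", 0), ("KKDD", 0), ("RRRR", 4)]
    )
    def test_net_charge_convention(self, seq, expected):
        assert compute_net_charge(seq) == expected

    def test_net_charge_rejects_nonstandard(self):
        with pytest.raises(ValueError, match="X"):
            compute_net_charge("ACDX")

    def test_net_charge_bounds(self):
        rng = np.random.default_rng(0)
        from randnat.sequence_gen import AA_ALPHABET

        for _ in range(20):
            seq = "".join(rng.choice(list(AA_ALPHABET), size=30))
            q = compute_net_charge(seq)
            assert -30 <= q <= 30

    def test_volume_gly_multiple(self):
        v_g = _residue_volumes()["G"]
        assert compute_volume("GGGGG") == pytest.approx(5 * v_g)

    def test_volume_additive_over_concatenation(self):
        s1, s2 = "ACDEF", "KLMNP"
        assert compute_volume(s1 + s2) == pytest.approx(
            compute_volume(s1) + compute_volume(s2)
        )

    def test_volume_matches_hand_summation(self):
        table = _residue_volumes()
        seq = "WYKDAGLIVS"
        assert compute_volume(seq) == pytest.approx(sum(table[a] for a in seq))

    def test_volume_empty_is_error(self):
        with pytest.raises(ValueError):
            compute_volume("")


class TestSurfaceHydrophobicity:
    def test_all_hydrophobic_is_one(self):
        model = model_from_backbone(
            build_backbone(6, phi=-57.0, psi=-47.0), resname="LEU", letter="L"
        )
        sasa = compute_sasa(model, n_points=240)
        assert surface_hydrophobicity(model, sasa.residue_area) == pytest.approx(1.0)

    def test_all_polar_is_zero(self):
        model = model_from_backbone(
            build_backbone(6, phi=-57.0, psi=-47.0), resname="ASP", letter="D"
        )
        sasa = compute_sasa(model, n_points=240)
        assert surface_hydrophobicity(model, sasa.residue_area) == pytest.approx(0.0)

    def test_mixed_chain_manual_ratio(self, helix_model):
        # relabel half the poly-Ala chain as polar residues
        n = helix_model.n_residues
        seq = "A" * (n // 2) + "D" * (n - n // 2)
        model = StructureModel(
            chain_id=helix_model.chain_id,
            sequence=seq,
            residue_names=["ALA"] * (n // 2) + ["ASP"] * (n - n // 2),
            atom_elements=helix_model.atom_elements,
            atom_names=helix_model.atom_names,
            atom_res_index=helix_model.atom_res_index,
            atom_coords=helix_model.atom_coords,
        )
        area = compute_sasa(model, n_points=240).residue_area
        expected = area[: n // 2].sum() / area.sum()
        assert surface_hydrophobicity(model, area) == pytest.approx(expected)

    def test_zero_area_is_error(self, helix_model):
        with pytest.raises(ValueError):
            surface_hydrophobicity(helix_model, np.zeros(helix_model.n_residues))


class TestExtractFeatures:
    def test_helix_percentages(self, helix_model):
        fv = extract_features(helix_model, n_points=240)
        n = helix_model.n_residues
        labels = assign_secondary_structure(helix_model)
        assert fv.pct_alpha == pytest.approx(100.0 * (labels == "H").sum() / n)
        assert fv.beta == 0
        assert fv.pct_beta == 0.0

    def test_pct_secondary_identity(self, helix_model, sheet_model):
        for model in (helix_model, sheet_model):
            fv = extract_features(model, n_points=240)
            assert fv.pct_secondary == fv.pct_alpha + fv.pct_beta

    def test_counts_bounded_by_length(self, sheet_model):
        fv = extract_features(sheet_model, n_points=240)
        assert 0 <= fv.alpha + fv.beta + fv.coil <= sheet_model.n_residues

    def test_deterministic(self, helix_model):
        fv1 = extract_features(helix_model, n_points=240)
        fv2 = extract_features(helix_model, n_points=240)
        assert fv1 == fv2

    def test_to_dict_has_canonical_names(self, helix_model):
        from randnat.structure_features import VARIABLE_NAMES

        fv = extract_features(helix_model, n_points=240)
        assert tuple(fv.to_dict().keys()) == VARIABLE_NAMES
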