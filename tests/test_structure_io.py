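"""Backbone parsing, validation, dihedrals and superposition RMSD."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from rdhmm.structure_io import (
    BackboneStructure,
    CorrespondenceError,
    EmptyStructureError,
    InsufficientResiduesError,
    backbone_rmsd,
    dihedral_angle,
    dihedrals,
    read_pdb,
    validate,
    write_pdb,
)
from rdhmm.synthetic_fixtures import FoldSpec, make_backbone

from conftest import torsion_oracle

MINIMAL_ALA = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  1.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  1.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  1.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  1.00           O
END
"""


def _transformed_copy(structure, seed=0):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
    shift = rng.normal(0, 20, 3)
    copy = read_pdb(write_pdb(structure))
    for r in copy.residues:
        for a in r.coords:
            r.coords[a] = rot @ r.coords[a] + shift
    return copy


class TestReadPdb:
    def test_minimal_single_residue(self):
        s = read_pdb(MINIMAL_ALA)
        assert len(s) == 1
        assert s.residues[0].res_name == "ALA"
        assert s.residues[0].is_complete()

    def test_residue_missing_oxygen_is_dropped(self, caplog):
        text = "\n".join(
            ln for ln in MINIMAL_ALA.splitlines() if " O " not in ln
        )
        with pytest.raises(EmptyStructureError):
            read_pdb(text)
        assert any("missing backbone atom" in r.message for r in caplog.records)

    def test_multi_model_selection(self):
        fold = make_backbone(FoldSpec([("helix", 10)]))
        shifted = _transformed_copy(fold, seed=3)
        text = (
            "MODEL     1\n" + write_pdb(fold).replace("END\n", "ENDMDL\n")
            + "MODEL     2\n" + write_pdb(shifted).replace("END\n", "ENDMDL\n")
            + "END\n"
        )
        m1 = read_pdb(text, model_index=1)
        m2 = read_pdb(text, model_index=2)
        assert np.allclose(m1.ca_coords, fold.ca_coords, atol=1e-3)
        assert not np.allclose(m2.ca_coords, fold.ca_coords, atol=1e-3)
        with pytest.raises(KeyError):
            read_pdb(text, model_index=3)

    def test_unknown_chain_raises(self):
        with pytest.raises(KeyError):
            read_pdb(MINIMAL_ALA, chain="Z")

    def test_altloc_keeps_highest_occupancy(self):
        text = (
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40  1.00           N\n"
            "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.60  1.00           N\n"
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  1.00           C\n"
            "ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  1.00           C\n"
            "ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00  1.00           O\n"
            "END\n"
        )
        s = read_pdb(text)
        assert s.residues[0].coords["N"][0] == pytest.approx(9.0, abs=1e-3)
        assert s.residues[0].had_altloc

    def test_roundtrip_preserves_coordinates(self):
        fold = make_backbone(FoldSpec([("helix", 6), ("strand", 6)]))
        again = read_pdb(write_pdb(fold))
        for a in ("N", "CA", "C", "O"):
            assert np.allclose(fold.atom_coords(a), again.atom_coords(a), atol=1.5e-3)


class TestValidate:
    def test_ideal_fold_is_clean(self):
        report = validate(make_backbone(FoldSpec([("helix", 12)])))
        assert report.passed

    def test_zero_bfactor_flagged(self):
        s = make_backbone(FoldSpec([("helix", 12)]))
        s.residues[4].b_factors["CA"] = 0.0
        report = validate(s)
        assert [(i.index, i.code) for i in report.issues] == [(4, "ZERO_BFACTOR")]

    def test_chain_break_flagged(self):
        s = make_backbone(FoldSpec([("helix", 12)]))
        for r in s.residues[6:]:
            for a in r.coords:
                r.coords[a] = r.coords[a] + np.array([8.0, 0, 0])
        codes = {i.code for i in validate(s).issues}
        assert "CHAIN_BREAK" in codes

    def test_nonstandard_name_flagged(self):
        s = make_backbone(FoldSpec([("helix", 12)]))
        s.residues[0].res_name = "UNK"
        assert any(i.code == "NONSTANDARD" for i in validate(s).issues)

    def test_report_tsv_has_header_and_rows(self):
        s = make_backbone(FoldSpec([("helix", 12)]))
        s.residues[2].b_factors["N"] = 0.0
        tsv = validate(s).to_tsv()
        assert tsv.startswith("index\tcode\tmessage")
        assert "ZERO_BFACTOR" in tsv


class TestDihedrals:
    def test_ideal_helix_angles(self):
        s = make_backbone(FoldSpec([("helix", 20)]))
        for phi, psi, _ in dihedrals(s)[1:-1]:
            assert phi == pytest.approx(-57.0, abs=0.5)
            assert psi == pytest.approx(-47.0, abs=0.5)

    def test_termini_undefined(self):
        d = dihedrals(make_backbone(FoldSpec([("helix", 10)])))
        assert d[0][0] is None and d[-1][1] is None and d[-1][2] is None

    def test_too_few_residues(self):
        s = read_pdb(MINIMAL_ALA)
        with pytest.raises(InsufficientResiduesError):
            dihedrals(s)

    @given(st.integers(0, 10_000))
    def test_matches_plane_normal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 3, (4, 3))
        # reject near-degenerate cases where both formulations are unstable
        b = np.diff(pts, axis=0)
        if min(np.linalg.norm(np.cross(b[0], b[1])),
               np.linalg.norm(np.cross(b[1], b[2]))) < 1e-3:
            return
        got = dihedral_angle(*pts)
        want = torsion_oracle(*pts)
        assert math.isclose(got, want, abs_tol=1e-6) or math.isclose(
            got + 360, want, abs_tol=1e-6) or math.isclose(got - 360, want, abs_tol=1e-6)

    def test_range_half_open(self):
        s = make_backbone(FoldSpec([("strand", 12)]))
        for phi, psi, om in dihedrals(s)[1:-1]:
            for ang in (phi, psi, om):
                assert -180.0 <= ang < 180.0


class TestBackboneRmsd:
    def test_self_is_zero(self, mixed_structure):
        assert backbone_rmsd(mixed_structure, mixed_structure) == pytest.approx(0.0, abs=1e-9)

    @given(st.integers(0, 500))
    def test_rigid_transform_invariance(self, seed):
        s = make_backbone(FoldSpec([("helix", 8), ("strand", 4)]))
        moved = _transformed_copy(s, seed=seed)
        assert backbone_rmsd(s, moved) == pytest.approx(0.0, abs=2e-3)

    def test_detects_real_displacement(self, mixed_structure):
        from rdhmm.synthetic_fixtures import PerturbSpec, perturb_backbone

        perturbed, achieved = perturb_backbone(mixed_structure, PerturbSpec(15.0, seed=9))
        assert backbone_rmsd(mixed_structure, perturbed) == pytest.approx(achieved, rel=1e-9)
        assert achieved > 0.3

    def test_correspondence_by_author_numbering(self):
        s = make_backbone(FoldSpec([("helix", 12)]))
        sub = BackboneStructure(s.residues[3:9])
        assert backbone_rmsd(s, sub) == pytest.approx(0.0, abs=1e-6)

    def test_no_common_residues_raises(self):
        s = make_backbone(FoldSpec([("helix", 12)]))
        other = read_pdb(write_pdb(s))
        for r in other.residues:
            r.res_seq += 1000
        with pytest.raises(CorrespondenceError):
            backbone_rmsd(s, other)
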