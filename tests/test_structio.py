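"""Structure / shift / mapping I/O."""

import numpy as np
import pytest

from flexscore import structio
from flexscore.types import Atom, ChemicalShiftSet, SegmentMapping, StructureEnsemble


def _atom(name, res_seq, coords, res_name="ALA", element=None, chain="A",
          bfactor=0.0, hetero=False):
    return Atom(name=name, element=element or name[0], res_seq=res_seq,
                res_name=res_name, chain_id=chain, coords=np.asarray(coords, float),
                bfactor=bfactor, hetero=hetero)


def _tripeptide(res_names=("ALA", "ALA", "ALA"), bfactor=0.0):
    """Minimal 3-residue backbone with plausible geometry."""
    atoms = []
    for i, rn in enumerate(res_names):
        x = 3.8 * i
        atoms += [
            _atom("N", i + 1, [x, 0.0, 0.0], rn, bfactor=bfactor),
            _atom("CA", i + 1, [x + 1.2, 0.9, 0.0], rn, bfactor=bfactor),
            _atom("C", i + 1, [x + 2.4, 0.0, 0.0], rn, bfactor=bfactor),
            _atom("O", i + 1, [x + 2.4, -1.23, 0.0], rn, bfactor=bfactor),
        ]
    return atoms


class TestStructureRoundTrip:
    def test_multi_model_roundtrip(self, tmp_path):
        models = [_tripeptide(), _tripeptide()]
        for a in models[1]:
            a.coords = a.coords + 0.251
        ens = StructureEnsemble(models, source_id="fix")
        path = tmp_path / "fix.pdb"
        structio.write_structure(ens, path)
        back = structio.read_structure(path)
        assert back.n_models == 2
        assert back.seq() == ens.seq()
        for m_in, m_out in zip(ens.models, back.models):
            for a, b in zip(m_in, m_out):
                assert a.name == b.name and a.res_seq == b.res_seq
                np.testing.assert_allclose(a.coords, b.coords, atol=5e-4)
                assert abs(a.bfactor - b.bfactor) < 5e-3

    def test_plddt_passthrough(self, tmp_path):
        ens = StructureEnsemble([_tripeptide(bfactor=70.0)])
        path = tmp_path / "pred.pdb"
        structio.write_structure(ens, path)
        back = structio.read_structure(path)
        assert all(a.bfactor == pytest.approx(70.0, abs=1e-2)
                   for m in back.models for a in m)

    def test_hetatm_water_flagged(self, tmp_path):
        atoms = _tripeptide()
        atoms.append(_atom("O", 99, [20.0, 20.0, 20.0], "HOH", hetero=True))
        path = tmp_path / "wat.pdb"
        structio.write_structure(StructureEnsemble([atoms]), path)
        back = structio.read_structure(path)
        het = [a for a in back.models[0] if a.hetero]
        assert len(het) == 1 and het[0].res_name == "HOH"
        from flexscore.rigidity import build_network
        net = build_network(back.models[0])
        assert not any(k[1] == 99 for k in net.bodies)

    def test_mmcif_roundtrip(self, tmp_path):
        ens = StructureEnsemble([_tripeptide()])
        path = tmp_path / "fix.cif"
        structio.write_structure(ens, path, format="mmcif")
        back = structio.read_structure(path, format="mmcif")
        assert back.seq() == ens.seq()

    def test_insertion_code_rejected(self, tmp_path):
        pdb = (
            "ATOM      1  N   ALA A   1      0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1A     1.458   0.000   0.000  1.00  0.00           C\n"
            "END\n")
        path = tmp_path / "icode.pdb"
        path.write_text(pdb)
        with pytest.raises(ValueError, match="insertion code"):
            structio.read_structure(path)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            structio.read_structure("/nonexistent/file.pdb")


class TestExtractRegion:
    def _ens50(self):
        atoms = []
        for i in range(1, 51):
            atoms.append(_atom("CA", i, [1.2 + 3.8 * i, 0.9, 0.0]))
        return StructureEnsemble([atoms])

    def test_simple_interval(self):
        sub = structio.extract_region(self._ens50(), [(10, 20)])
        assert sub.residue_numbers() == list(range(10, 21))

    def test_study_style_segments(self):
        """Two overlapping segments extracted as separate calls, as in
        multi-entry averaging (48- and 35-residue regions)."""
        atoms = [_atom("CA", i, [3.8 * i, 0.0, 0.0]) for i in range(600, 701)]
        ens = StructureEnsemble([atoms])
        r1 = structio.extract_region(ens, [(623, 670)])
        r2 = structio.extract_region(ens, [(623, 657)])
        assert len(r1.residue_numbers()) == 48
        assert len(r2.residue_numbers()) == 35

    def test_identity_and_idempotence(self):
        ens = self._ens50()
        full = structio.extract_region(ens, [(1, 50)])
        assert full.residue_numbers() == ens.residue_numbers()
        twice = structio.extract_region(
            structio.extract_region(ens, [(5, 15)]), [(5, 15)])
        once = structio.extract_region(ens, [(5, 15)])
        assert twice.residue_numbers() == once.residue_numbers()
        for a, b in zip(twice.models[0], once.models[0]):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match=r"\[60, 70\]"):
            structio.extract_region(self._ens50(), [(60, 70)])


class TestAmideHydrogens:
    def _poly_ala(self, n=5, pro_at=None):
        from flexscore.synthdata import SyntheticSpec, build_structure
        seq = "".join("P" if pro_at == i else "A" for i in range(n))
        spec = SyntheticSpec(ss_string="H" * n, sequence=seq, seed=0)
        model = build_structure(spec).models[0]
        # strip caps and hydrogens: bare chain
        return [a for a in model
                if a.res_name not in ("ACE", "NME") and a.name != "H"]

    def test_poly_ala_gets_n_minus_1_protons(self):
        out = structio.place_backbone_amide_hydrogens(self._poly_ala(5))
        hs = [a for a in out if a.name == "H"]
        assert len(hs) == 4  # N-terminus has none
        assert sorted(a.res_seq for a in hs) == [2, 3, 4, 5]

    def test_proline_skipped(self):
        out = structio.place_backbone_amide_hydrogens(self._poly_ala(3, pro_at=1))
        assert sorted(a.res_seq for a in out if a.name == "H") == [3]

    def test_already_protonated_unchanged(self):
        once = structio.place_backbone_amide_hydrogens(self._poly_ala(5))
        twice = structio.place_backbone_amide_hydrogens(once)
        assert len(twice) == len(once)
        for a, b in zip(once, twice):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_geometry_and_immutability(self):
        bare = self._poly_ala(6)
        before = {(a.res_seq, a.name): a.coords.copy() for a in bare}
        out = structio.place_backbone_amide_hydrogens(bare)
        for a in out:
            if (a.res_seq, a.name) in before:
                np.testing.assert_array_equal(a.coords, before[(a.res_seq, a.name)])
        ns = {a.res_seq: a.coords for a in out if a.name == "N"}
        for h in (a for a in out if a.name == "H"):
            assert np.linalg.norm(h.coords - ns[h.res_seq]) == pytest.approx(
                1.01, abs=1e-6)


class TestShiftsIO:
    def _shift_set(self):
        entries = {}
        seq = {}
        for i in range(1, 6):
            seq[i] = "ALA"
            for nuc, val in (("N", 120.0), ("CA", 52.0), ("CB", 19.0), ("C", 177.0)):
                entries[(i, nuc)] = val + 0.1 * i
        return ChemicalShiftSet(entries, seq)

    def test_roundtrip_and_count(self, tmp_path):
        ss = self._shift_set()
        path = tmp_path / "s.str"
        structio.write_shifts(ss, path)
        back = structio.read_shifts(path)
        assert len(back) == 20
        assert back.entries == pytest.approx(ss.entries)
        assert back.seq == ss.seq

    def test_non_backbone_nuclei_ignored(self, tmp_path):
        path = tmp_path / "hb.str"
        structio.write_shifts(self._shift_set(), path)
        text = path.read_text().replace("   stop_",
                                        "      99    1     ALA  HB   1.390\n   stop_")
        path.write_text(text)
        assert len(structio.read_shifts(path)) == 20

    def test_conflicting_duplicate_raises(self, tmp_path):
        path = tmp_path / "dup.str"
        structio.write_shifts(self._shift_set(), path)
        text = path.read_text().replace("   stop_",
                                        "      99    1     ALA  CA   99.000\n   stop_")
        path.write_text(text)
        with pytest.raises(ValueError, match="residue 1 atom CA"):
            structio.read_shifts(path)

    def test_no_loop_raises(self, tmp_path):
        path = tmp_path / "empty.str"
        path.write_text("data_nothing\n")
        with pytest.raises(ValueError, match="no _Atom_chem_shift loop"):
            structio.read_shifts(path)


class TestSegmentMappings:
    def test_roundtrip(self, tmp_path):
        segs = [
            SegmentMapping("O00206", "5NAM", "A", (23, 70), (623, 670)),
            SegmentMapping("O00206", "5NAO", "A", (23, 57), (623, 657)),
        ]
        path = tmp_path / "map.tsv"
        structio.write_segment_mappings(segs, path)
        back = structio.read_segment_mappings(path)
        assert back == segs
        assert back[0].offset == 600
        assert len(back[0]) == 48 and len(back[1]) == 35

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            SegmentMapping("X", "1ABC", "A", (1, 10), (101, 111))
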