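"""Structure model: parsing, writing, partitioning, geometry."""

import numpy as np
import pytest

from parchscape.errors import GeometryError, InputError, ParseError, PartitionError
from parchscape.parch_core import PVTable
from parchscape.structure_model import (
    AMINO_ACIDS,
    BACKBONE_ATOMS,
    DNA_ALIASES,
    ION_NAMES,
    NUCLEOBASE_ATOMS,
    WATER_NAMES,
    Atom,
    Moiety,
    Residue,
    ResidueKind,
    center_of_geometry,
    parse_pdb,
    partition_dna_atoms,
    read_parch_pdb,
    residue_kind,
    write_parch_pdb,
    write_pdb,
)


def _pdb_line(record, serial, name, res_name, chain, seq, x, y, z,
              alt_loc=" ", occupancy=1.0, element=None):
    element = element or name[0]
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{alt_loc}{res_name:>3s} {chain}"
        f"{seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


class TestParse:
    def test_water_hetatm(self):
        text = _pdb_line("HETATM", 1, "O", "HOH", "W", 1, 1.0, 2.0, 3.0)
        s = parse_pdb(text)
        assert len(s) == 1
        assert s.residues[0].kind is ResidueKind.WATER

    def test_dc_is_dna(self):
        lines = [
            _pdb_line("ATOM", 1, "P", "DC", "I", 1, 0, 0, 0),
            _pdb_line("ATOM", 2, "C1'", "DC", "I", 1, 1, 0, 0),
        ]
        s = parse_pdb("\n".join(lines))
        assert s.residues[0].kind is ResidueKind.DNA
        assert len(s.residues[0].atoms) == 2

    def test_empty_input_errors(self):
        with pytest.raises(ParseError):
            parse_pdb("")
        with pytest.raises(ParseError):
            parse_pdb("REMARK nothing here\nEND\n")

    def test_malformed_coordinates_report_line_number(self):
        bad = _pdb_line("ATOM", 1, "CA", "ALA", "A", 1, 0, 0, 0).replace(
            "   0.000", "  xx.yyy", 1
        )
        with pytest.raises(ParseError, match="line 1"):
            parse_pdb(bad)

    def test_altloc_keeps_highest_occupancy_then_alpha_order(self):
        lines = [
            _pdb_line("ATOM", 1, "CA", "ALA", "A", 1, 0, 0, 0, alt_loc="A",
                      occupancy=0.4),
            _pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 9, 9, 9, alt_loc="B",
                      occupancy=0.6),
        ]
        s = parse_pdb("\n".join(lines))
        assert np.allclose(s.residues[0].atoms[0].coords, [9, 9, 9])
        # tie: alt-loc 'A' wins
        lines = [
            _pdb_line("ATOM", 1, "CA", "ALA", "A", 1, 0, 0, 0, alt_loc="B",
                      occupancy=0.5),
            _pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 9, 9, 9, alt_loc="A",
                      occupancy=0.5),
        ]
        s = parse_pdb("\n".join(lines))
        assert np.allclose(s.residues[0].atoms[0].coords, [9, 9, 9])

    def test_multi_model_keeps_first_with_warning(self):
        text = "\n".join([
            "MODEL        1",
            _pdb_line("ATOM", 1, "CA", "ALA", "A", 1, 0, 0, 0),
            "ENDMDL",
            "MODEL        2",
            _pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 5, 5, 5),
            "ENDMDL",
        ])
        with pytest.warns(UserWarning, match="model 1 of 2"):
            s = parse_pdb(text)
        assert np.allclose(s.residues[0].atoms[0].coords, [0, 0, 0])


class TestResidueKindTable:
    def test_kind_is_pure_function_of_name(self):
        for name in AMINO_ACIDS:
            assert residue_kind(name) is ResidueKind.PROTEIN
        for name in DNA_ALIASES:
            assert residue_kind(name) is ResidueKind.DNA
        for name in WATER_NAMES:
            assert residue_kind(name) is ResidueKind.WATER
        for name in ION_NAMES:
            assert residue_kind(name) is ResidueKind.ION
        assert residue_kind("XYZ") is ResidueKind.OTHER


class TestRoundTrip:
    def test_parse_write_round_trip(self, small_nucleosome):
        text = write_pdb(small_nucleosome)
        back = parse_pdb(text)
        assert len(back) == len(small_nucleosome)
        for a, b in zip(small_nucleosome.residues, back.residues):
            assert a.key == b.key
            assert a.name == b.name
            assert a.kind == b.kind
            assert len(a.atoms) == len(b.atoms)
            assert np.allclose(a.coord_array(heavy_only=False),
                               b.coord_array(heavy_only=False), atol=1e-3)


class TestPartition:
    def _dc(self, names):
        atoms = [Atom(name=n, element="C" if "C" in n else n[0],
                      coords=np.random.default_rng(1).uniform(0, 5, 3))
                 for n in names]
        return Residue(chain_id="I", seq_id=1, name="DC", atoms=atoms)

    FULL_DC = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
               "C2'", "C1'", "N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"]

    def test_full_dc_template(self):
        bb, nb = partition_dna_atoms(self._dc(self.FULL_DC))
        assert bb == {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'",
                      "O3'", "C2'", "C1'"}
        assert nb == {"N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"}

    def test_five_prime_terminus_skips_missing_phosphate(self):
        names = [n for n in self.FULL_DC if n not in ("P", "OP1", "OP2")]
        bb, nb = partition_dna_atoms(self._dc(names))
        assert bb == {"O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"}

    def test_methylcytosine_methyl_in_nb(self):
        atoms = [Atom(name=n, element="C", coords=[i, 0, 0])
                 for i, n in enumerate(self.FULL_DC + ["C5M"])]
        res = Residue(chain_id="I", seq_id=1, name="5CM", atoms=atoms)
        bb, nb = partition_dna_atoms(res)
        assert "C5M" in nb and "C5M" not in bb

    def test_partition_covers_and_disjoint_for_all_templates(self):
        for base, nb_template in NUCLEOBASE_ATOMS.items():
            assert not (BACKBONE_ATOMS & nb_template)

    def test_unknown_atom_name_errors_with_atom(self):
        res = self._dc(["P", "QQ1"])
        with pytest.raises(PartitionError, match="QQ1"):
            partition_dna_atoms(res)

    def test_non_dna_residue_rejected(self):
        res = Residue(chain_id="A", seq_id=1, name="ALA",
                      atoms=[Atom(name="CA", element="C", coords=[0, 0, 0])])
        with pytest.raises(PartitionError):
            partition_dna_atoms(res)

    def test_toy_dna_partitions_exactly_once(self, small_nucleosome):
        for res in small_nucleosome.dna_residues():
            bb, nb = partition_dna_atoms(res)
            heavy = {a.name for a in res.heavy_atoms()}
            assert bb | nb == heavy
            assert not (bb & nb)


class TestCenterOfGeometry:
    def test_single_and_pair(self):
        a = Atom(name="X", element="C", coords=[1, 2, 3])
        assert np.allclose(center_of_geometry([a]), [1, 2, 3])
        b = Atom(name="Y", element="C", coords=[2, 0, 0])
        c = Atom(name="Z", element="C", coords=[0, 0, 0])
        assert np.allclose(center_of_geometry([b, c]), [1, 0, 0])

    def test_matches_mean_oracle(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-10, 10, (10, 3))
        atoms = [Atom(name=f"A{i}", element="C", coords=c)
                 for i, c in enumerate(coords)]
        assert np.allclose(center_of_geometry(atoms), coords.mean(axis=0))

    def test_empty_set_errors(self):
        with pytest.raises(GeometryError):
            center_of_geometry([])


class TestParchPdbDialect:
    def test_protein_only_all_zero(self):
        from parchscape.structure_model import Structure

        res = Residue(chain_id="A", seq_id=1, name="ALA",
                      atoms=[Atom(name="CA", element="C", coords=[0, 0, 0])])
        s = Structure(residues=[res])
        pv = PVTable()
        pv.set(res.key, Moiety.PROT, 0.0, res_name="ALA")
        text = write_parch_pdb(s, pv)
        atom_lines = [l for l in text.splitlines() if l.startswith("ATOM")]
        assert all(l.endswith("0.00") for l in atom_lines)

    def test_dna_bb_nb_values_on_matching_atoms(self):
        from parchscape.structure_model import Structure

        names = TestPartition.FULL_DC
        atoms = [Atom(name=n, element="C", coords=[i * 2.0, 0, 0])
                 for i, n in enumerate(names)]
        res = Residue(chain_id="I", seq_id=1, name="DC", atoms=atoms)
        s = Structure(residues=[res])
        pv = PVTable()
        pv.set(res.key, Moiety.BB, 5.0, res_name="DC")
        pv.set(res.key, Moiety.NB, 0.4, res_name="DC")
        text = write_parch_pdb(s, pv)
        for line in text.splitlines():
            if not line.startswith("ATOM"):
                continue
            name = line[12:16].strip()
            expected = "5.00" if name in BACKBONE_ATOMS else "0.40"
            assert line.endswith(expected), (name, line)

    def test_annotated_round_trip_recovers_table(self, small_nucleosome):
        rng = np.random.default_rng(3)
        from parchscape.parch_core import structure_groups, parse_group_id

        pv = PVTable()
        for gid in structure_groups(small_nucleosome):
            key, moiety = parse_group_id(gid)
            pv.set(key, moiety, round(float(rng.uniform(0, 9)), 2))
        text = write_parch_pdb(small_nucleosome, pv)
        _, back = read_parch_pdb(text)
        assert len(back) == len(pv)
        for key, moiety in pv.keys():
            assert back.get(key, moiety) == pytest.approx(
                pv.get(key, moiety), abs=0.005
            )

    def test_missing_pv_lists_residues(self):
        from parchscape.structure_model import Structure

        res = Residue(chain_id="A", seq_id=7, name="ALA",
                      atoms=[Atom(name="CA", element="C", coords=[0, 0, 0])])
        s = Structure(residues=[res])
        with pytest.raises(InputError, match="7"):
            write_parch_pdb(s, PVTable())
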