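"""Spatial classifiers against brute-force distance oracles."""

import numpy as np
import pytest

from parchscape.classifiers import (
    ACIDIC_PATCH_SPECS,
    ResidueSpec,
    classify_contacts,
    classify_inner_outer,
    classify_proximal_distal,
    contact_residues,
    select_acidic_patch,
    select_residue_set,
)
from parchscape.errors import ConfigError, InputError
from parchscape.structure_model import Atom, Residue, ResidueKind, Structure
from parchscape.synthetic_data import DEFAULT_CHAIN_MAP, build_toy_nucleosome

from conftest import random_structure


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation)
# ---------------------------------------------------------------------------


def brute_min_dist(coords_a, coords_b):
    return min(
        float(np.linalg.norm(a - b)) for a in coords_a for b in coords_b
    )


def brute_proximal(structure, cutoff):
    protein = [a.coords for r in structure.protein_residues()
               for a in r.heavy_atoms()]
    labels = {}
    for res in structure.dna_residues():
        d = brute_min_dist([a.coords for a in res.heavy_atoms()], protein)
        labels[res.key] = "PROXIMAL" if d <= cutoff else "DISTAL"
    return labels


def brute_contacts(structure, cutoff):
    dna_cogs = [np.mean([a.coords for a in r.heavy_atoms()], axis=0)
                for r in structure.dna_residues()]
    out = set()
    for res in structure.protein_residues():
        cog = np.mean([a.coords for a in res.heavy_atoms()], axis=0)
        if min(np.linalg.norm(cog - c) for c in dna_cogs) <= cutoff:
            out.add(res.key)
    return out


def brute_inner_outer(structure, cutoff):
    per_unit = {0: [], 1: []}
    for res in structure.residues:
        if res.kind in (ResidueKind.WATER, ResidueKind.ION):
            continue
        per_unit[structure.unit_labels[res.key]].append(res)
    coords = {
        u: [a.coords for r in per_unit[u] for a in r.heavy_atoms()]
        for u in per_unit
    }
    labels = {}
    for u in (0, 1):
        for res in per_unit[u]:
            d = brute_min_dist([a.coords for a in res.heavy_atoms()],
                               coords[1 - u])
            labels[res.key] = "INNER" if d <= cutoff else "OUTER"
    return labels


# ---------------------------------------------------------------------------
# Proximal / distal
# ---------------------------------------------------------------------------


class TestProximalDistal:
    def _two_residue_structure(self, gap):
        prot = Residue(chain_id="A", seq_id=1, name="ALA",
                       atoms=[Atom(name="CA", element="C", coords=[0, 0, 0])])
        dna = Residue(chain_id="I", seq_id=1, name="DC",
                      atoms=[Atom(name="P", element="P", coords=[gap, 0, 0])])
        return Structure(residues=[prot, dna])

    def test_within_cutoff_is_proximal(self):
        s = self._two_residue_structure(2.5)
        res = classify_proximal_distal(s, 3.0)
        assert res.labels[("I", 1, "")] == "PROXIMAL"

    def test_beyond_cutoff_is_distal(self):
        s = self._two_residue_structure(3.5)
        res = classify_proximal_distal(s, 3.0)
        assert res.labels[("I", 1, "")] == "DISTAL"

    def test_boundary_counts_as_within(self):
        s = self._two_residue_structure(3.0)
        assert classify_proximal_distal(s, 3.0).labels[("I", 1, "")] == "PROXIMAL"

    def test_matches_brute_force_on_random_structures(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            s = random_structure(rng)
            cutoff = float(rng.uniform(2, 12))
            assert classify_proximal_distal(s, cutoff).labels == \
                brute_proximal(s, cutoff)

    def test_toy_nucleosome_matches_oracle_and_both_classes(self, small_nucleosome):
        got = classify_proximal_distal(small_nucleosome, 3.0).labels
        assert got == brute_proximal(small_nucleosome, 3.0)
        assert {"PROXIMAL", "DISTAL"} == set(got.values())

    def test_no_protein_errors(self):
        dna = Residue(chain_id="I", seq_id=1, name="DC",
                      atoms=[Atom(name="P", element="P", coords=[0, 0, 0])])
        with pytest.raises(InputError):
            classify_proximal_distal(Structure(residues=[dna]))

    def test_labels_partition_queried_set(self, small_nucleosome):
        res = classify_proximal_distal(small_nucleosome)
        assert set(res.labels) == {r.key for r in small_nucleosome.dna_residues()}

    def test_monotone_in_cutoff(self, small_nucleosome):
        sets = [
            classify_proximal_distal(small_nucleosome, c).keys_with("PROXIMAL")
            for c in (2.0, 3.0, 5.0, 10.0)
        ]
        for a, b in zip(sets, sets[1:]):
            assert a <= b


# ---------------------------------------------------------------------------
# Contacts (COG criterion)
# ---------------------------------------------------------------------------


class TestContacts:
    def test_matches_brute_force_on_random_structures(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            s = random_structure(rng)
            cutoff = float(rng.uniform(3, 15))
            assert contact_residues(s, cutoff) == brute_contacts(s, cutoff)

    def test_far_apart_gives_empty_set(self):
        rng = np.random.default_rng(3)
        s = random_structure(rng, box=5.0)
        for res in s.dna_residues():
            for a in res.atoms:
                a.coords = a.coords + np.array([500.0, 0, 0])
        assert contact_residues(s, 8.0) == set()

    def test_toy_nucleosome_matches_oracle(self, small_nucleosome):
        assert contact_residues(small_nucleosome, 8.0) == \
            brute_contacts(small_nucleosome, 8.0)

    def test_monotone_in_cutoff(self, small_nucleosome):
        sets = [contact_residues(small_nucleosome, c) for c in (4.0, 8.0, 16.0)]
        for a, b in zip(sets, sets[1:]):
            assert a <= b


# ---------------------------------------------------------------------------
# Inner / outer
# ---------------------------------------------------------------------------


class TestInnerOuter:
    def test_matches_brute_force_on_random_two_unit_structures(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            s = random_structure(rng, two_units=True, box=40.0)
            cutoff = float(rng.uniform(5, 30))
            assert classify_inner_outer(s, cutoff).labels == \
                brute_inner_outer(s, cutoff)

    def test_symmetric_under_unit_swap(self):
        rng = np.random.default_rng(24)
        s = random_structure(rng, two_units=True, box=40.0)
        before = classify_inner_outer(s, 15.0).labels
        s.unit_labels = {k: 1 - v for k, v in s.unit_labels.items()}
        assert classify_inner_outer(s, 15.0).labels == before

    def test_requires_exactly_two_units(self):
        rng = np.random.default_rng(25)
        s = random_structure(rng, two_units=True)
        s.unit_labels = {k: 0 for k in s.unit_labels}
        with pytest.raises(InputError, match="2 nucleosome units"):
            classify_inner_outer(s)

    def test_boundary_inclusive(self):
        a = Residue(chain_id="A", seq_id=1, name="ALA",
                    atoms=[Atom(name="CA", element="C", coords=[0, 0, 0])])
        b = Residue(chain_id="B", seq_id=1, name="ALA",
                    atoms=[Atom(name="CA", element="C", coords=[19.0, 0, 0])])
        s = Structure(residues=[a, b],
                      unit_labels={a.key: 0, b.key: 1})
        assert classify_inner_outer(s, 20.0).labels[a.key] == "INNER"
        b.atoms[0].coords = np.array([30.0, 0, 0])
        assert classify_inner_outer(s, 20.0).labels[a.key] == "OUTER"


# ---------------------------------------------------------------------------
# Named residue sets
# ---------------------------------------------------------------------------


class TestResidueSets:
    def test_acidic_patch_has_16_residues_on_toy_octamer(self, small_nucleosome):
        sel = select_acidic_patch(small_nucleosome, DEFAULT_CHAIN_MAP)
        assert len(sel.found) == 16  # 6 H2A + 2 H2B specs x 2 copies each
        assert not sel.missing
        assert not sel.mismatched

    def test_missing_residue_reported_with_warning(self, small_nucleosome):
        pruned = [r for r in small_nucleosome.residues
                  if not (r.chain_id == "D" and r.seq_id == 110)]
        s = Structure(residues=pruned)
        with pytest.warns(UserWarning, match="E110"):
            sel = select_acidic_patch(s, DEFAULT_CHAIN_MAP)
        assert len(sel.found) == 15
        assert len(sel.missing) == 1

    def test_type_mismatch_flagged_not_dropped(self, small_nucleosome):
        residues = []
        for r in small_nucleosome.residues:
            if r.chain_id == "C" and r.seq_id == 91:
                r = Residue(chain_id=r.chain_id, seq_id=r.seq_id, icode=r.icode,
                            name="LYS", atoms=r.atoms)
            residues.append(r)
        s = Structure(residues=residues)
        sel = select_acidic_patch(s, DEFAULT_CHAIN_MAP)
        assert len(sel.found) == 16
        flagged = [f for f in sel.mismatched]
        assert len(flagged) == 1
        assert flagged[0].key == ("C", 91, "")

    def test_generic_selector_two_copies(self, small_nucleosome):
        sel = select_residue_set(
            small_nucleosome, [ResidueSpec("H3", "R", 83)], DEFAULT_CHAIN_MAP
        )
        assert len(sel.found) == 2
        assert {f.key[0] for f in sel.found} == set(DEFAULT_CHAIN_MAP["H3"])

    def test_unresolvable_chain_map_errors(self, small_nucleosome):
        with pytest.raises(ConfigError):
            select_acidic_patch(small_nucleosome, {"H2A": ("C", "G")})

    def test_empty_spec_list_rejected(self, small_nucleosome):
        with pytest.raises(ConfigError):
            select_residue_set(small_nucleosome, [], DEFAULT_CHAIN_MAP)

    def test_spec_on_absent_structure_warns(self, small_nucleosome):
        with pytest.warns(UserWarning):
            sel = select_residue_set(
                small_nucleosome, [ResidueSpec("H4", "R", 999)], DEFAULT_CHAIN_MAP
            )
        assert not sel.found
        assert len(sel.missing) == 2
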