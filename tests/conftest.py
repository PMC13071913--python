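"""Shared fixtures: small toy systems and random-structure generators."""

from __future__ import annotations

import numpy as np
import pytest

from parchscape.structure_model import Atom, Residue, Structure
from parchscape.synthetic_data import build_toy_dinucleosome, build_toy_nucleosome


@pytest.fixture(scope="session")
def toy_nucleosome():
    """Full-size toy nucleosome (147 bp, 8 chains)."""
    return build_toy_nucleosome()


@pytest.fixture(scope="session")
def small_nucleosome():
    """Fast 24-bp toy nucleosome for per-test work."""
    return build_toy_nucleosome(n_bp=24)


@pytest.fixture(scope="session")
def toy_dinucleosome():
    return build_toy_dinucleosome()


def random_structure(
    rng: np.random.Generator,
    n_protein: int = 12,
    n_dna: int = 12,
    atoms_per_residue: int = 3,
    box: float = 30.0,
    two_units: bool = False,
) -> Structure:
    """Random point-cloud structure for brute-force oracle comparisons."""
    residues = []
    unit_labels = {}
    protein_atoms = ("N", "CA", "C", "O", "CB")
    dna_atoms = ("P", "C1'", "N1", "C2", "O2")
    for i in range(n_protein):
        atoms = [
            Atom(name=protein_atoms[a % len(protein_atoms)], element="C",
                 coords=rng.uniform(0, box, 3))
            for a in range(atoms_per_residue)
        ]
        chain = "A" if (not two_units or i < n_protein // 2) else "a"
        res = Residue(chain_id=chain, seq_id=i + 1, name="ALA", atoms=atoms)
        residues.append(res)
        unit_labels[res.key] = 0 if chain == "A" else 1
    for i in range(n_dna):
        atoms = [
            Atom(name=dna_atoms[a % len(dna_atoms)], element="P" if a == 0 else "C",
                 coords=rng.uniform(0, box, 3))
            for a in range(atoms_per_residue)
        ]
        chain = "I" if (not two_units or i < n_dna // 2) else "i"
        res = Residue(chain_id=chain, seq_id=i + 1, name="DC", atoms=atoms)
        residues.append(res)
        unit_labels[res.key] = 0 if chain == "I" else 1
    return Structure(
        residues=residues, unit_labels=unit_labels if two_units else None
    )
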