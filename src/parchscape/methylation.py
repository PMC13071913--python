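"""In-silico cytosine methylation.

Builds the fully methylated partner of a DNA-containing structure by
adding one heavy methyl carbon (named ``C5M``) at the C5 ring position
of every cytosine and renaming the residue to the modified-nucleotide
id ``5CM``.  Placement is deterministic vector geometry, not a force
field: the new atom lies in the least-squares plane of the pyrimidine
ring, along the external bisector of the C4-C5-C6 angle, at the
aromatic C-C bond length (1.50 Å by default).  Methyl hydrogens are not
added; the package is heavy-atom only throughout.

Cytosines missing any of C4/C5/C6, or with rings bent beyond the
planarity tolerance, are skipped with a reason in the report.  If the
placed carbon lands closer than 1.8 Å to a non-bonded atom the residue
is still methylated but flagged as clashing — relaxing such contacts is
a simulation step outside this package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InputError
from .structure_model import (
    Atom,
    Residue,
    ResidueKey,
    ResidueKind,
    Structure,
    normalize_atom_name,
)

__all__ = ["MethylationReport", "methylate_all_cytosines", "place_methyl_carbon"]

#: residue names treated as unmethylated cytosine
CYTOSINE_NAMES = {"DC", "C"}
#: residue names already methylated (never re-methylated)
METHYLATED_NAMES = {"5CM", "FMC"}

RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6")
PLACED_ATOM_NAME = "C5M"
CLASH_CUTOFF_A = 1.8


@dataclass
class MethylationReport:
    n_cytosines_found: int = 0
    n_methylated: int = 0
    skipped: list[tuple[ResidueKey, str]] = field(default_factory=list)
    clashes: list[tuple[ResidueKey, float]] = field(default_factory=list)
    bond_length_A: float = 1.50
    placed_atom_name: str = PLACED_ATOM_NAME

    def to_tsv(self, path=None) -> str | None:
        rows = [
            {"chain": k[0], "seq_id": k[1], "icode": k[2], "status": "skipped",
             "detail": reason}
            for k, reason in self.skipped
        ] + [
            {"chain": k[0], "seq_id": k[1], "icode": k[2], "status": "clash",
             "detail": f"nearest non-bonded atom {d:.2f} A"}
            for k, d in self.clashes
        ]
        frame = pd.DataFrame(rows, columns=["chain", "seq_id", "icode", "status", "detail"])
        header = (
            f"# cytosines_found\t{self.n_cytosines_found}\n"
            f"# methylated\t{self.n_methylated}\n"
            f"# bond_length_A\t{self.bond_length_A}\n"
            f"# placed_atom\t{self.placed_atom_name}\n"
        )
        text = header + frame.to_csv(sep="\t", index=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane of ring atoms: (centroid, unit normal)."""
    centroid = coords.mean(axis=0)
    _, s, vt = np.linalg.svd(coords - centroid)
    normal = vt[-1]
    return centroid, normal / np.linalg.norm(normal)


def place_methyl_carbon(
    c4: np.ndarray, c5: np.ndarray, c6: np.ndarray,
    ring_coords: np.ndarray, bond_length: float = 1.50,
) -> np.ndarray:
    """Coordinates of the methyl carbon off C5.

    In the least-squares ring plane, along the external bisector of the
    C4-C5-C6 angle, ``bond_length`` from C5.
    """
    _, normal = _ring_plane(ring_coords)
    u1 = c4 - c5
    u2 = c6 - c5
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    bisector = u1 + u2
    norm = np.linalg.norm(bisector)
    if norm < 1e-6:
        raise InputError("C4-C5-C6 is degenerate (collinear); no external bisector")
    direction = -bisector / norm
    # project into the ring plane and renormalize
    direction = direction - np.dot(direction, normal) * normal
    norm = np.linalg.norm(direction)
    if norm < 1e-6:
        raise InputError("external bisector is normal to the ring plane")
    return c5 + bond_length * direction / norm


def _ring_planarity(ring_coords: np.ndarray) -> float:
    centroid, normal = _ring_plane(ring_coords)
    return float(np.abs((ring_coords - centroid) @ normal).max())


def methylate_all_cytosines(
    structure: Structure,
    bond_length: float = 1.50,
    planarity_tol: float = 0.25,
) -> tuple[Structure, MethylationReport]:
    """Methylate every cytosine at C5; return the new structure and a report.

    Pre-existing atoms are shared with the input (coordinates bit-exact);
    only cytosine residues are replaced by copies carrying the extra
    ``C5M`` atom and the ``5CM`` name.  Already-methylated residues and
    non-cytosine nucleotides are untouched, so the operation is
    idempotent.
    """
    if bond_length <= 0:
        raise InputError("bond_length must be positive")
    report = MethylationReport(bond_length_A=bond_length)

    # global heavy-atom cloud for clash detection (coordinates only)
    all_coords = []
    owners: list[tuple[ResidueKey, str]] = []
    for res in structure.residues:
        for a in res.heavy_atoms():
            all_coords.append(a.coords)
            owners.append((res.key, normalize_atom_name(a.name)))
    tree = cKDTree(np.array(all_coords)) if all_coords else None

    new_residues: list[Residue] = []
    for res in structure.residues:
        name = res.name.strip().upper()
        if res.kind is not ResidueKind.DNA or name not in CYTOSINE_NAMES:
            new_residues.append(res)
            continue
        report.n_cytosines_found += 1
        atoms = {normalize_atom_name(a.name): a for a in res.atoms}
        needed = ("C4", "C5", "C6")
        if any(n not in atoms for n in needed):
            missing = [n for n in needed if n not in atoms]
            report.skipped.append((res.key, f"missing ring atoms {missing}"))
            new_residues.append(res)
            continue
        ring = np.array([atoms[n].coords for n in RING_ATOMS if n in atoms])
        if len(ring) >= 4 and _ring_planarity(ring) > planarity_tol:
            report.skipped.append(
                (res.key, f"ring non-planar beyond {planarity_tol} A tolerance")
            )
            new_residues.append(res)
            continue
        try:
            pos = place_methyl_carbon(
                atoms["C4"].coords, atoms["C5"].coords, atoms["C6"].coords,
                ring, bond_length,
            )
        except InputError as exc:
            report.skipped.append((res.key, str(exc)))
            new_residues.append(res)
            continue

        if tree is not None:
            dists, idx = tree.query(pos, k=min(8, len(all_coords)))
            dists = np.atleast_1d(dists)
            idx = np.atleast_1d(idx)
            for d, i in zip(dists, idx):
                key, aname = owners[i]
                if key == res.key and aname in ("C4", "C5", "C6"):
                    continue  # bonded neighbor or its ring flank
                if d < CLASH_CUTOFF_A:
                    report.clashes.append((res.key, float(d)))
                break

        methyl = Atom(name=PLACED_ATOM_NAME, element="C", coords=pos)
        new_res = Residue(
            chain_id=res.chain_id, seq_id=res.seq_id, icode=res.icode,
            name="5CM", atoms=list(res.atoms) + [methyl],
        )
        new_residues.append(new_res)
        report.n_methylated += 1

    out = Structure(
        residues=new_residues,
        unit_labels=dict(structure.unit_labels) if structure.unit_labels else None,
        title=structure.title,
    )
    # serial numbers are reassigned consistently on write; untouched
    # residues still share their Atom objects with the input
    return out, report
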