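"""Spatial classification of nucleosome residues.

Three distance-based operators, all over heavy atoms, all reading
"within X Å" inclusively (a distance exactly equal to the cutoff counts
as within):

* proximal/distal DNA — a DNA residue is *proximal* when any of its
  heavy atoms lies within 3 Å of any protein heavy atom;
* DNA-contacting histone residues — a protein residue whose center of
  geometry lies within 8 Å of the center of geometry of any DNA residue;
* dinucleosome inner/outer — a residue of one nucleosome unit is
  *inner* when any of its heavy atoms lies within 20 Å of any protein
  or DNA heavy atom of the adjacent unit.

Waters and ions are never classified.  Named functional residue sets
(the H2A/H2B acidic patch; user-configured arginine anchors) are
selected by (histone type, position) through a chain map; residues whose
observed amino acid disagrees with the requested one are returned with a
mismatch flag rather than silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .errors import ConfigError, InputError
from .structure_model import (
    AMINO_ACIDS,
    Residue,
    ResidueKey,
    ResidueKind,
    Structure,
    center_of_geometry,
)

__all__ = [
    "ClassificationResult",
    "ResidueSpec",
    "SelectedResidue",
    "SelectionResult",
    "classify_proximal_distal",
    "classify_contacts",
    "contact_residues",
    "classify_inner_outer",
    "select_residue_set",
    "select_acidic_patch",
    "ACIDIC_PATCH_SPECS",
    "load_residue_specs",
    "default_arginine_anchors",
]

HISTONE_TYPES = ("H2A", "H2B", "H3", "H4")


@dataclass
class ClassificationResult:
    """Exhaustive labeling of a residue set under one distance criterion."""

    labels: dict[ResidueKey, str]
    cutoff_A: float
    criterion: str  # "ANY_ATOM" or "COG"
    distances: dict[ResidueKey, float] = field(default_factory=dict)

    def keys_with(self, label: str) -> set[ResidueKey]:
        return {k for k, v in self.labels.items() if v == label}

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "chain": k[0],
                "seq_id": k[1],
                "icode": k[2],
                "label": self.labels[k],
                "distance_A": self.distances.get(k, float("nan")),
            }
            for k in sorted(self.labels)
        ]
        return pd.DataFrame(rows, columns=["chain", "seq_id", "icode", "label", "distance_A"])


def _min_distances(residues: Sequence[Residue], target: np.ndarray) -> dict[ResidueKey, float]:
    tree = cKDTree(target)
    out: dict[ResidueKey, float] = {}
    for res in residues:
        coords = res.coord_array()
        if coords.size == 0:
            continue
        d, _ = tree.query(coords, k=1)
        out[res.key] = float(d.min())
    return out


def classify_proximal_distal(
    structure: Structure, cutoff: float = 3.0
) -> ClassificationResult:
    """Label every DNA residue PROXIMAL or DISTAL by nearest protein atom."""
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    protein = structure.heavy_coords([ResidueKind.PROTEIN])
    if protein.shape[0] == 0:
        raise InputError("structure contains no protein heavy atoms")
    dna = structure.dna_residues()
    if not dna:
        raise InputError("structure contains no DNA residues")
    dists = _min_distances(dna, protein)
    labels = {k: ("PROXIMAL" if d <= cutoff else "DISTAL") for k, d in dists.items()}
    return ClassificationResult(labels, cutoff, "ANY_ATOM", dists)


def classify_contacts(
    structure: Structure, cutoff: float = 8.0
) -> ClassificationResult:
    """Label protein residues CONTACT/NONCONTACT by COG-to-COG distance to DNA."""
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    dna = structure.dna_residues()
    protein = structure.protein_residues()
    if not dna:
        raise InputError("structure contains no DNA residues")
    if not protein:
        raise InputError("structure contains no protein residues")
    dna_cogs = np.array([center_of_geometry(r.coord_array()) for r in dna])
    tree = cKDTree(dna_cogs)
    labels: dict[ResidueKey, str] = {}
    dists: dict[ResidueKey, float] = {}
    for res in protein:
        cog = center_of_geometry(res.coord_array())
        d, _ = tree.query(cog, k=1)
        dists[res.key] = float(d)
        labels[res.key] = "CONTACT" if d <= cutoff else "NONCONTACT"
    return ClassificationResult(labels, cutoff, "COG", dists)


def contact_residues(structure: Structure, cutoff: float = 8.0) -> set[ResidueKey]:
    """Protein residues whose COG lies within ``cutoff`` of any DNA residue COG."""
    return classify_contacts(structure, cutoff).keys_with("CONTACT")


def classify_inner_outer(
    structure: Structure, cutoff: float = 20.0
) -> ClassificationResult:
    """Label non-water residues of a two-unit structure INNER or OUTER.

    INNER means any heavy atom within ``cutoff`` of any protein or DNA
    heavy atom of the *other* nucleosome unit; the criterion is
    symmetric across units.
    """
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    if not structure.unit_labels:
        raise InputError("structure carries no nucleosome unit labels")
    units = sorted(set(structure.unit_labels.values()))
    if len(units) != 2:
        raise InputError(f"expected exactly 2 nucleosome units, found {len(units)}")

    classifiable = (ResidueKind.PROTEIN, ResidueKind.DNA)
    per_unit: dict[int, list[Residue]] = {u: [] for u in units}
    for res in structure.residues:
        if res.kind in (ResidueKind.WATER, ResidueKind.ION):
            continue
        unit = structure.unit_labels.get(res.key)
        if unit is None:
            raise InputError(f"residue {res.key} has no unit label")
        per_unit[unit].append(res)

    target_coords = {
        u: np.vstack([r.coord_array() for r in per_unit[u] if r.kind in classifiable])
        for u in units
    }
    labels: dict[ResidueKey, str] = {}
    dists: dict[ResidueKey, float] = {}
    for u, other in ((units[0], units[1]), (units[1], units[0])):
        d = _min_distances(per_unit[u], target_coords[other])
        for key, val in d.items():
            dists[key] = val
            labels[key] = "INNER" if val <= cutoff else "OUTER"
    return ClassificationResult(labels, cutoff, "ANY_ATOM", dists)


# ---------------------------------------------------------------------------
# Named residue sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueSpec:
    """One residue of a histone type, e.g. ``ResidueSpec("H2A", "E", 91)``."""

    histone_type: str
    amino_acid: str  # one-letter code
    seq_id: int

    def __post_init__(self) -> None:
        if self.histone_type not in HISTONE_TYPES:
            raise ConfigError(f"unknown histone type {self.histone_type!r}")
        if self.amino_acid.upper() not in set(AMINO_ACIDS.values()):
            raise ConfigError(f"unknown amino-acid code {self.amino_acid!r}")

    def __str__(self) -> str:
        return f"{self.histone_type} {self.amino_acid}{self.seq_id}"


@dataclass(frozen=True)
class SelectedResidue:
    key: ResidueKey
    spec: ResidueSpec
    observed_name: str
    mismatch: bool


@dataclass
class SelectionResult:
    found: list[SelectedResidue]
    missing: list[tuple[str, ResidueSpec]]  # (chain id, spec)

    @property
    def keys(self) -> list[ResidueKey]:
        return [s.key for s in self.found]

    @property
    def mismatched(self) -> list[SelectedResidue]:
        return [s for s in self.found if s.mismatch]


#: the conserved H2A/H2B acidic patch
ACIDIC_PATCH_SPECS: tuple[ResidueSpec, ...] = (
    ResidueSpec("H2A", "E", 56),
    ResidueSpec("H2A", "E", 61),
    ResidueSpec("H2A", "E", 64),
    ResidueSpec("H2A", "D", 90),
    ResidueSpec("H2A", "E", 91),
    ResidueSpec("H2A", "E", 92),
    ResidueSpec("H2B", "E", 102),
    ResidueSpec("H2B", "E", 110),
)


def select_residue_set(
    structure: Structure,
    specs: Sequence[ResidueSpec],
    chain_map: Mapping[str, Sequence[str]],
) -> SelectionResult:
    """Resolve residue specs against every chain copy of each histone type.

    ``chain_map`` maps histone type to the chain ids carrying it (two
    copies each in an octamer).  Missing residues are reported in
    ``missing`` with a warning; residues present but of a different
    amino acid come back flagged, never dropped.
    """
    if not specs:
        raise ConfigError("residue spec list is empty")
    needed = {s.histone_type for s in specs}
    unresolved = needed - set(chain_map)
    if unresolved:
        raise ConfigError(f"chain_map does not resolve histone types: {sorted(unresolved)}")

    by_key = {res.key: res for res in structure.residues}
    found: list[SelectedResidue] = []
    missing: list[tuple[str, ResidueSpec]] = []
    for spec in specs:
        for chain in chain_map[spec.histone_type]:
            res = by_key.get((chain, spec.seq_id, ""))
            if res is None or res.kind is not ResidueKind.PROTEIN:
                missing.append((chain, spec))
                warnings.warn(f"residue {spec} not found on chain {chain}", stacklevel=2)
                continue
            observed = AMINO_ACIDS.get(res.name.upper(), "?")
            found.append(
                SelectedResidue(
                    key=res.key,
                    spec=spec,
                    observed_name=res.name,
                    mismatch=observed != spec.amino_acid.upper(),
                )
            )
    return SelectionResult(found=found, missing=missing)


def select_acidic_patch(
    structure: Structure, chain_map: Mapping[str, Sequence[str]]
) -> SelectionResult:
    """The acidic-patch residues on every H2A/H2B copy (16 in an octamer)."""
    for ht in ("H2A", "H2B"):
        if ht not in chain_map:
            raise ConfigError(f"chain_map must resolve {ht} chains")
    return select_residue_set(structure, ACIDIC_PATCH_SPECS, chain_map)


def load_residue_specs(path_or_buf) -> list[ResidueSpec]:
    """Load residue specs from a YAML list of {histone_type, amino_acid, seq_id}."""
    if hasattr(path_or_buf, "read"):
        raw = yaml.safe_load(path_or_buf)
    else:
        with open(path_or_buf) as fh:
            raw = yaml.safe_load(fh)
    if raw is None:
        return []
    if not isinstance(raw, list):
        raise ConfigError("residue-spec file must contain a YAML list")
    return [
        ResidueSpec(str(e["histone_type"]), str(e["amino_acid"]), int(e["seq_id"]))
        for e in raw
    ]


def default_arginine_anchors() -> list[ResidueSpec]:
    """Arginine-anchor specs shipped with the package (empty until configured).

    The anchor identities vary with the structure's numbering; edit
    ``parchscape/config/arginine_anchors.yaml`` or pass explicit specs.
    """
    ref = resources.files("parchscape").joinpath("config/arginine_anchors.yaml")
    with ref.open() as fh:
        return load_residue_specs(fh)
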