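"""Paired-system ΔPARCH differencing.

A ΔPV compares the same residue in two system states — DNA present
versus DNA removed, or methylated versus unmethylated — as
``pv_a - pv_b``.  Positive values mean the residue is more hydrophilic
in state A; negative values mean reduced hydrophilicity.  Residues are
matched by (chain, seq_id, icode, moiety); renumbered pairs can be
aligned with an explicit per-chain offset map.  For methylation pairs
the 5CM<->DC residue-name change is irrelevant because names play no
part in matching.

``strip_dna`` builds the histone-only partner of a nucleosome by
deleting DNA residues while leaving every remaining atom bit-exact;
crystallographic waters and ions are retained by default.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import InputError
from .parch_core import PVTable
from .structure_model import Moiety, ResidueKey, ResidueKind, Structure

__all__ = ["DeltaPVRecord", "DeltaResult", "strip_dna", "delta_pv"]

MORE_HYDROPHILIC = "MORE_HYDROPHILIC"
REDUCED_HYDROPHILICITY = "REDUCED_HYDROPHILICITY"
UNCHANGED = "UNCHANGED"


@dataclass(frozen=True)
class DeltaPVRecord:
    chain_id: str
    seq_id: int
    icode: str
    moiety: Moiety
    pv_a: float
    pv_b: float
    dpv: float
    polarity: str
    res_name: str = ""

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.seq_id, self.icode)


@dataclass
class DeltaResult:
    records: list[DeltaPVRecord]
    unmatched_a: list[tuple[ResidueKey, Moiety]]
    unmatched_b: list[tuple[ResidueKey, Moiety]]
    zero_tol: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain": r.chain_id,
                "seq_id": r.seq_id,
                "icode": r.icode,
                "res_name": r.res_name,
                "moiety": r.moiety.value,
                "pv_a": r.pv_a,
                "pv_b": r.pv_b,
                "dpv": r.dpv,
                "polarity": r.polarity,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=["chain", "seq_id", "icode", "res_name", "moiety",
                     "pv_a", "pv_b", "dpv", "polarity"],
        )

    def to_tsv(self, path=None) -> str | None:
        frame = self.to_frame()
        if path is None:
            buf = io.StringIO()
            frame.to_csv(buf, sep="\t", index=False, float_format="%.6g")
            return buf.getvalue()
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return None


def strip_dna(structure: Structure, keep_solvent: bool = True) -> Structure:
    """Histone-only partner: remove DNA residues, leave everything else intact.

    Atom objects are shared with the input, so coordinates are unchanged
    bit-exact.  A protein-only input is a no-op, and the operation is
    idempotent.
    """
    kept = []
    for res in structure.residues:
        if res.kind is ResidueKind.DNA:
            continue
        if not keep_solvent and res.kind in (ResidueKind.WATER, ResidueKind.ION):
            continue
        kept.append(res)
    unit_labels = None
    if structure.unit_labels is not None:
        kept_keys = {r.key for r in kept}
        unit_labels = {k: v for k, v in structure.unit_labels.items() if k in kept_keys}
    return Structure(residues=kept, unit_labels=unit_labels, title=structure.title)


def _polarity(dpv: float, zero_tol: float) -> str:
    if abs(dpv) < zero_tol:
        return UNCHANGED
    return MORE_HYDROPHILIC if dpv > 0 else REDUCED_HYDROPHILICITY


def delta_pv(
    pv_a: PVTable,
    pv_b: PVTable,
    offset_map: Mapping[str, int] | None = None,
    zero_tol: float = 0.05,
) -> DeltaResult:
    """Signed per-(residue, moiety) difference ``pv_a - pv_b``.

    ``offset_map`` maps chain id to the sequence-number offset of system
    B relative to system A (B seq_id = A seq_id + offset).  Records come
    back in deterministic (chain, seq, icode, moiety) order; entries
    present in only one table are reported as unmatched, not differenced.
    The polarity deadband ``zero_tol`` keeps float noise from being
    labeled as a real shift.
    """
    if zero_tol < 0:
        raise InputError("zero_tol must be non-negative")
    offset_map = dict(offset_map or {})

    def b_key(key: ResidueKey) -> ResidueKey:
        return (key[0], key[1] + offset_map.get(key[0], 0), key[2])

    a_items = {(key, m) for (key, m) in pv_a.keys()}
    b_items = {(key, m) for (key, m) in pv_b.keys()}

    records: list[DeltaPVRecord] = []
    matched_b: set[tuple[ResidueKey, Moiety]] = set()
    unmatched_a: list[tuple[ResidueKey, Moiety]] = []
    for key, moiety in sorted(a_items, key=lambda km: (km[0], km[1].value)):
        bk = (b_key(key), moiety)
        vb = pv_b.get(*bk)
        if vb is None:
            unmatched_a.append((key, moiety))
            continue
        matched_b.add(bk)
        va = pv_a.get(key, moiety)
        dpv = va - vb
        records.append(
            DeltaPVRecord(
                chain_id=key[0], seq_id=key[1], icode=key[2], moiety=moiety,
                pv_a=va, pv_b=vb, dpv=dpv, polarity=_polarity(dpv, zero_tol),
                res_name=pv_a._res_names.get(key, ""),
            )
        )
    unmatched_b = sorted(b_items - matched_b, key=lambda km: (km[0], km[1].value))
    return DeltaResult(records, unmatched_a, list(unmatched_b), zero_tol)
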