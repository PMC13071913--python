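"""PARCH hydropathy scoring.

The PARCH scale ranks residues by how long they retain their hydration
shell while the system is heated on a linear ramp: hydrophilic groups
hold water to high temperature, hydrophobic ones dewet early.  This
module consumes a hydration signal — either explicit water-oxygen
frames or precomputed per-group count series — and reduces it to one
PARCH value (PV) per scoring group: one ``PROT`` value per protein
residue and separate ``BB``/``NB`` values per DNA residue.

The PV implemented here is the time-averaged shell water count over the
final window of the annealing trajectory (``scale * mean`` of the last
``window_fraction`` of frames).  This reproduces the mechanism and the
magnitudes of the scale (backbone values of a few waters, nucleobase
values well below one); an alternative published normalization can be
swapped in behind :func:`compute_pv` without touching callers.

Running actual annealing molecular dynamics is out of scope; the
trajectories come from external simulation output or from
:mod:`parchscape.synthetic_data`.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, GeometryError, InputError
from .structure_model import (
    Moiety,
    Residue,
    ResidueKey,
    ResidueKind,
    Structure,
    moiety_atoms,
)

__all__ = [
    "AnnealingSchedule",
    "make_schedule",
    "ParchConfig",
    "PVRecord",
    "PVTable",
    "HydrationTrajectory",
    "group_id",
    "parse_group_id",
    "structure_groups",
    "count_shell_waters",
    "compute_pv",
    "run_parch",
    "read_counts_tsv",
    "write_counts_tsv",
]


# ---------------------------------------------------------------------------
# Annealing schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnealingSchedule:
    """Linear temperature ramp; the defaults heat 300 K -> 800 K at 0.1 K/ps.

    ``restraint_k`` (kJ mol^-1 nm^-2) is metadata recording the position
    restraint that keeps the solute rigid while the solvent dewets.
    """

    t_start: float = 300.0
    t_end: float = 800.0
    rate: float = 0.1
    restraint_k: float = 10000.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ConfigError(f"heating rate must be positive, got {self.rate}")
        if self.t_end < self.t_start:
            raise ConfigError(
                f"t_end ({self.t_end} K) must be >= t_start ({self.t_start} K)"
            )

    @property
    def duration_ps(self) -> float:
        return (self.t_end - self.t_start) / self.rate

    def temperature_at(self, t_ps: float) -> float:
        if not 0 <= t_ps <= self.duration_ps:
            raise ConfigError(
                f"time {t_ps} ps outside the ramp [0, {self.duration_ps}] ps"
            )
        return self.t_start + self.rate * t_ps


def make_schedule(
    t_start: float = 300.0, t_end: float = 800.0, rate: float = 0.1
) -> AnnealingSchedule:
    return AnnealingSchedule(t_start=t_start, t_end=t_end, rate=rate)


@dataclass(frozen=True)
class ParchConfig:
    """Knobs of the scoring step.

    r_shell
        hydration-shell radius around heavy atoms, Å (first-shell scale).
    window_fraction
        fraction of trailing frames averaged into the PV.
    scale
        multiplicative constant applied to the window mean.
    """

    r_shell: float = 4.0
    window_fraction: float = 0.1
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.r_shell <= 0:
            raise ConfigError("r_shell must be positive")
        if not 0 < self.window_fraction <= 1:
            raise ConfigError("window_fraction must be in (0, 1]")
        if self.scale <= 0:
            raise ConfigError("scale must be positive")


# ---------------------------------------------------------------------------
# PV table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PVRecord:
    chain_id: str
    seq_id: int
    icode: str
    moiety: Moiety
    pv: float
    res_name: str = ""

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.seq_id, self.icode)


class PVTable:
    """Per-(residue, moiety) PARCH values; values are non-negative."""

    def __init__(self) -> None:
        self._values: dict[tuple[ResidueKey, Moiety], float] = {}
        self._res_names: dict[ResidueKey, str] = {}

    def set(self, key: ResidueKey, moiety: Moiety, pv: float, res_name: str = "") -> None:
        if pv < 0:
            raise InputError(f"PV must be non-negative, got {pv} for {key} {moiety}")
        self._values[(key, Moiety(moiety))] = float(pv)
        if res_name:
            self._res_names[key] = res_name

    def get(self, key: ResidueKey, moiety: Moiety) -> float | None:
        return self._values.get((key, Moiety(moiety)))

    def __len__(self) -> int:
        return len(self._values)

    def __contains__(self, item: tuple[ResidueKey, Moiety]) -> bool:
        return item in self._values

    def keys(self):
        return self._values.keys()

    def records(self) -> list[PVRecord]:
        out = []
        for (key, moiety), pv in sorted(
            self._values.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        ):
            out.append(
                PVRecord(key[0], key[1], key[2], moiety, pv,
                         res_name=self._res_names.get(key, ""))
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain": r.chain_id,
                "seq_id": r.seq_id,
                "icode": r.icode,
                "res_name": r.res_name,
                "moiety": r.moiety.value,
                "pv": r.pv,
            }
            for r in self.records()
        ]
        return pd.DataFrame(
            rows, columns=["chain", "seq_id", "icode", "res_name", "moiety", "pv"]
        )

    def to_tsv(self, path=None) -> str | None:
        frame = self.to_frame()
        if path is None:
            buf = io.StringIO()
            frame.to_csv(buf, sep="\t", index=False, float_format="%.6g")
            return buf.getvalue()
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PVTable":
        table = cls()
        for row in frame.itertuples(index=False):
            icode = "" if pd.isna(row.icode) else str(row.icode)
            res_name = "" if pd.isna(row.res_name) else str(row.res_name)
            table.set(
                (str(row.chain), int(row.seq_id), icode),
                Moiety(row.moiety),
                float(row.pv),
                res_name=res_name,
            )
        return table

    @classmethod
    def from_tsv(cls, path_or_buf) -> "PVTable":
        frame = pd.read_csv(path_or_buf, sep="\t", comment="#",
                            keep_default_na=False, na_values=[])
        return cls.from_frame(frame)

    def values_for(self, moiety: Moiety, keys: Iterable[ResidueKey] | None = None
                   ) -> np.ndarray:
        """All PVs of one moiety, optionally restricted to a residue-key set."""
        keyset = set(keys) if keys is not None else None
        vals = [
            pv for (key, m), pv in sorted(self._values.items(),
                                          key=lambda kv: (kv[0][0], kv[0][1].value))
            if m is Moiety(moiety) and (keyset is None or key in keyset)
        ]
        return np.array(vals)


# ---------------------------------------------------------------------------
# Hydration trajectory
# ---------------------------------------------------------------------------


def group_id(key: ResidueKey, moiety: Moiety) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{Moiety(moiety).value}"


def parse_group_id(gid: str) -> tuple[ResidueKey, Moiety]:
    chain, seq, icode, moiety = gid.split(":")
    return (chain, int(seq), icode), Moiety(moiety)


@dataclass
class HydrationTrajectory:
    """Water-oxygen frames or per-group count series over the ramp.

    Exactly one of ``frames`` (list of ``(time_ps, (n_waters, 3) array)``)
    or ``counts`` (map group id -> per-frame integer counts) is set.
    """

    frames: list[tuple[float, np.ndarray]] | None = None
    counts: dict[str, np.ndarray] | None = None
    frame_interval_ps: float = 1.0

    def __post_init__(self) -> None:
        if (self.frames is None) == (self.counts is None):
            raise InputError("provide exactly one of frames or counts")
        if self.frame_interval_ps <= 0:
            raise InputError("frame_interval_ps must be positive")
        if self.frames is not None:
            times = [t for t, _ in self.frames]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise InputError("frame times must be strictly increasing")
            self.frames = [
                (float(t), np.asarray(c, dtype=float).reshape(-1, 3))
                for t, c in self.frames
            ]
        if self.counts is not None:
            lengths = set()
            clean: dict[str, np.ndarray] = {}
            for gid, series in self.counts.items():
                arr = np.asarray(series)
                if arr.ndim != 1 or len(arr) == 0:
                    raise InputError(f"group {gid}: count series must be 1-D, non-empty")
                if np.any(arr < 0):
                    raise InputError(f"group {gid}: counts must be non-negative")
                clean[gid] = arr.astype(np.int64)
                lengths.add(len(arr))
            if len(lengths) > 1:
                raise InputError(f"groups disagree on frame count: {sorted(lengths)}")
            self.counts = clean

    @property
    def n_frames(self) -> int:
        if self.frames is not None:
            return len(self.frames)
        return len(next(iter(self.counts.values())))


def read_counts_tsv(path_or_buf, frame_interval_ps: float | None = None
                    ) -> HydrationTrajectory:
    """Read the count-series format (group_id, frame_index, time_ps, n_waters)."""
    frame = pd.read_csv(path_or_buf, sep="\t", comment="#")
    required = {"group_id", "frame_index", "time_ps", "n_waters"}
    if not required.issubset(frame.columns):
        raise InputError(
            f"count table must have columns {sorted(required)}, got {list(frame.columns)}"
        )
    counts: dict[str, np.ndarray] = {}
    for gid, sub in frame.groupby("group_id", sort=False):
        sub = sub.sort_values("frame_index")
        counts[str(gid)] = sub["n_waters"].to_numpy()
    if frame_interval_ps is None:
        times = np.sort(frame["time_ps"].unique())
        frame_interval_ps = float(times[1] - times[0]) if len(times) > 1 else 1.0
    return HydrationTrajectory(counts=counts, frame_interval_ps=frame_interval_ps)


def write_counts_tsv(traj: HydrationTrajectory, path=None) -> str | None:
    if traj.counts is None:
        raise InputError("only count-series trajectories can be written as TSV")
    rows = []
    for gid in sorted(traj.counts):
        series = traj.counts[gid]
        for i, n in enumerate(series):
            rows.append((gid, i, i * traj.frame_interval_ps, int(n)))
    frame = pd.DataFrame(rows, columns=["group_id", "frame_index", "time_ps", "n_waters"])
    if path is None:
        buf = io.StringIO()
        frame.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()
    frame.to_csv(path, sep="\t", index=False)
    return None


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def count_shell_waters(
    frame: np.ndarray, group: np.ndarray, r_shell: float
) -> int:
    """Number of water oxygens within ``r_shell`` of any group atom.

    Each water is counted at most once per group, whichever group atom
    it is closest to.
    """
    if r_shell <= 0:
        raise ConfigError("r_shell must be positive")
    group = np.asarray(group, dtype=float).reshape(-1, 3)
    if group.shape[0] == 0:
        raise GeometryError("cannot count shell waters around an empty atom group")
    frame = np.asarray(frame, dtype=float).reshape(-1, 3)
    if frame.shape[0] == 0:
        return 0
    tree = cKDTree(group)
    dist, _ = tree.query(frame, k=1)
    return int(np.count_nonzero(dist <= r_shell))


def compute_pv(
    counts: np.ndarray, window_fraction: float = 0.1, scale: float = 1.0
) -> float:
    """PARCH value: scaled mean count over the final trajectory window."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise InputError("count series must be 1-D and non-empty")
    if not 0 < window_fraction <= 1:
        raise ConfigError("window_fraction must be in (0, 1]")
    m = math.ceil(window_fraction * counts.size)
    return float(scale * counts[-m:].mean())


def structure_groups(structure: Structure) -> dict[str, list]:
    """Scoring groups of a structure: group id -> heavy atoms.

    Protein residues contribute one PROT group; DNA residues a BB and an
    NB group; waters, ions and unknown residues are excluded.
    """
    groups: dict[str, list] = {}
    for res in structure.residues:
        if res.kind is ResidueKind.PROTEIN:
            atoms = res.heavy_atoms()
            if atoms:
                groups[group_id(res.key, Moiety.PROT)] = atoms
        elif res.kind is ResidueKind.DNA:
            for moiety in (Moiety.BB, Moiety.NB):
                atoms = moiety_atoms(res, moiety)
                if atoms:
                    groups[group_id(res.key, moiety)] = atoms
    return groups


def run_parch(
    structure: Structure,
    traj: HydrationTrajectory,
    config: ParchConfig = ParchConfig(),
) -> PVTable:
    """Score every residue/moiety group of a structure from a trajectory.

    With a count-series trajectory the group ids must match the
    structure's groups exactly; orphans on either side are reported.
    With coordinate frames, shell waters are counted per frame with
    ``config.r_shell``.
    """
    groups = structure_groups(structure)
    res_names = {res.key: res.name for res in structure.residues}

    if traj.counts is not None:
        have = set(traj.counts)
        want = set(groups)
        if have != want:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise InputError(
                "trajectory groups do not match structure groups; "
                f"missing from trajectory: {missing[:5]}{'...' if len(missing) > 5 else ''}; "
                f"unknown to structure: {extra[:5]}{'...' if len(extra) > 5 else ''}"
            )
        series = traj.counts
    else:
        coords = {gid: np.array([a.coords for a in atoms])
                  for gid, atoms in groups.items()}
        series = {gid: np.zeros(len(traj.frames)) for gid in groups}
        for i, (_t, waters) in enumerate(traj.frames):
            for gid, xyz in coords.items():
                series[gid][i] = count_shell_waters(waters, xyz, config.r_shell)

    table = PVTable()
    for gid, counts in series.items():
        key, moiety = parse_group_id(gid)
        pv = compute_pv(counts, config.window_fraction, config.scale)
        table.set(key, moiety, pv, res_name=res_names.get(key, ""))
    return table
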