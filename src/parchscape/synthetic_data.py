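"""Synthetic stand-ins for the study's structures and hydration data.

Three generator families:

* **Toy structures** — a ~147-bp DNA duplex laid on a left-handed-style
  superhelix (radius 42 Å, pitch 24 Å, 1.65 turns: textbook nucleosome
  numbers) around a cylindrical pseudo-octamer of 8 protein chains, two
  per histone type.  The octamer is a geometric fixture, not a physical
  model: a coarse residue cylinder plus a "contact ridge" of residues
  tracking the central DNA turns at histone-DNA contact distance, and
  short axial tail residues so that stacked dinucleosomes develop an
  inter-nucleosome interface.  Every residue uses standard atom names so
  the backbone/nucleobase partition applies cleanly.

* **Planted hydration trajectories** — per-group water-count series
  whose final-window average realizes a prescribed PV table exactly
  (integer counts with Bresenham-style compensating dither), with an
  exponential "dewetting" decay from a hydrated plateau in the earlier
  frames and optional iid Gaussian per-frame noise.

* **PV-sample presets** — truncated Gaussian mixtures encoding the
  study's described distributional structure: a bimodal nucleosomal
  backbone with components at 1 and 5, a unimodal free-fragment backbone
  at 4, nucleobase values near 0.35, a planted −0.8 backbone shift for
  methylated cytosine, and a −1.5 inner-vs-outer backbone shift for
  dinucleosomes.  Component locations follow the described distributions;
  weights, spreads and effect sizes are synthetic choices documented in
  ``PRESETS``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from .errors import ConfigError, GeometryError, InputError
from .parch_core import (
    AnnealingSchedule,
    HydrationTrajectory,
    PVTable,
    group_id,
    parse_group_id,
    structure_groups,
)
from .structure_model import (
    Atom,
    Moiety,
    Residue,
    ResidueKind,
    Structure,
)

__all__ = [
    "MixturePreset",
    "PRESETS",
    "PlantedSystem",
    "sample_preset",
    "build_toy_nucleosome",
    "build_toy_dinucleosome",
    "gen_hydration_trajectory",
    "make_planted_system",
    "DEFAULT_CHAIN_MAP",
]


# ---------------------------------------------------------------------------
# Mixture presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixturePreset:
    """Truncated-at-zero Gaussian mixture: components are (weight, loc, spread)."""

    name: str
    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ConfigError(f"preset {self.name}: weights sum to {w}, expected 1")
        for weight, loc, spread in self.components:
            if weight <= 0 or spread <= 0 or loc < 0:
                raise ConfigError(f"preset {self.name}: invalid component "
                                  f"({weight}, {loc}, {spread})")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        weights = np.array([c[0] for c in self.components])
        which = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n)
        for i, (_w, loc, spread) in enumerate(self.components):
            mask = which == i
            k = int(mask.sum())
            if k:
                a = (0.0 - loc) / spread  # truncate at PV = 0
                out[mask] = truncnorm.rvs(a, np.inf, loc=loc, scale=spread,
                                          size=k, random_state=rng)
        return out


PRESETS: dict[str, MixturePreset] = {
    # bimodal nucleosomal backbone: components at the described peaks 1 and 5
    "nucleosomal_bb": MixturePreset(
        "nucleosomal_bb", ((0.5, 1.0, 0.4), (0.5, 5.0, 1.2))
    ),
    # isolated DNA fragment backbone: unimodal near 4
    "fragment_bb": MixturePreset("fragment_bb", ((1.0, 4.0, 1.0),)),
    # nucleobases: uniformly low, 0.3-0.4
    "nucleobase": MixturePreset("nucleobase", ((1.0, 0.35, 0.05),)),
    # backbone PV of unmethylated cytosine, and the methylated partner
    # shifted down by the planted effect of -0.8
    "methylation_dc": MixturePreset("methylation_dc", ((1.0, 4.0, 1.0),)),
    "methylation_fmc": MixturePreset("methylation_fmc", ((1.0, 3.2, 1.0),)),
    # dinucleosome backbone: inner (interface-facing) shifted -1.5 from outer
    "dinuc_outer_bb": MixturePreset("dinuc_outer_bb", ((1.0, 5.0, 1.5),)),
    "dinuc_inner_bb": MixturePreset("dinuc_inner_bb", ((1.0, 3.5, 1.5),)),
}


def sample_preset(name: str, n: int, seed: int) -> np.ndarray:
    """``n`` iid draws from a named preset; identical for identical (name, n, seed)."""
    if name not in PRESETS:
        raise InputError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    if n <= 0:
        raise InputError("n must be positive")
    rng = np.random.default_rng(seed)
    return PRESETS[name].sample(n, rng)


# ---------------------------------------------------------------------------
# Toy structure geometry
# ---------------------------------------------------------------------------

DEFAULT_CHAIN_MAP: dict[str, tuple[str, str]] = {
    "H3": ("A", "E"),
    "H4": ("B", "F"),
    "H2A": ("C", "G"),
    "H2B": ("D", "H"),
}

_DNA_CHAINS = ("I", "J")

#: backbone atom offsets in the local (radial-out, tangent, z) frame, Å
_BB_OFFSETS: dict[str, tuple[float, float, float]] = {
    "P": (0.0, 0.0, 0.0),
    "OP1": (0.4, -0.6, 0.3),
    "OP2": (0.4, 0.6, 0.3),
    "O5'": (-0.3, 0.6, -0.4),
    "C5'": (-0.7, 1.1, -0.2),
    "C4'": (-1.0, 0.8, 0.2),
    "O4'": (-1.3, 0.2, 0.0),
    "C3'": (-0.9, 1.4, 0.3),
    "O3'": (-0.7, 1.9, 0.1),
    "C2'": (-1.4, 0.9, -0.2),
    "C1'": (-1.7, 0.4, 0.1),
}

#: ring-plane coordinates (inward, tangent) of nucleobase atoms, Å.
#: Pyrimidine: idealized hexagon; purine: hexagon plus fused pentagon.
_HEX = {name: (1.39 * math.cos(math.radians(90 - 60 * i)),
               1.39 * math.sin(math.radians(90 - 60 * i)))
        for i, name in enumerate(["N1", "C6", "C5", "C4", "N3", "C2"])}
_NB_LAYOUT: dict[str, dict[str, tuple[float, float]]] = {
    "DC": {**_HEX, "O2": (-1.2, 2.2), "N4": (1.4, -2.1)},
    "DT": {**_HEX, "O2": (-1.2, 2.2), "O4": (1.4, -2.1), "C7": (2.6, 0.6)},
    "DA": {**_HEX, "N6": (1.4, -2.1), "N7": (2.6, 0.4), "C8": (3.3, -0.8),
           "N9": (2.7, -2.0)},
    "DG": {**_HEX, "O6": (1.4, -2.1), "N2": (-1.4, 2.4), "N7": (2.6, 0.4),
           "C8": (3.3, -0.8), "N9": (2.7, -2.0)},
}

_COMPLEMENT = {"DA": "DT", "DT": "DA", "DC": "DG", "DG": "DC"}

#: compact amino-acid offsets for ridge/tail residues (radial, tangent, z)
_RIDGE_AA_OFFSETS = {
    "N": (0.2, -0.6, -0.1),
    "CA": (0.0, 0.0, 0.0),
    "C": (0.2, 0.6, -0.1),
    "O": (0.5, 0.9, -0.2),
    "CB": (0.0, 0.6, 0.35),
}

#: roomier offsets for core-cylinder residues
_CORE_AA_OFFSETS = {
    "N": (0.0, -0.9, 0.6),
    "CA": (0.0, 0.0, 0.0),
    "C": (0.0, 0.9, -0.6),
    "O": (0.8, 1.2, -0.7),
    "CB": (0.9, 0.0, 0.6),
}

#: per-histone pseudo-sequences: seq_id -> residue name.  Functional
#: positions (acidic patch, sample arginines) are planted explicitly;
#: filler positions cycle through small hydrophobics.
_FILLER = ("ALA", "LEU", "SER", "VAL", "GLY", "THR")


def _histone_sequence(histone: str) -> dict[int, str]:
    planted = {
        "H2A": {56: "GLU", 61: "GLU", 64: "GLU", 90: "ASP", 91: "GLU", 92: "GLU"},
        "H2B": {102: "GLU", 110: "GLU"},
        "H3": {63: "ARG", 83: "ARG"},
        "H4": {45: "ARG"},
    }[histone]
    filler_ids = {
        "H2A": [50, 52, 54, 58, 66, 70, 75, 80, 85, 95, 100, 105, 108, 112],
        "H2B": [60, 65, 70, 75, 80, 85, 90, 95, 100, 105, 108, 115],
        "H3": [40, 48, 56, 64, 72, 88, 96, 104, 112, 120],
        "H4": [30, 37, 44, 51, 58, 65, 72, 79, 86, 93],
    }[histone]
    seq = dict(planted)
    for i, sid in enumerate(filler_ids):
        seq.setdefault(sid, _FILLER[i % len(_FILLER)])
    return dict(sorted(seq.items()))


def _frame_at(theta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local frame on the superhelix: (radial-out, tangent, z) unit vectors."""
    r_hat = np.array([math.cos(theta), math.sin(theta), 0.0])
    t_hat = np.array([-math.sin(theta), math.cos(theta), 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])
    return r_hat, t_hat, z_hat


def _place(center: np.ndarray, theta: float,
           offsets: dict[str, tuple[float, float, float]]) -> dict[str, np.ndarray]:
    r_hat, t_hat, z_hat = _frame_at(theta)
    return {
        name: center + dr * r_hat + dt * t_hat + dz * z_hat
        for name, (dr, dt, dz) in offsets.items()
    }


def _dna_residue(chain: str, seq_id: int, base: str, radius: float,
                 theta: float, z: float) -> Residue:
    center = np.array([radius * math.cos(theta), radius * math.sin(theta), z])
    coords = _place(center, theta, _BB_OFFSETS)
    atoms = [Atom(name=n, element=n[0], coords=c) for n, c in coords.items()]
    # base ring in the plane spanned by the inward radial and tangent axes
    r_hat, t_hat, _ = _frame_at(theta)
    ring_radius = radius - 3.5
    ring_center = np.array(
        [ring_radius * math.cos(theta), ring_radius * math.sin(theta), z]
    )
    for name, (inward, tang) in _NB_LAYOUT[base].items():
        pos = ring_center - inward * r_hat + tang * t_hat
        atoms.append(Atom(name=name, element=name[0], coords=pos))
    return Residue(chain_id=chain, seq_id=seq_id, name=base, atoms=atoms)


def _aa_residue(chain: str, seq_id: int, name: str, radius: float, theta: float,
                z: float, offsets: dict) -> Residue:
    center = np.array([radius * math.cos(theta), radius * math.sin(theta), z])
    coords = _place(center, theta, offsets)
    atoms = [Atom(name=n, element=n[0], coords=c) for n, c in coords.items()]
    return Residue(chain_id=chain, seq_id=seq_id, name=name, atoms=atoms)


def _check_clashes(structure: Structure, min_dist: float = 2.0) -> None:
    """Error on any inter-chain heavy-atom pair closer than ``min_dist`` Å."""
    coords, chains = [], []
    for res in structure.residues:
        for a in res.heavy_atoms():
            coords.append(a.coords)
            chains.append(res.chain_id)
    coords = np.array(coords)
    chains = np.array(chains)
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(min_dist):
        if chains[i] != chains[j]:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            raise GeometryError(
                f"inter-chain heavy-atom clash: chains {chains[i]}/{chains[j]} "
                f"at {d:.2f} A (< {min_dist} A)"
            )


def build_toy_nucleosome(
    n_bp: int = 147,
    superhelix_radius: float = 42.0,
    pitch: float = 24.0,
    turns: float = 1.65,
    chain_offset: int = 0,
    z_offset: float = 0.0,
    theta_offset: float = 0.0,
    validate: bool = True,
) -> Structure:
    """Coarse nucleosome: a DNA superhelix around a pseudo-octamer.

    Two complementary strands of ``n_bp`` residues (chains I/J, full
    standard heavy-atom names) wrap ``turns`` superhelical turns around
    8 protein chains, two per histone type (A/E = H3, B/F = H4, C/G =
    H2A, D/H = H2B).  Central-turn DNA residues sit within contact
    distance (<= 3 Å) of ridge residues; outer residues are distal.
    ``chain_offset``/``z_offset``/``theta_offset`` support dinucleosome
    stacking.  Raises on invalid geometry or inter-chain clashes.
    """
    if n_bp < 2:
        raise GeometryError("n_bp must be at least 2")
    if superhelix_radius <= 0 or pitch <= 0 or turns <= 0:
        raise GeometryError("superhelix radius, pitch and turns must be positive")

    total_angle = 2 * math.pi * turns
    z_span = pitch * turns
    thetas = theta_offset + np.linspace(0.0, total_angle, n_bp)
    zs = z_offset + np.linspace(-z_span / 2, z_span / 2, n_bp)

    def shifted_chain(c: str) -> str:
        if chain_offset == 0:
            return c
        return chr(ord(c) + chain_offset)

    residues: list[Residue] = []
    bases = [("DA", "DC", "DG", "DT")[i % 4] for i in range(n_bp)]

    # strand I on the superhelix; strand II the same path raised 3.4 Å
    for i in range(n_bp):
        residues.append(
            _dna_residue(shifted_chain("I"), i + 1, bases[i],
                         superhelix_radius, thetas[i], zs[i])
        )
    for i in range(n_bp):
        comp = _COMPLEMENT[bases[n_bp - 1 - i]]
        residues.append(
            _dna_residue(shifted_chain("J"), i + 1, comp,
                         superhelix_radius, thetas[n_bp - 1 - i],
                         zs[n_bp - 1 - i] + 3.4)
        )

    # pseudo-octamer core: 8 chains in 45-degree sectors on a cylinder
    histone_of_chain: dict[str, str] = {}
    for histone, chains in DEFAULT_CHAIN_MAP.items():
        for c in chains:
            histone_of_chain[c] = histone
    chain_ids = sorted(histone_of_chain)  # A..H
    core_radius = 25.0
    for ci, chain in enumerate(chain_ids):
        seq = _histone_sequence(histone_of_chain[chain])
        sector_center = math.radians(45.0 * ci) + theta_offset
        ids = list(seq)
        n_rows = math.ceil(len(ids) / 4)
        for k, sid in enumerate(ids):
            row, col = divmod(k, 4)
            theta = sector_center + math.radians(-13.5 + 9.0 * col)
            z = z_offset + (-10.0 + 20.0 * row / max(n_rows - 1, 1))
            residues.append(
                _aa_residue(shifted_chain(chain), sid, seq[sid],
                            core_radius, theta, z, _CORE_AA_OFFSETS)
            )

    # contact ridge: arginine-rich residues tracking the central DNA turn
    # 2.9 Å below strand I, every second base pair
    lo, hi = n_bp // 3, 2 * n_bp // 3
    for k, i in enumerate(range(lo, hi, 2)):
        theta = thetas[i]
        sector = int(((math.degrees(theta - theta_offset) % 360) + 22.5) // 45) % 8
        chain = chain_ids[sector]
        residues.append(
            _aa_residue(shifted_chain(chain), 200 + k, "ARG",
                        superhelix_radius, theta, zs[i] - 2.9, _RIDGE_AA_OFFSETS)
        )

    # axial tails flanking the DNA entry/exit gyres (they form the
    # inter-nucleosome interface when two units stack); the top tails sit
    # above the raised second strand, the bottom tails below the first
    tail_radius = superhelix_radius - 2.0
    top_theta = theta_offset + total_angle
    for t, chain in enumerate(chain_ids[:4]):
        theta = top_theta + math.radians(-12.0 + 6.0 * t)
        residues.append(
            _aa_residue(shifted_chain(chain), 1, "LYS", tail_radius, theta,
                        z_offset + z_span / 2 + 5.9, _RIDGE_AA_OFFSETS)
        )
    for t, chain in enumerate(chain_ids[4:]):
        theta = theta_offset + math.radians(-6.0 + 6.0 * t)
        residues.append(
            _aa_residue(shifted_chain(chain), 1, "LYS", tail_radius, theta,
                        z_offset - z_span / 2 - 2.5, _RIDGE_AA_OFFSETS)
        )

    structure = Structure(residues=residues, title=f"toy nucleosome ({n_bp} bp)")
    if validate:
        _check_clashes(structure)
    return structure


def build_toy_dinucleosome(
    separation: float = 60.0,
    linker_bp: int = 0,
    n_bp: int = 147,
    superhelix_radius: float = 42.0,
    pitch: float = 24.0,
    turns: float = 1.65,
) -> Structure:
    """Two stacked toy nucleosomes with unit labels and an optional linker.

    The second unit is translated ``separation`` Å along the superhelix
    axis and rotated so its DNA entry sits above the first unit's exit,
    continuing the helical path.  ``linker_bp`` > 0 inserts a straight
    duplex linker (chains M/N) between the units; its residues are
    assigned to units by splitting each strand at its midpoint.
    Overlapping placement (units too close) raises a geometry error.
    """
    if separation <= 0:
        raise GeometryError("separation must be positive")
    if linker_bp < 0:
        raise GeometryError("linker_bp must be non-negative")

    end_angle = 2 * math.pi * turns
    unit1 = build_toy_nucleosome(n_bp, superhelix_radius, pitch, turns,
                                 validate=False)
    # second copy: chains shifted far into lowercase letters to stay unique
    unit2 = build_toy_nucleosome(n_bp, superhelix_radius, pitch, turns,
                                 chain_offset=32, z_offset=separation,
                                 theta_offset=end_angle, validate=False)

    residues = list(unit1.residues) + list(unit2.residues)
    unit_labels = {r.key: 0 for r in unit1.residues}
    unit_labels.update({r.key: 1 for r in unit2.residues})

    if linker_bp > 0:
        z_span = pitch * turns
        z_lo = z_span / 2
        z_hi = separation - z_span / 2
        step = (z_hi - z_lo) / (linker_bp + 1)
        if step < 2.2:
            raise GeometryError(
                f"linker of {linker_bp} bp does not fit a {separation} A "
                f"separation (rise {step:.2f} A < 2.2 A)"
            )
        # straight vertical duplex, kept clear of both cores: radially
        # outside the superhelix and on the azimuth opposite the stacking
        # interface
        theta = end_angle + math.pi
        linker_radius = superhelix_radius + 4.0
        bases = [("DA", "DC", "DG", "DT")[i % 4] for i in range(linker_bp)]
        for i in range(linker_bp):
            z = z_lo + (i + 1) * step
            res = _dna_residue("M", i + 1, bases[i], linker_radius, theta, z)
            residues.append(res)
            unit_labels[res.key] = 0 if i < linker_bp / 2 else 1
        # second strand: same vertical grid, displaced sideways so the two
        # straight strands keep duplex-like spacing without interleaving
        theta_n = theta + 7.0 / linker_radius
        for i in range(linker_bp):
            z = z_lo + (linker_bp - i) * step + 1.1
            res = _dna_residue("N", i + 1, _COMPLEMENT[bases[linker_bp - 1 - i]],
                               linker_radius, theta_n, z)
            residues.append(res)
            unit_labels[res.key] = 0 if (linker_bp - 1 - i) < linker_bp / 2 else 1

    structure = Structure(
        residues=residues, unit_labels=unit_labels,
        title=f"toy dinucleosome (separation {separation} A, linker {linker_bp} bp)",
    )
    _check_clashes(structure)
    return structure


# ---------------------------------------------------------------------------
# Planted hydration trajectories
# ---------------------------------------------------------------------------


def _dithered_counts(target: np.ndarray) -> np.ndarray:
    """Integer series whose running sums track the target's (Bresenham dither)."""
    cum = np.round(np.cumsum(target)).astype(np.int64)
    counts = np.diff(np.concatenate([[0], cum]))
    return np.maximum(counts, 0)


def gen_hydration_trajectory(
    structure: Structure,
    planted_pv: PVTable,
    schedule: AnnealingSchedule = AnnealingSchedule(),
    noise_sd: float = 0.0,
    seed: int = 0,
    n_frames: int = 2000,
    window_fraction: float = 0.1,
    plateau_excess: float = 6.0,
) -> HydrationTrajectory:
    """Count series realizing a planted PV table through ``run_parch``.

    Earlier frames decay exponentially from a hydrated plateau
    (``pv + plateau_excess`` waters) to the target, mimicking annealing
    dewetting; the final ``window_fraction`` of frames is flat at the
    target.  At ``noise_sd = 0`` the integer window mean equals the
    planted value exactly whenever ``pv * window_frames`` is integral
    (PVs on a 0.005 grid with the default 200-frame window); with noise,
    frames get iid Gaussian perturbations, stochastically rounded so
    counts stay unbiased integers.
    """
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    if n_frames < 10:
        raise InputError("n_frames must be at least 10")
    groups = structure_groups(structure)
    missing = [
        gid for gid in groups
        if planted_pv.get(*parse_group_id(gid)) is None
    ]
    if missing:
        raise InputError(
            f"planted PV table does not cover groups: {missing[:5]}"
            f"{'...' if len(missing) > 5 else ''}"
        )
    rng = np.random.default_rng(seed)
    m = math.ceil(window_fraction * n_frames)
    decay_len = n_frames - m
    t = np.arange(decay_len) / max(decay_len, 1)
    counts: dict[str, np.ndarray] = {}
    for gid in sorted(groups):
        pv = planted_pv.get(*parse_group_id(gid))
        target = np.empty(n_frames)
        target[:decay_len] = pv + plateau_excess * np.exp(-6.0 * t)
        target[decay_len:] = pv
        if noise_sd == 0:
            # dither the decay freely; the window must be exact, so
            # dither it separately starting from a clean accumulator
            head = _dithered_counts(target[:decay_len])
            tail = _dithered_counts(target[decay_len:])
            counts[gid] = np.concatenate([head, tail])
        else:
            noisy = target + rng.normal(0.0, noise_sd, size=n_frames)
            floor = np.floor(noisy)
            frac = noisy - floor
            counts[gid] = np.maximum(
                floor + (rng.random(n_frames) < frac), 0
            ).astype(np.int64)
    frame_interval = schedule.duration_ps / n_frames if schedule.duration_ps > 0 else 1.0
    return HydrationTrajectory(counts=counts, frame_interval_ps=frame_interval)


@dataclass
class PlantedSystem:
    """A toy structure, its planted ground-truth PVs, and a realizing trajectory."""

    structure: Structure
    planted_pv: PVTable
    trajectory: HydrationTrajectory
    seed: int


def make_planted_system(
    seed: int = 0,
    n_bp: int = 24,
    noise_sd: float = 0.0,
    n_frames: int = 2000,
    structure: Structure | None = None,
) -> PlantedSystem:
    """Toy nucleosome with preset-drawn planted PVs and a realizing trajectory.

    BB values come from the nucleosomal-backbone preset, NB values from
    the nucleobase preset, PROT values from the fragment preset, all
    quantized to the 0.005 grid the 200-frame scoring window can realize
    exactly.
    """
    rng = np.random.default_rng(seed)
    if structure is None:
        structure = build_toy_nucleosome(n_bp=n_bp)
    res_names = {r.key: r.name for r in structure.residues}
    table = PVTable()
    for gid in sorted(structure_groups(structure)):
        key, moiety = parse_group_id(gid)
        preset = {
            Moiety.BB: PRESETS["nucleosomal_bb"],
            Moiety.NB: PRESETS["nucleobase"],
            Moiety.PROT: PRESETS["fragment_bb"],
        }[moiety]
        pv = float(preset.sample(1, rng)[0])
        pv = max(round(pv * 200) / 200, 0.0)
        table.set(key, moiety, pv, res_name=res_names.get(key, ""))
    traj = gen_hydration_trajectory(
        structure, table, noise_sd=noise_sd, seed=seed + 1, n_frames=n_frames
    )
    return PlantedSystem(structure=structure, planted_pv=table,
                         trajectory=traj, seed=seed)
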