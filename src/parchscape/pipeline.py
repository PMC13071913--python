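"""End-to-end analyses on packaged fixtures.

Each ``run_*`` function reproduces one analysis layout — backbone /
nucleobase density distributions, paired ΔPV tables, dinucleosome
inner/outer comparisons — on synthetic presets or user-supplied PV
tables, and exports TSVs whose headers embed the full configuration and
seed, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .classifiers import (
    ACIDIC_PATCH_SPECS,
    classify_inner_outer,
    contact_residues,
    select_acidic_patch,
    select_residue_set,
)
from .delta import DeltaResult, delta_pv
from .errors import ConfigError, InputError
from .hydro_stats import (
    DensityEstimate,
    GroupComparison,
    ViolinSummary,
    compare_groups,
    find_modes,
    kde,
    violin_summary,
)
from .parch_core import PVTable
from .structure_model import Moiety, ResidueKind, Structure
from .synthetic_data import (
    DEFAULT_CHAIN_MAP,
    PRESETS,
    build_toy_dinucleosome,
    sample_preset,
)

__all__ = [
    "PipelineConfig",
    "Fig2Result",
    "DinucResult",
    "run_fig2_analysis",
    "run_paired_delta",
    "run_dinuc_analysis",
]


@dataclass
class PipelineConfig:
    """All pipeline knobs; serializes to/from YAML and into output headers."""

    proximal_cutoff: float = 3.0
    contact_cutoff: float = 8.0
    inner_cutoff: float = 20.0
    t_start: float = 300.0
    t_end: float = 800.0
    rate: float = 0.1
    r_shell: float = 4.0
    window_fraction: float = 0.1
    kde_bandwidth: str | float = "silverman"
    min_prominence: float = 0.05
    zero_tol: float = 0.05
    seed: int = 1
    n_preset: int = 5000
    n_bp: int = 147
    separation: float = 60.0
    linker_bp: int = 0

    def __post_init__(self) -> None:
        for name in ("proximal_cutoff", "contact_cutoff", "inner_cutoff", "r_shell"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.window_fraction <= 1:
            raise ConfigError("window_fraction must be in (0, 1]")
        if self.n_preset < 2:
            raise ConfigError("n_preset must be at least 2")

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is None:
            return text
        Path(path).write_text(text)
        return None

    @classmethod
    def from_yaml(cls, path_or_buf) -> "PipelineConfig":
        if hasattr(path_or_buf, "read"):
            raw = yaml.safe_load(path_or_buf)
        else:
            raw = yaml.safe_load(Path(path_or_buf).read_text())
        if raw is None:
            return cls()
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def header(self) -> str:
        items = sorted(dataclasses.asdict(self).items())
        return "".join(f"# {k} = {v}\n" for k, v in items)


def _write_tsv(frame: pd.DataFrame, config: PipelineConfig, path=None) -> str | None:
    text = config.header() + frame.to_csv(sep="\t", index=False, float_format="%.6g")
    if path is None:
        return text
    Path(path).write_text(text)
    return None


# ---------------------------------------------------------------------------
# Density / mode analysis
# ---------------------------------------------------------------------------


@dataclass
class Fig2Result:
    densities: dict[str, DensityEstimate]
    modes: dict[str, list[float]]
    config: PipelineConfig

    def density_frame(self) -> pd.DataFrame:
        parts = []
        for name, d in sorted(self.densities.items()):
            frame = d.to_frame()
            frame.insert(0, "group", name)
            parts.append(frame)
        return pd.concat(parts, ignore_index=True)

    def mode_frame(self) -> pd.DataFrame:
        rows = [
            {"group": name, "mode_index": i, "location": loc}
            for name, locs in sorted(self.modes.items())
            for i, loc in enumerate(locs)
        ]
        return pd.DataFrame(rows, columns=["group", "mode_index", "location"])

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_tsv(self.density_frame(), self.config, out_dir / "density.tsv")
        _write_tsv(self.mode_frame(), self.config, out_dir / "modes.tsv")


def run_fig2_analysis(
    config: PipelineConfig,
    pv_table: PVTable | None = None,
    structure: Structure | None = None,
) -> Fig2Result:
    """Density distributions and modes of backbone/nucleobase PV samples.

    Without inputs, the packaged presets are analyzed (nucleosomal
    backbone, free-fragment backbone, nucleobase).  Given a PV table it
    analyzes its BB and NB values instead, stratified per base
    (dA/dC/dG/dT) when a structure provides base identities.
    """
    samples: dict[str, np.ndarray] = {}
    if pv_table is None:
        for offset, name in enumerate(("nucleosomal_bb", "fragment_bb", "nucleobase")):
            samples[name] = sample_preset(name, config.n_preset, config.seed + offset)
    else:
        samples["BB"] = pv_table.values_for(Moiety.BB)
        samples["NB"] = pv_table.values_for(Moiety.NB)
        if structure is not None:
            by_base: dict[str, list[float]] = {}
            for res in structure.dna_residues():
                v = pv_table.get(res.key, Moiety.BB)
                if v is not None:
                    by_base.setdefault(res.name.upper(), []).append(v)
            for base, vals in sorted(by_base.items()):
                if len(vals) >= 2:
                    samples[f"BB_{base}"] = np.array(vals)
    samples = {k: v for k, v in samples.items() if v.size >= 2}
    if not samples:
        raise InputError("no PV samples to analyze (empty input)")
    densities = {name: kde(vals, config.kde_bandwidth) for name, vals in samples.items()}
    modes = {name: find_modes(d, config.min_prominence) for name, d in densities.items()}
    return Fig2Result(densities=densities, modes=modes, config=config)


# ---------------------------------------------------------------------------
# Paired-system ΔPV
# ---------------------------------------------------------------------------


def run_paired_delta(
    config: PipelineConfig,
    pv_a: PVTable,
    pv_b: PVTable,
    restrict_to: str | None = None,
    structure: Structure | None = None,
    chain_map: Mapping[str, tuple[str, ...]] | None = None,
    out_path=None,
) -> DeltaResult:
    """ΔPV table between two system states, optionally restricted to a residue set.

    ``restrict_to`` may be ``"acidic_patch"`` or ``"contacts"``; both
    need the structure (and a chain map for the acidic patch).
    """
    result = delta_pv(pv_a, pv_b, zero_tol=config.zero_tol)
    if restrict_to is not None:
        if structure is None:
            raise InputError(f"restrict_to={restrict_to!r} requires a structure")
        if restrict_to == "acidic_patch":
            sel = select_acidic_patch(structure, chain_map or DEFAULT_CHAIN_MAP)
            keep = set(sel.keys)
        elif restrict_to == "contacts":
            keep = contact_residues(structure, config.contact_cutoff)
        else:
            raise ConfigError(f"unknown restriction {restrict_to!r}")
        result.records = [r for r in result.records if r.residue_key in keep]
    if out_path is not None:
        text = config.header() + result.to_tsv()
        Path(out_path).write_text(text)
    return result


# ---------------------------------------------------------------------------
# Dinucleosome inner/outer analysis
# ---------------------------------------------------------------------------


@dataclass
class DinucResult:
    comparisons: dict[str, GroupComparison]
    violins: dict[str, ViolinSummary]  # keyed "MOIETY_inner"/"MOIETY_outer"
    n_inner: int
    n_outer: int
    config: PipelineConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for moiety, comp in sorted(self.comparisons.items()):
            rows.append(
                {
                    "moiety": moiety,
                    "u_statistic": comp.u_statistic,
                    "p_value": comp.p_value,
                    "stars": comp.stars,
                    "n1": comp.n1,
                    "n2": comp.n2,
                    "median_shift": comp.median_shift,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["moiety", "u_statistic", "p_value", "stars", "n1", "n2",
                     "median_shift"],
        )

    def write(self, path) -> None:
        _write_tsv(self.to_frame(), self.config, path)


def run_dinuc_analysis(
    config: PipelineConfig,
    structure: Structure | None = None,
    pv_table: PVTable | None = None,
) -> DinucResult:
    """Inner/outer group comparisons for BB, NB and PROT PV values.

    Without inputs, a toy dinucleosome is built and planted PVs are
    drawn per residue: backbone values from the inner/outer presets
    according to each residue's classification (the planted interface
    effect), nucleobase and protein values from shift-free presets.
    An input with an empty inner or outer group is an error.
    """
    if structure is None:
        structure = build_toy_dinucleosome(
            separation=config.separation, linker_bp=config.linker_bp,
            n_bp=config.n_bp,
        )
    classification = classify_inner_outer(structure, config.inner_cutoff)
    inner_keys = classification.keys_with("INNER")
    outer_keys = classification.keys_with("OUTER")
    if not inner_keys or not outer_keys:
        raise InputError(
            f"degenerate classification: {len(inner_keys)} inner / "
            f"{len(outer_keys)} outer residues"
        )

    if pv_table is None:
        pv_table = _plant_dinuc_pv(structure, classification, config.seed)

    comparisons: dict[str, GroupComparison] = {}
    violins: dict[str, ViolinSummary] = {}
    for moiety in (Moiety.BB, Moiety.NB, Moiety.PROT):
        inner_vals = pv_table.values_for(moiety, inner_keys)
        outer_vals = pv_table.values_for(moiety, outer_keys)
        if inner_vals.size < 2 or outer_vals.size < 2:
            raise InputError(
                f"{moiety.value}: need >= 2 inner and outer values, got "
                f"{inner_vals.size}/{outer_vals.size}"
            )
        comparisons[moiety.value] = compare_groups(inner_vals, outer_vals)
        violins[f"{moiety.value}_inner"] = violin_summary(inner_vals)
        violins[f"{moiety.value}_outer"] = violin_summary(outer_vals)
    return DinucResult(
        comparisons=comparisons, violins=violins,
        n_inner=len(inner_keys), n_outer=len(outer_keys), config=config,
    )


def _plant_dinuc_pv(structure: Structure, classification, seed: int) -> PVTable:
    """Planted PVs keyed to the inner/outer classification (BB shift only)."""
    rng = np.random.default_rng(seed)
    table = PVTable()
    inner_keys = classification.keys_with("INNER")
    for res in structure.residues:
        if res.kind is ResidueKind.PROTEIN:
            pv = float(PRESETS["fragment_bb"].sample(1, rng)[0])
            table.set(res.key, Moiety.PROT, pv, res_name=res.name)
        elif res.kind is ResidueKind.DNA:
            bb_preset = (
                PRESETS["dinuc_inner_bb"] if res.key in inner_keys
                else PRESETS["dinuc_outer_bb"]
            )
            table.set(res.key, Moiety.BB, float(bb_preset.sample(1, rng)[0]),
                      res_name=res.name)
            table.set(res.key, Moiety.NB, float(PRESETS["nucleobase"].sample(1, rng)[0]),
                      res_name=res.name)
    return table
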