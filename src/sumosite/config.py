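"""TOML run configuration and remnant-definition serialization."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

from .chem import RemnantDefinition, parse_composition
from .filtering import FilterParams

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "remnants_to_toml",
    "remnants_from_toml",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_KNOWN_SECTIONS = {
    "paths", "filter", "quant", "equilibrium", "simulate", "conservation",
}
_KNOWN_KEYS = {
    "paths": {
        "evidence", "design", "fasta", "annotations", "msa_dir", "out_dir",
        "protein_names", "lysine_classes",
    },
    "filter": {
        "min_delta_multi", "min_loc_delta", "min_andromeda",
        "min_delta_single", "require_diagnostic", "min_peptide_length",
    },
    "quant": {"s0", "fdr", "n_perm", "seed", "impute_width", "impute_shift",
              "min_detected", "min_peptides"},
    "equilibrium": {"species", "error_type"},
    "simulate": {
        "seed", "n_proteins", "n_sites", "kxe_adherence", "conditions",
        "replicates", "intensity_cv", "missing_rate", "decoy_rate",
        "comod_rate",
    },
    "conservation": {"matrix", "alpha_diversity", "beta_chemistry",
                     "gamma_gap", "weighting"},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    paths: Dict[str, str] = field(default_factory=dict)
    filter_params: FilterParams = field(default_factory=FilterParams)
    quant: Dict[str, float] = field(default_factory=dict)
    equilibrium: Dict[str, str] = field(default_factory=dict)
    simulate: Dict[str, object] = field(default_factory=dict)
    conservation: Dict[str, object] = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration (unknown keys rejected)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config section(s) {sorted(unknown)}")
    for section, keys in raw.items():
        bad = set(keys) - _KNOWN_KEYS[section]
        if bad:
            raise ConfigError(
                f"unknown key(s) {sorted(bad)} in section [{section}]"
            )
    filt = raw.get("filter", {})
    params = FilterParams(
        min_delta_multi=float(filt.get("min_delta_multi", 40.0)),
        min_loc_delta=float(filt.get("min_loc_delta", 6.0)),
        min_andromeda=float(filt.get("min_andromeda", 40.0)),
        min_delta_single=float(filt.get("min_delta_single", 20.0)),
        require_diagnostic=bool(filt.get("require_diagnostic", True)),
        min_peptide_length=int(filt.get("min_peptide_length", 7)),
    )
    return RunConfig(
        paths={k: str(v) for k, v in raw.get("paths", {}).items()},
        filter_params=params,
        quant=dict(raw.get("quant", {})),
        equilibrium=dict(raw.get("equilibrium", {})),
        simulate=dict(raw.get("simulate", {})),
        conservation=dict(raw.get("conservation", {})),
    )


def _toml_str_list(values: Sequence[str]) -> str:
    return "[" + ", ".join(f'"{v}"' for v in values) + "]"


def remnants_to_toml(remnants: Sequence[RemnantDefinition], path: str | Path) -> None:
    """Write remnant definitions as a TOML document."""
    lines: List[str] = []
    for r in remnants:
        lines.append("[[remnant]]")
        lines.append(f'name = "{r.name}"')
        lines.append(f'protease = "{r.protease}"')
        lines.append(f'sequence = "{r.sequence}"')
        lines.append(f'composition = "{r.composition.formula()}"')
        lines.append(f"monoisotopic_mass = {r.monoisotopic_mass!r}")
        lines.append(f"neutral_losses = {_toml_str_list(r.neutral_losses)}")
        lines.append(f"diagnostic_ions = {_toml_str_list(r.diagnostic_ions)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def remnants_from_toml(path: str | Path) -> List[RemnantDefinition]:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    out = []
    for entry in raw.get("remnant", []):
        out.append(
            RemnantDefinition(
                name=entry["name"],
                protease=entry["protease"],
                sequence=entry["sequence"],
                composition=parse_composition(entry["composition"]),
                monoisotopic_mass=float(entry["monoisotopic_mass"]),
                neutral_losses=list(entry.get("neutral_losses", [])),
                diagnostic_ions=list(entry.get("diagnostic_ions", [])),
            )
        )
    return out
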