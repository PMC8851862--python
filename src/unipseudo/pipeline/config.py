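"""Pipeline configuration: flat key-value file, strict key checking."""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # input paths ("" = not provided)
    reference_fasta: str = ""
    reference_gff3: str = ""
    query_fasta: str = ""
    control_fasta: str = ""  # optional second species, used by the relax gate
    read_support: str = ""
    synteny: str = ""
    obo: str = ""
    gaf: str = ""
    keyword_map: str = ""
    # species roles
    species: str = "query"
    control_species: str = "control"
    reference_species: str = "reference"
    # thresholds (defaults fixed by contract)
    flank: int = 5000
    evalue: float = 1e-3
    copy_cov: float = 0.8
    trunc: float = 0.9
    window: int = 30
    min_identity: float = 0.4
    gap_flank: int = 6
    min_aln: int = 150
    k_threshold: float = 1.0
    fdr_alpha: float = 0.05
    boundary_nt: int = 10
    coverage_floor: float = 0.5
    min_chain_cov: float = 0.4
    n_decoys: int = 200
    read_support_min: float = 0.8
    read_depth_min: int = 5
    # behaviour
    check_reads: bool = True
    relax_gate: bool = True
    seed: int = 0
    family_exclusion: tuple[str, ...] = (
        "olfactory receptor",
        "zinc finger",
        "vomeronasal receptor",
    )


_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def parse_config(path: Path) -> PipelineConfig:
    """Parse 'key = value' lines; unknown keys are rejected."""
    spec = {f.name: f for f in fields(PipelineConfig)}
    kwargs: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in spec:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        ftype = spec[key].type
        try:
            if ftype == "bool":
                kwargs[key] = _BOOL[value.lower()]
            elif ftype == "int":
                kwargs[key] = int(value)
            elif ftype == "float":
                kwargs[key] = float(value)
            elif ftype == "tuple[str, ...]":
                kwargs[key] = tuple(v.strip() for v in value.split(",") if v.strip())
            else:
                kwargs[key] = value
        except (ValueError, KeyError) as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key}: {value!r}") from exc
    return PipelineConfig(**kwargs)


def write_config(config: PipelineConfig, path: Path) -> None:
    lines = []
    for f in fields(PipelineConfig):
        v = getattr(config, f.name)
        if isinstance(v, tuple):
            v = ", ".join(v)
        lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")
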