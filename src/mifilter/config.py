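"""Run configuration: one validated YAML file for all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .io_xl import DEFAULT_DECOY_PREFIXES
from .linktypes import TypeMapping, UnmappedPolicy
from .records import ConfigError
from .structval import DEFAULT_DISTANCE_CUTOFF
from .synth import SynthConfig


@dataclass
class RunConfig:
    """Merged view of all module configurations.

    Loaded from YAML; unknown keys are rejected so typos fail loudly
    before any stage runs. Command-line flags override file values.
    """

    decoy_prefixes: list[str] = field(
        default_factory=lambda: list(DEFAULT_DECOY_PREFIXES)
    )
    #: raw label -> mono/intra/inter/drop
    type_mapping: dict[str, str] = field(default_factory=dict)
    unmapped_policy: str = "error"
    cutoffs: list[float] = field(default_factory=lambda: [20.0, 25.0, 28.0, 32.0])
    min_replicates: Optional[int] = None
    #: canonical field -> source column (switches on the generic CSV reader)
    column_map: Optional[dict[str, str]] = None
    csv_delimiter: str = ","
    strict: bool = True
    #: protein accession -> list of structure chain ids
    chain_map: dict[str, list[str]] = field(default_factory=dict)
    #: chain id -> residue-numbering offset
    offsets: dict[str, int] = field(default_factory=dict)
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF
    synth: dict = field(default_factory=dict)
    log_level: str = "INFO"
    outdir: str = "."

    def __post_init__(self) -> None:
        UnmappedPolicy(self.unmapped_policy.lower())
        self.synth_config()  # validates synth parameters
        self.link_type_mapping()  # validates canonical labels

    @classmethod
    def load(cls, path: Optional[str | Path]) -> "RunConfig":
        """Read a YAML config file; ``None`` yields the defaults."""
        if path is None:
            return cls()
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def link_type_mapping(self) -> TypeMapping:
        return TypeMapping.from_config(self.type_mapping, self.unmapped_policy)

    def synth_config(self) -> SynthConfig:
        return SynthConfig.from_dict(dict(self.synth))

    def pipeline_kwargs(self) -> dict:
        """Keyword arguments for :func:`mifilter.core.run_pipeline`."""
        return {
            "decoy_prefixes": tuple(self.decoy_prefixes),
            "type_mapping": self.link_type_mapping(),
            "column_map": self.column_map,
            "csv_delimiter": self.csv_delimiter,
            "strict": self.strict,
        }
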