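"""Pipeline configuration: one human-readable YAML file drives every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .domains import ScanConfig
from .errors import ConfigurationError


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults reproduce the packaged repertoire-fixture results."""

    motif_path: str | None = None          # None -> packaged registry
    scan: ScanConfig = field(default_factory=ScanConfig)
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    local_identity: bool = False
    ddct_mode: str = "pfaffl"              # pfaffl | classic
    reference_gene: str = "rp49"
    exclusions_path: str | None = None     # None -> packaged curation list
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ddct_mode not in ("pfaffl", "classic"):
            raise ConfigurationError(f"unknown ddct mode {self.ddct_mode!r}")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        scan = ScanConfig(**data.pop("scan", {}) or {})
        return cls(scan=scan, **data)

    def digest(self) -> str:
        """Short stable hash for provenance logging."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)
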