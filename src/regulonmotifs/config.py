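"""Pipeline configuration with defaults matching the published procedure."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and knobs of the motif-search pipeline.

    Defaults reproduce the published parameter set: DEG selection at
    >=3-fold with q <= 0.05; 500 bp upstream + 50 bp downstream promoter
    windows; motif widths 8-50 with motif E <= 0.1 (ANR model, both
    strands); site q <= 0.05; Criterion A at <=1000 sites; Criterion B at
    >10%; 20 homologs per footprinting seed.
    """

    min_fold: float = 3.0
    max_q_deg: float = 0.05
    max_q_site: float = 0.05
    upstream: int = 500
    downstream: int = 50
    wmin: int = 8
    wmax: int = 50
    max_evalue: float = 0.1
    max_motifs: int = 5
    max_sites: int = 1000
    min_fraction: float = 0.10
    top_n_homologs: int = 20
    both_strands: bool = True
    seed: int = 1
    # numerical knobs of the EM search and the scanner
    n_starts: int = 100
    n_refine: int = 2
    n_shuffles: int = 20
    bins: int = 1000
    width_sweep: tuple[int, ...] | str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(data.get("width_sweep"), list):
            data["width_sweep"] = tuple(data["width_sweep"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if isinstance(data["width_sweep"], tuple):
            data["width_sweep"] = list(data["width_sweep"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
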