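"""Pipeline configuration: defaults, file loading, provenance hashing.

Every knob of the pipeline lives here with a default, so a run is fully
described by (config, seed, inputs). Configs load from a plain-text
key-value (YAML) file; unknown keys are rejected rather than ignored, and
the fully resolved config is echoed into every output for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # I/O
    pixel_size_um: float | None = None  # override for uncalibrated TIFFs
    out_dir: str = "results"
    # segmentation
    min_area_um2: float = 0.2
    bin_edges_um: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    myofibril_axis_deg: float = 0.0
    exclude_edges: bool = True
    # aggregate scoring
    rows: int = 16
    cols: int = 16
    threshold_mode: str = "global"
    area_cutoff_um2: float = 1.0
    # cross sections
    step_deg: float = 2.0
    n_rotations: int = 180
    min_coverage: float = 0.9
    prominence_min: float = 0.1
    smoothing_window: int = 5
    # statistics
    exact_limit: int = 200
    mc_replicates: int = 100_000
    # simulation driver (used when no input images are given)
    n_fields_per_group: int = 2
    mutant_diameter_factor: float = 0.7
    n_aggregates: int = 0
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("global", "per_tile"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        self.bin_edges_um = tuple(float(e) for e in self.bin_edges_um)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["bin_edges_um"] = list(d["bin_edges_um"])
        return d

    def config_hash(self) -> str:
        """Hash of the computation-relevant settings (out_dir excluded)."""
        d = self.resolved()
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
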