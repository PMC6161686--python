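"""Run configuration: every threshold and toggle of the pipeline in one
auditable document, with a hash echoed into every output file."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    """All pipeline knobs with their literature-default values."""

    seed: int = 1

    # mircall
    min_reads: int = 10                 # criterion i
    min_homogeneity: float = 0.5        # criterion iii
    overhang_mode: str = "strict2"      # criterion ii: strict2 | relaxed0to4
    energy_threshold: Optional[float] = None   # criterion iv; None = backend default
    min_pairing: float = 0.60           # criterion v
    pseudocount: float = 1.0
    ko_max_log2fc: float = -2.0         # "clearly downregulated" in the knockout
    dev_min_abs_log2fc: float = 1.0
    mor_max_gap: int = 3
    fold_flank: int = 20                # hairpin window = feature +- flank
    stack_min_overlap: float = 0.75

    # readclass
    length_filter: int = 21
    weight_by_hits: bool = False

    # extent
    min_depth: int = 1
    readthrough_max_gap: int = 50
    readthrough_a_frac: float = 0.8

    # termini
    motif_window: int = 140
    motif_min_run: int = 8
    pfm_upstream_span: int = 30

    # io
    genome: Optional[str] = None
    features: Optional[str] = None
    outdir: str = "out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
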