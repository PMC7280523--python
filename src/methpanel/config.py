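"""Pipeline configuration and deterministic seed fan-out.

One global seed drives every stochastic stage. Stage seeds derive from it as
``SeedSequence((seed, stage_index)).generate_state(1)[0] % 2**31`` with the
stage order fixed below, so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import yaml

STAGES = ("reference", "cohort", "calls", "assay", "cv")


def stage_seed(seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence((seed, idx)).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its default."""

    seed: int = 0
    # reference generation
    n_islands: int = 12
    island_len: int = 600
    inter_island_len: int = 800
    xmai_density: float = 4.0
    bsthhi_density: float = 8.0
    # cohort
    n_responders: int = 27
    n_nonresponders: int = 10
    n_markers: int = 10
    enrichment: float = 0.8
    n_background_cpgs: int = 200
    missing_rate: float = 0.0
    # library / beta calling
    min_fragment_len: int = 110
    max_fragment_len: int = 200
    min_coverage: int = 5
    # screening
    alpha: float = 0.01
    tss_window: int = 1000
    # assay design
    min_sites: int = 3
    max_product_len: int = 200
    min_clear_flank: int = 50
    # platform transfer / assay readout
    call_threshold: float = 0.5
    flip_prob: float = 0.29
    control_fail_prob: float = 0.03
    # evaluation
    cv_repeats: int = 100
    cv_folds: int = 5
    max_combo_size: int = 3
    n_combo_candidates: int = 6
    positive_class: str = "PR"

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
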