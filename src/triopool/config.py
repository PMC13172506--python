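"""Run configuration: every tunable threshold of the workflow in one place.

The defaults are the validated operating point of the method: proband calls
need VAF >= 0.3 and DP >= 20; pool presence is decided at VAF >= 1%;
dominant-context variants need gnomAD AC < 5 and recessive-context ones
AF < 0.1%; missense evidence combines CADD/REVEL/AlphaMissense/SIFT by
majority of available predictors.  Configs load from YAML with unknown
keys rejected, and dump back to YAML for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # proband call QC
    proband_min_vaf: float = 0.3
    proband_min_dp: int = 20
    # pooled-parent evidence
    pool_presence_threshold: float = 0.01
    pool_size: int = 8
    # SNV prioritization
    predictor_mode: str = "majority"  # majority | all_of | any_of
    # CNV cascade
    loeuf_rule: str = "literal"  # literal | semantic | off
    loeuf_cutoff: float = 0.6
    dosage_score_max: float = 40.0
    max_run_recurrence: int = 1
    min_reciprocal_overlap: float = 0.5
    # workflow routing: patients with 1..max_unresolved_vus solo candidates
    # are resolved by single-variant segregation instead of entering the
    # trio phase; 0 sends every undiagnosed patient with pools to the trio.
    max_unresolved_vus: int = 0
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("proband_min_vaf", 0.0, 1.0),
            ("pool_presence_threshold", 0.0, 1.0),
            ("min_reciprocal_overlap", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} out of [{lo}, {hi}]")
        if self.proband_min_dp < 0 or self.pool_size < 1:
            raise ValueError("proband_min_dp must be >= 0 and pool_size >= 1")
        if self.predictor_mode not in ("majority", "all_of", "any_of"):
            raise ValueError(f"unknown predictor_mode {self.predictor_mode!r}")
        if self.loeuf_rule not in ("literal", "semantic", "off"):
            raise ValueError(f"unknown loeuf_rule {self.loeuf_rule!r}")
        if self.max_unresolved_vus < 0 or self.max_run_recurrence < 0:
            raise ValueError("count thresholds must be >= 0")
        if self.verbosity not in ("debug", "info", "warning"):
            raise ValueError(f"unknown verbosity {self.verbosity!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
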