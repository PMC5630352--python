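"""Run configuration: YAML loading and up-front validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems)
        )


@dataclass
class RunConfig:
    """Declarative configuration for pipeline runs.

    All thresholds and window sizes live here; paths are resolved
    relative to the config file's directory when loaded from YAML.
    """

    # transition analysis inputs
    annotation: str | None = None
    annotation_format: str = "BED"
    peaks: dict[str, str] = field(default_factory=dict)  # "<mark>:<condition>" -> path
    condition_a: str = "vector"
    condition_b: str = "twist"
    promoter_upstream: int = 2000
    promoter_downstream: int = 2000
    # expression / signature / enrichment inputs
    expression: str | None = None
    signature: str | None = None
    ontology: str | None = None
    fpkm_threshold: float = 10.0
    # cohort inputs
    cohort_matrix: str | None = None
    cohort_metadata: str | None = None
    cohort_gene: str | None = None
    geneset_statistic: str = "sum"
    # qPCR inputs
    rt_ct: str | None = None
    chip_ct: str | None = None
    reference_gene: str = "GAPDH"
    comparisons: dict[str, list[str]] = field(default_factory=dict)
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "bivtrans_out"

    def validate(self, stages: list[str]) -> None:
        """Validate everything the requested stages need; aggregate errors."""
        problems: list[str] = []
        if not (0.0 < self.alpha < 1.0):
            problems.append(f"alpha must be in (0, 1), got {self.alpha}")
        if "classify" in stages:
            if not self.annotation:
                problems.append("annotation path missing")
            elif not Path(self.annotation).exists():
                problems.append(f"annotation file not found: {self.annotation}")
            for mark in ("H3K4me3", "H3K27me3"):
                for cond in (self.condition_a, self.condition_b):
                    key = f"{mark}:{cond}"
                    if key not in self.peaks:
                        problems.append(f"peak file missing for {key}")
                    elif not Path(self.peaks[key]).exists():
                        problems.append(
                            f"peak file not found for {key}: {self.peaks[key]}"
                        )
        if "expression" in stages and (
            not self.expression or not Path(self.expression).exists()
        ):
            problems.append(f"expression table missing or not found: {self.expression}")
        if "overlap" in stages and (
            not self.signature or not Path(self.signature).exists()
        ):
            problems.append(f"signature file missing or not found: {self.signature}")
        if "enrich" in stages and (
            not self.ontology or not Path(self.ontology).exists()
        ):
            problems.append(f"ontology GMT missing or not found: {self.ontology}")
        if "cohort" in stages:
            for name in ("cohort_matrix", "cohort_metadata"):
                value = getattr(self, name)
                if not value or not Path(value).exists():
                    problems.append(f"{name} missing or not found: {value}")
        if "qpcr" in stages:
            if not self.rt_ct or not Path(self.rt_ct).exists():
                problems.append(f"rt_ct table missing or not found: {self.rt_ct}")
            for name in ("down", "up", "block"):
                pair = self.comparisons.get(name)
                if not pair or len(pair) != 2:
                    problems.append(
                        f"comparison {name!r} must list [control, condition] samples"
                    )
        if problems:
            raise ConfigError(problems)

    def content_hash(self) -> str:
        """Hash of the analysis-relevant configuration (outdir excluded)."""
        payload = {k: v for k, v in self.__dict__.items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as handle:
            raw: dict[str, Any] = yaml.safe_load(handle) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError([f"unknown config key {k!r}" for k in sorted(unknown)])
        config = cls(**raw)
        base = path.parent
        for attr in (
            "annotation",
            "expression",
            "signature",
            "ontology",
            "cohort_matrix",
            "cohort_metadata",
            "rt_ct",
            "chip_ct",
        ):
            value = getattr(config, attr)
            if value and not Path(value).is_absolute():
                setattr(config, attr, str(base / value))
        config.peaks = {
            key: (value if Path(value).is_absolute() else str(base / value))
            for key, value in config.peaks.items()
        }
        return config
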