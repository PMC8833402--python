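"""Pipeline configuration.

Every threshold and tuning constant of the analysis lives in
:class:`AnalysisConfig` so that a run is fully described by one YAML file
plus a seed.  Result tables written by the pipeline carry a hash of the
configuration in their header comment, which makes outputs traceable and
lets the determinism check compare runs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Any

import yaml

VALID_LINKAGES = ("ward", "complete")


@dataclass
class AnalysisConfig:
    """All tunable constants of the analysis pipeline.

    Quantile thresholds follow the stable-gene selection rule (per-patient
    median above its 97.5% quantile, raw MAD below its 2.5% quantile); the
    screen tiers are a strict FDR of 0.05 on the most-variant genes and a
    liberal FDR of 0.2 on the full gene set.
    """

    mad_quantile: float = 0.025
    median_quantile: float = 0.975
    top_variant_fraction: float = 0.10
    fdr_strict: float = 0.05
    fdr_liberal: float = 0.20
    bonferroni_alpha: float = 0.05
    tost_alpha: float = 0.05
    #: equivalence margin in pooled-SD units (the study reports no margin)
    tost_margin_sd: float = 1.0
    #: dynamics-class threshold in z-units
    dynamics_tau: float = 0.5
    cluster_k: int = 2
    linkage_method: str = "ward"
    correlation: str = "pearson"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mad_quantile", "median_quantile", "fdr_strict",
                     "fdr_liberal", "bonferroni_alpha", "tost_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if not 0.0 < self.top_variant_fraction <= 1.0:
            raise ValueError("top_variant_fraction must lie in (0,1]")
        if self.cluster_k < 2:
            raise ValueError("cluster_k must be >= 2")
        if self.linkage_method not in VALID_LINKAGES:
            raise ValueError(f"linkage_method must be one of {VALID_LINKAGES}")
        if self.tost_margin_sd <= 0:
            raise ValueError("tost_margin_sd must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d or {})

    def hash(self) -> str:
        """Short stable digest of the configuration, used in output headers."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
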