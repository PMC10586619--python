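"""Run configuration with the pipeline's default thresholds."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Tunable parameters of the detection pipeline.

    Defaults follow the published protocol: 30-mers at minimum occurrence 1
    for the cross-species read screen, a 50% merged-k-mer read-similarity
    threshold, dust low-complexity cutoff 10, a 1 kb minimum scaffold length
    for candidate calling, and the Ma & Bennetzen molecular clock
    (1.3e-8 substitutions/site/year) for transfer dating.
    """

    k: int = 30
    min_kmer_occurrence: int = 1
    read_similarity_threshold: float = 0.5
    retention_mode: str = "per_read"  # per_read | per_pair
    dust_threshold: float = 10.0
    assembly_k: int = 55
    min_scaffold_length: int = 1000
    homolog_identity_min: float = 0.80
    homolog_coverage_min: float = 0.60
    cluster_identity_min: float = 0.80
    cluster_coverage_min: float = 0.80
    evalue_protein: float = 1e-5
    evalue_nucleotide: float = 1e-20
    clock_rate: float = 1.3e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")
        if not (0 < self.read_similarity_threshold <= 1):
            raise ValueError("read_similarity_threshold must be in (0, 1]")
        if not (0 <= self.dust_threshold <= 100):
            raise ValueError("dust_threshold must be in [0, 100]")
        if self.retention_mode not in {"per_read", "per_pair"}:
            raise ValueError("retention_mode must be per_read or per_pair")
        if self.min_kmer_occurrence < 1:
            raise ValueError("min_kmer_occurrence must be >= 1")
        for name in ("homolog_identity_min", "homolog_coverage_min",
                     "cluster_identity_min", "cluster_coverage_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.clock_rate <= 0:
            raise ValueError("clock_rate must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
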