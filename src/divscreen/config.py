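"""Run configuration for the screening pipeline.

Defaults follow the study design the package implements: SNPs are retained
per species when the minor allele frequency is at least 0.05, the
Phred-scaled site quality at least 30 and the read depth at least 100
(all thresholds inclusive); unigenes are called divergent at a mean
interspecific differentiation index D-bar >= 0.94; the Ka/Ks branch screen
uses an ingroup ratio >= 0.5 with both outgroup ratios < 0.5; predicted
coding sequences must encode at least 100 residues; the multi-SNP candidate
rule requires at least three highly differentiated SNPs in one unigene.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    maf_min: float = 0.05
    qual_min: float = 30.0
    depth_min: int = 100
    dbar_threshold: float = 0.94
    d_threshold: float = 0.94
    kaks_candidate_min: float = 0.5
    kaks_outgroup_max: float = 0.5
    min_orf_residues: int = 100
    min_snps_for_multi_snp_rule: int = 3
    rng_seed: int = 0
    # specificity to one species requires evaluable depth in the other
    # (the alternative -- no coverage requirement -- is selectable here)
    require_coverage_for_specificity: bool = True
    # oppositely fixed sites (MAF = 0 in both species) are admitted to the
    # D computation when both species pass depth/quality
    fixed_sites_callable: bool = True
    # ">= 100 residues" vs "> 100 residues" for ORF retention
    orf_min_inclusive: bool = True

    def __post_init__(self) -> None:
        numeric = (
            self.maf_min, self.qual_min, self.depth_min, self.dbar_threshold,
            self.d_threshold, self.kaks_candidate_min, self.kaks_outgroup_max,
            self.min_orf_residues, self.min_snps_for_multi_snp_rule,
        )
        if any(v < 0 for v in numeric):
            raise ValueError("all thresholds must be >= 0")
        if self.maf_min > 0.5:
            raise ValueError("maf_min cannot exceed 0.5")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
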