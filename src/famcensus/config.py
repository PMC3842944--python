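"""Configuration objects for every pipeline stage.

Each threshold that drives a biological decision is carried here with the
census defaults: candidate proteins must be longer than 200 aa, domain
matches need E < 1e-3, the ATPase-region profile score must reach 200 bits,
genomic hits within 15 kb are single-linkage clustered, tree sequences take
30 aa flanks, FoldIndex calls disorder below -0.2, and FPKM classes break at
5 and 200.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ScanConfig:
    """Thresholds for family-candidate calling.

    ``min_length_aa`` is a strict lower bound (a 200-residue protein is
    rejected); ``profile_bitscore_min`` is inclusive (a 200-bit score is
    kept).  ``domain_evalue_max`` is a strict upper bound on domain-match
    E-values.  ``flank_aa`` pads the extracted ATPase region on both sides.
    """

    min_length_aa: int = 200
    domain_evalue_max: float = 1e-3
    profile_bitscore_min: float = 200.0
    flank_aa: int = 30

    def __post_init__(self) -> None:
        if self.flank_aa < 0:
            raise ValueError("flank_aa must be >= 0")
        for name in ("min_length_aa", "domain_evalue_max", "profile_bitscore_min"):
            v = float(getattr(self, name))
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite")


@dataclass
class RecallConfig:
    """Parameters for homology-guided locus recovery.

    ``cluster_distance_bp`` is the single-linkage cutoff on the interval gap
    between genome hits (hits with gap <= cutoff merge; overlap counts as
    gap 0).  ``gap_metric`` may be ``"edge"`` (interval gap, default) or
    ``"midpoint"`` (distance between interval midpoints).
    """

    hit_evalue_max: float = 10.0
    cluster_distance_bp: int = 15_000
    gap_metric: str = "edge"
    strand_aware: bool = False
    annotation_overlap_rule: str = "any"
    region_padding_bp: int = 0
    max_rounds: int = 3

    def __post_init__(self) -> None:
        if self.cluster_distance_bp < 0:
            raise ValueError("cluster_distance_bp must be >= 0")
        if self.gap_metric not in ("edge", "midpoint"):
            raise ValueError("gap_metric must be 'edge' or 'midpoint'")


@dataclass
class DisorderConfig:
    """FoldIndex settings: odd sliding window, strict cutoff, minimum run."""

    window: int = 51
    cutoff: float = -0.2
    min_region_len: int = 30

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.window < 5:
            raise ValueError("window must be >= 5")
        if self.min_region_len < 1:
            raise ValueError("min_region_len must be >= 1")


@dataclass
class ExpressionConfig:
    """FPKM class boundaries (both inclusive on the upper edge) and the
    operational 'expressed' rule: >= ``expressed_min_fpkm`` in at least
    ``expressed_min_libraries`` libraries."""

    low_max: float = 5.0
    moderate_max: float = 200.0
    expressed_min_fpkm: float = 1.0
    expressed_min_libraries: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.low_max < self.moderate_max):
            raise ValueError("need 0 <= low_max < moderate_max")
        if self.expressed_min_libraries < 1:
            raise ValueError("expressed_min_libraries must be >= 1")


@dataclass
class ClassifyConfig:
    """Tree-rooting and census-statistics options."""

    rooting: str = "midpoint"  # or "outgroup"
    outgroup: str | None = None
    majority_vote: bool = False
    quartile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.rooting not in ("midpoint", "outgroup", "none"):
            raise ValueError("rooting must be midpoint, outgroup or none")
        if self.rooting == "outgroup" and not self.outgroup:
            raise ValueError("outgroup rooting requires an outgroup leaf id")


@dataclass
class PipelineConfig:
    """Top-level config embedding every stage's settings."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    recall: RecallConfig = field(default_factory=RecallConfig)
    disorder: DisorderConfig = field(default_factory=DisorderConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    included_genomes: list[str] = field(default_factory=list)
    output_dir: str = "famcensus_out"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        for name, sub in (
            ("scan", ScanConfig),
            ("recall", RecallConfig),
            ("disorder", DisorderConfig),
            ("expression", ExpressionConfig),
            ("classify", ClassifyConfig),
        ):
            if name in kw and isinstance(kw[name], dict):
                kw[name] = sub(**kw[name])
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """Stable hash of the config contents, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
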