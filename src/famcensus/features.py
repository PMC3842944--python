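"""Intrinsic-disorder profiling and domain-architecture summaries.

Disorder is scored with the FoldIndex statistic: in a sliding window the
mean Kyte-Doolittle hydropathy (rescaled to [0, 1] as (kd + 4.5) / 9) is
balanced against the mean net charge,

    score = 2.785 * <H> - |<R>| - 1.151 .

Windows dominated by charged, low-hydropathy residues score negative;
values below the cutoff (-0.2) predict intrinsic disorder.  Maximal runs
of sub-cutoff positions longer than a minimum length are called disordered
regions.  The architecture summary merges the ATPase span, accessory
domains (BROMO, QLQ, HSA, ...) and disordered regions into one
coordinate-sorted track and flags proteins whose only domains are the two
core ATPase-region domains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from famcensus.config import DisorderConfig
from famcensus.scan import CORE_DOMAINS, DomainHit, ProteinRecord, default_atpase_span

logger = logging.getLogger(__name__)

# net charge at neutral pH: Asp/Glu negative, Lys/Arg positive, His neutral
CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}

FOLDINDEX_H_COEF = 2.785
FOLDINDEX_OFFSET = 1.151


@dataclass
class DisorderProfile:
    protein_id: str
    window: int
    scores: np.ndarray  # one score per center position of a full window
    first_center: int  # 1-based residue position of scores[0]
    regions: list[tuple[int, int]] = field(default_factory=list)
    cutoff: float = -0.2


def _residue_arrays(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    seq = sequence.upper()
    unknown = sorted(set(seq) - set(KYTE_DOOLITTLE))
    if unknown:
        logger.info("residues without hydropathy value treated as neutral: %s", unknown)
    hyd = np.array([(KYTE_DOOLITTLE.get(a, 0.0) + 4.5) / 9.0 for a in seq])
    chg = np.array([CHARGE.get(a, 0.0) for a in seq])
    return hyd, chg


def foldindex_score(sequence: str, window: int = 51) -> np.ndarray:
    """Per-position FoldIndex scores for every full window.

    Returns one score per center position; a sequence shorter than the
    window yields a single whole-sequence score.  ``window`` must be odd
    and >= 5.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 5:
        raise ValueError("window must be >= 5")
    if not sequence:
        raise ValueError("empty sequence")
    hyd, chg = _residue_arrays(sequence)
    n = len(sequence)
    if n < window:
        h = hyd.mean()
        r = chg.mean()
        return np.array([FOLDINDEX_H_COEF * h - abs(r) - FOLDINDEX_OFFSET])
    kernel = np.ones(window) / window
    mean_h = np.convolve(hyd, kernel, mode="valid")
    mean_r = np.convolve(chg, kernel, mode="valid")
    return FOLDINDEX_H_COEF * mean_h - np.abs(mean_r) - FOLDINDEX_OFFSET


def call_disordered_regions(
    scores: Sequence[float],
    cutoff: float = -0.2,
    min_region_len: int = 1,
    first_center: int = 1,
) -> list[tuple[int, int]]:
    """Maximal runs of positions with score strictly below the cutoff.

    A score exactly at the cutoff counts as ordered.  Runs shorter than
    ``min_region_len`` are discarded.  ``first_center`` is the 1-based
    residue position of ``scores[0]``; returned intervals are in residue
    coordinates of the window centers.
    """
    arr = np.asarray(scores, dtype=float)
    below = arr < cutoff
    regions: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_region_len:
                regions.append((first_center + start, first_center + i - 1))
            start = None
    if start is not None and len(below) - start >= min_region_len:
        regions.append((first_center + start, first_center + len(below) - 1))
    return regions


def disorder_profile(
    protein_id: str, sequence: str, cfg: DisorderConfig | None = None
) -> DisorderProfile:
    """Score a protein and call its disordered regions in one step."""
    cfg = cfg or DisorderConfig()
    scores = foldindex_score(sequence, cfg.window)
    first_center = cfg.window // 2 + 1 if len(sequence) >= cfg.window else 1
    regions = call_disordered_regions(
        scores, cfg.cutoff, cfg.min_region_len, first_center
    )
    return DisorderProfile(
        protein_id=protein_id,
        window=cfg.window,
        scores=scores,
        first_center=first_center,
        regions=regions,
        cutoff=cfg.cutoff,
    )


@dataclass
class TrackElement:
    name: str
    start: int
    end: int
    kind: str  # "atpase" | "accessory" | "disorder"


@dataclass
class ArchitectureSummary:
    protein_id: str
    elements: list[TrackElement]
    has_accessory_domains: bool

    @property
    def accessory_domains(self) -> list[TrackElement]:
        return [e for e in self.elements if e.kind == "accessory"]


def summarize_architecture(
    protein: ProteinRecord,
    domain_hits: Iterable[DomainHit],
    profile: DisorderProfile | None = None,
) -> ArchitectureSummary:
    """Merge ATPase span, accessory domains and disorder into one track.

    The ATPase span is the union of the best SNF2_N and Helicase_C hit
    intervals when both are present; any other domain is accessory.  A
    protein with only the two core domains is flagged as having no
    accessory domains.
    """
    hits = [h for h in domain_hits if h.protein_id == protein.id]
    core = {name: [h for h in hits if h.domain_name == name] for name in CORE_DOMAINS}
    elements: list[TrackElement] = []
    if all(core.values()):
        span = default_atpase_span(core["SNF2_N"], core["Helicase_C"])
        elements.append(TrackElement("ATPase_region", span[0], span[1], "atpase"))
    accessory = [h for h in hits if h.domain_name not in CORE_DOMAINS]
    for h in accessory:
        if h.ali_end > protein.length:
            raise ValueError(f"domain {h.domain_name} outside protein bounds")
        elements.append(TrackElement(h.domain_name, h.ali_start, h.ali_end, "accessory"))
    if profile is not None:
        for s, e in profile.regions:
            elements.append(TrackElement("disordered", s, e, "disorder"))
    elements.sort(key=lambda e: (e.start, e.end, e.kind))
    return ArchitectureSummary(
        protein_id=protein.id,
        elements=elements,
        has_accessory_domains=bool(accessory),
    )
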