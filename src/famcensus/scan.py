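"""Family-candidate identification in predicted proteomes.

A protein is called a family candidate when it passes three filters in
conjunction: it is longer than the fragment cutoff (200 aa by default, so
that partial gene predictions shorter than the ~400 aa ATPase region are
excluded), it carries at least one SNF2_N and at least one Helicase_C
domain match below the E-value threshold, and its ATPase-region profile
bitscore reaches the score threshold (200 bits by default).  The module
also curates seed sets for profile construction and extracts the ATPase
region with flanking residues for downstream alignment and tree building.

Profile scoring itself (HMM build + search) is delegated to an external
engine producing a per-protein bitscore table; this module implements every
decision rule around those scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from famcensus.config import ScanConfig

logger = logging.getLogger(__name__)

#: Domain names that define the ATPase region; anything else is accessory.
CORE_DOMAINS = ("SNF2_N", "Helicase_C")

#: Description keywords that disqualify a protein from the seed set.
SEED_EXCLUDE_KEYWORDS = ("putative", "uncharacterized", "predicted")

# IUPAC amino-acid one-letter codes, X/B/Z/U/O ambiguity codes permitted.
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZUO*")


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein with its locus grouping key."""

    id: str
    sequence: str
    species: str = ""
    gene_id: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id}: non-amino-acid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """A profile-search domain match, 1-based inclusive coordinates."""

    protein_id: str
    domain_name: str
    ali_start: int
    ali_end: int
    e_value: float
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.ali_start <= self.ali_end):
            raise ValueError(
                f"hit on {self.protein_id}: invalid coordinates "
                f"[{self.ali_start}, {self.ali_end}]"
            )
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass
class Snf2Candidate:
    """A protein retained by the family filter, with its evidence."""

    protein: ProteinRecord
    snf2n_hits: list[DomainHit] = field(default_factory=list)
    helicase_c_hits: list[DomainHit] = field(default_factory=list)
    atpase_bitscore: float = 0.0
    atpase_span: tuple[int, int] = (0, 0)


def _best_hit(hits: Sequence[DomainHit]) -> DomainHit:
    # lowest E-value; ties by highest bitscore, then leftmost start
    return min(hits, key=lambda h: (h.e_value, -h.bitscore, h.ali_start))


def default_atpase_span(
    snf2n_hits: Sequence[DomainHit], helicase_c_hits: Sequence[DomainHit]
) -> tuple[int, int]:
    """Span covering the best SNF2_N and best Helicase_C hit intervals.

    Used when no engine-reported envelope is available: the union of the two
    best hits approximates the motif Q-N span of the ATPase region.
    """
    a = _best_hit(snf2n_hits)
    b = _best_hit(helicase_c_hits)
    return (min(a.ali_start, b.ali_start), max(a.ali_end, b.ali_end))


def filter_candidates(
    proteome: Iterable[ProteinRecord],
    hits: Iterable[DomainHit],
    scores: Mapping[str, float],
    cfg: ScanConfig | None = None,
) -> list[Snf2Candidate]:
    """Apply the three-part family filter to a proteome.

    Parameters
    ----------
    proteome
        Protein records to screen.
    hits
        Domain matches; every hit must reference a protein in ``proteome``.
    scores
        Per-protein ATPase-region profile bitscores.  A protein without a
        score row is treated as score 0 (with a warning), so it cannot pass
        the bitscore filter.
    cfg
        Thresholds; defaults to the census values (length > 200 aa,
        E < 1e-3, bitscore >= 200).

    Returns
    -------
    list of Snf2Candidate, sorted by (species, id).
    """
    cfg = cfg or ScanConfig()
    prots = list(proteome)
    by_id = {p.id: p for p in prots}
    if len(by_id) < len(prots):
        raise ValueError("duplicate protein ids in proteome")

    domain_hits: dict[str, dict[str, list[DomainHit]]] = {}
    for h in hits:
        if h.protein_id not in by_id:
            raise KeyError(f"domain hit references unknown protein {h.protein_id!r}")
        if h.ali_end > by_id[h.protein_id].length:
            raise ValueError(
                f"hit on {h.protein_id} extends past protein end "
                f"({h.ali_end} > {by_id[h.protein_id].length})"
            )
        domain_hits.setdefault(h.protein_id, {}).setdefault(h.domain_name, []).append(h)

    kept: list[Snf2Candidate] = []
    for pid, prot in by_id.items():
        if prot.length <= cfg.min_length_aa:
            continue
        perdom = domain_hits.get(pid, {})
        snf2n = [h for h in perdom.get("SNF2_N", []) if h.e_value < cfg.domain_evalue_max]
        helc = [
            h for h in perdom.get("Helicase_C", []) if h.e_value < cfg.domain_evalue_max
        ]
        if not snf2n or not helc:
            continue
        if pid not in scores:
            logger.warning("no profile score for %s; treating as 0", pid)
        score = float(scores.get(pid, 0.0))
        if score < cfg.profile_bitscore_min:
            continue
        kept.append(
            Snf2Candidate(
                protein=prot,
                snf2n_hits=sorted(snf2n, key=lambda h: h.ali_start),
                helicase_c_hits=sorted(helc, key=lambda h: h.ali_start),
                atpase_bitscore=score,
                atpase_span=default_atpase_span(snf2n, helc),
            )
        )
    kept.sort(key=lambda c: (c.protein.species, c.protein.id))
    return kept


def collapse_to_loci(candidates: Iterable[Snf2Candidate]) -> list[Snf2Candidate]:
    """Keep one representative isoform per gene locus.

    Family counts are per locus, not per splice form: for each ``gene_id``
    the longest protein is kept, ties broken lexicographically by id.
    Candidates with an empty ``gene_id`` are treated as singleton loci.
    """
    best: dict[str, Snf2Candidate] = {}
    for c in candidates:
        key = c.protein.gene_id or c.protein.id
        cur = best.get(key)
        if cur is None or (-c.protein.length, c.protein.id) < (
            -cur.protein.length,
            cur.protein.id,
        ):
            best[key] = c
    out = list(best.values())
    out.sort(key=lambda c: (c.protein.species, c.protein.id))
    return out


def curate_seed_set(
    records: Iterable[ProteinRecord], hits: Iterable[DomainHit]
) -> list[ProteinRecord]:
    """Select seed sequences for building the ATPase-region profile.

    Retained iff length >= 200 aa, the description contains none of the
    disqualifying keywords ("putative", "uncharacterized", "predicted";
    case-insensitive substring match), and both core domains are present.
    Note the boundary differs from the candidate filter: a 200 aa protein
    is a valid seed but not a valid candidate.
    """
    have: dict[str, set[str]] = {}
    for h in hits:
        have.setdefault(h.protein_id, set()).add(h.domain_name)
    out = []
    for r in records:
        if r.length < 200:
            continue
        desc = r.description.lower()
        if any(k in desc for k in SEED_EXCLUDE_KEYWORDS):
            continue
        if not set(CORE_DOMAINS) <= have.get(r.id, set()):
            continue
        out.append(r)
    return out


def extract_atpase_region(
    candidate: Snf2Candidate, cfg: ScanConfig | None = None
) -> str:
    """Extract the ATPase-region subsequence with flanking residues.

    Returns ``sequence[max(1, start - flank) .. min(length, end + flank)]``
    in 1-based inclusive coordinates.  The flanks compensate for inaccuracy
    in domain-boundary prediction before alignment.
    """
    cfg = cfg or ScanConfig()
    start, end = candidate.atpase_span
    if start < 1 or end < start:
        raise ValueError(f"empty or invalid ATPase span {candidate.atpase_span}")
    n = candidate.protein.length
    if end > n:
        raise ValueError("ATPase span outside protein bounds")
    lo = max(1, start - cfg.flank_aa)
    hi = min(n, end + cfg.flank_aa)
    return candidate.protein.sequence[lo - 1 : hi]
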