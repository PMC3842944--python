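"""Homology-guided recovery of unannotated family loci.

Protein-vs-genome alignment hits (tblastn-style, pre-filtered to E < 10)
are clustered into candidate gene regions by single linkage: two hits on
the same target sequence join when the gap between their intervals is at
most the distance cutoff (15 kb by default; overlapping hits have gap 0).
Clusters become padded regions handed to an external gene predictor, and
recovered loci are reconciled against an existing annotation to separate
already-annotated genes from newly found ones.

Single-linkage on intervals sorted by start reduces to a linear sweep:
a cluster closes when the next start exceeds the running maximum end by
more than the cutoff.  This is exactly the connected components of the
pairwise gap graph because interval adjacency along the sorted order
dominates all other pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from famcensus.config import RecallConfig


@dataclass(frozen=True)
class GenomicHit:
    """A protein-to-genome alignment hit, coordinates normalized.

    ``target_start <= target_end`` always; a minus-strand alignment is
    recorded via ``strand`` with coordinates already swapped.
    """

    query_protein_id: str
    target_seq_id: str
    target_start: int
    target_end: int
    strand: str = "+"
    e_value: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.target_start < 1 or self.target_end < 1:
            raise ValueError("coordinates must be positive (1-based)")
        if self.target_start > self.target_end:
            raise ValueError(
                "unnormalized hit: target_start > target_end "
                f"({self.target_start} > {self.target_end}); swap and set strand"
            )
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass
class LocusCluster:
    """A single-linkage cluster of genome hits defining a candidate locus."""

    target_seq_id: str
    span: tuple[int, int]
    member_hits: list[GenomicHit] = field(default_factory=list)

    @property
    def n_distinct_queries(self) -> int:
        return len({h.query_protein_id for h in self.member_hits})


def interval_gap(a: GenomicHit, b: GenomicHit) -> int:
    """Gap in bp between two hit intervals; 0 when they overlap or abut."""
    return max(0, max(a.target_start, b.target_start) - min(a.target_end, b.target_end) - 1)


def _pair_distance(a: GenomicHit, b: GenomicHit, metric: str) -> float:
    if metric == "edge":
        return interval_gap(a, b)
    mid_a = (a.target_start + a.target_end) / 2
    mid_b = (b.target_start + b.target_end) / 2
    return abs(mid_a - mid_b)


def cluster_hits(
    hits: Iterable[GenomicHit], cfg: RecallConfig | None = None
) -> list[LocusCluster]:
    """Single-linkage clustering of genome hits into candidate loci.

    Clusters are the connected components of the graph on hits sharing a
    target sequence (and strand, if ``cfg.strand_aware``), with an edge
    whenever the pair distance is <= ``cfg.cluster_distance_bp``.  Output
    is sorted by (target_seq_id, span start).
    """
    cfg = cfg or RecallConfig()
    groups: dict[tuple, list[GenomicHit]] = {}
    for h in hits:
        key = (h.target_seq_id, h.strand) if cfg.strand_aware else (h.target_seq_id,)
        groups.setdefault(key, []).append(h)

    clusters: list[LocusCluster] = []
    for key, members in groups.items():
        members.sort(key=lambda h: (h.target_start, h.target_end))
        if cfg.gap_metric == "edge":
            clusters.extend(_sweep_edge(members, cfg.cluster_distance_bp))
        else:
            clusters.extend(_components_midpoint(members, cfg.cluster_distance_bp))
    clusters.sort(key=lambda c: (c.target_seq_id, c.span[0]))
    return clusters


def _make_cluster(members: Sequence[GenomicHit]) -> LocusCluster:
    return LocusCluster(
        target_seq_id=members[0].target_seq_id,
        span=(min(h.target_start for h in members), max(h.target_end for h in members)),
        member_hits=list(members),
    )


def _sweep_edge(sorted_hits: Sequence[GenomicHit], cutoff: int) -> list[LocusCluster]:
    out = []
    cur: list[GenomicHit] = []
    max_end = 0
    for h in sorted_hits:
        if cur and h.target_start - max_end - 1 > cutoff:
            out.append(_make_cluster(cur))
            cur = []
        cur.append(h)
        max_end = max(max_end, h.target_end)
    if cur:
        out.append(_make_cluster(cur))
    return out


def _components_midpoint(
    sorted_hits: Sequence[GenomicHit], cutoff: int
) -> list[LocusCluster]:
    # midpoints are sorted-order monotone only per start, so sort by midpoint
    hs = sorted(sorted_hits, key=lambda h: (h.target_start + h.target_end) / 2)
    out = []
    cur: list[GenomicHit] = []
    last_mid = None
    for h in hs:
        mid = (h.target_start + h.target_end) / 2
        if cur and mid - last_mid > cutoff:
            out.append(_make_cluster(cur))
            cur = []
        cur.append(h)
        last_mid = mid
    if cur:
        out.append(_make_cluster(cur))
    return out


def emit_regions(
    clusters: Iterable[LocusCluster], padding_bp: int = 0
) -> list[dict]:
    """Turn clusters into GFF3-style region records for a gene predictor.

    Each cluster yields one ``region`` record with the span padded by
    ``padding_bp`` on both sides and clamped to start >= 1; attributes
    carry the member query-protein ids.
    """
    regions = []
    for i, c in enumerate(clusters, start=1):
        start = max(1, c.span[0] - padding_bp)
        end = c.span[1] + padding_bp
        queries = sorted({h.query_protein_id for h in c.member_hits})
        regions.append(
            {
                "seqid": c.target_seq_id,
                "source": "famcensus",
                "type": "region",
                "start": start,
                "end": end,
                "score": ".",
                "strand": ".",
                "phase": ".",
                "attributes": {
                    "ID": f"locus_region_{i}",
                    "queries": ",".join(queries),
                    "n_hits": str(len(c.member_hits)),
                },
            }
        )
    return regions


@dataclass
class AnnotationPartition:
    """Three-way split of recalled loci against an existing annotation."""

    annotated_recovered: list[LocusCluster] = field(default_factory=list)
    unannotated_new: list[LocusCluster] = field(default_factory=list)
    annotation_only: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "annotated_recovered": len(self.annotated_recovered),
            "unannotated_new": len(self.unannotated_new),
            "annotation_only": len(self.annotation_only),
        }


def reconcile_with_annotation(
    clusters: Iterable[LocusCluster],
    annotation: Iterable[Mapping],
    family_gene_ids: Iterable[str],
) -> AnnotationPartition:
    """Partition recalled loci against an annotation's family genes.

    A cluster overlapping (>= 1 bp, any strand) an annotated family gene is
    ``annotated_recovered``; otherwise it is ``unannotated_new``.  Family
    genes no cluster touches are ``annotation_only``.

    Parameters
    ----------
    annotation
        Gene records as mappings with at least ``gene_id``, ``seqid``,
        ``start`` and ``end`` (1-based inclusive, same assembly namespace
        as the clusters).
    family_gene_ids
        Ids of the annotation genes that belong to the family under study.
    """
    fam = set(family_gene_ids)
    genes: dict[str, tuple[str, int, int]] = {}
    for g in annotation:
        gid = g["gene_id"]
        if gid in genes:
            raise ValueError(f"duplicate gene id in annotation: {gid}")
        genes[gid] = (g["seqid"], int(g["start"]), int(g["end"]))

    fam_genes = {gid: coords for gid, coords in genes.items() if gid in fam}
    part = AnnotationPartition()
    hit_gene_ids: set[str] = set()
    for c in clusters:
        overlapping = [
            gid
            for gid, (seqid, s, e) in fam_genes.items()
            if seqid == c.target_seq_id and s <= c.span[1] and e >= c.span[0]
        ]
        if overlapping:
            part.annotated_recovered.append(c)
            hit_gene_ids.update(overlapping)
        else:
            part.unannotated_new.append(c)
    part.annotation_only = sorted(set(fam_genes) - hit_gene_ids)
    return part
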