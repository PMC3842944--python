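"""Single-linkage locus clustering against a brute-force union-find oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famcensus.config import RecallConfig
from famcensus.recall import (
    GenomicHit,
    cluster_hits,
    emit_regions,
    interval_gap,
    reconcile_with_annotation,
)
from famcensus.simulate import SimGenomeSpec, gen_annotation, gen_genome_hits

from oracles import brute_force_cluster_count


def _hit(start, end, seqid="chr1", query="q1"):
    return GenomicHit(query, seqid, start, end)


def random_hits(rng, n, n_seqs=2, coord_max=200_000):
    hits = []
    for _ in range(n):
        s = int(rng.integers(1, coord_max))
        hits.append(
            _hit(s, s + int(rng.integers(0, 3_000)),
                 seqid=f"chr{int(rng.integers(1, n_seqs + 1))}")
        )
    return hits


class TestClusterHits:
    def test_gap_below_cutoff_merges(self):
        # interval gap 14899 <= 15000: one locus
        clusters = cluster_hits([_hit(100, 200), _hit(15_100, 15_200)])
        assert len(clusters) == 1
        assert clusters[0].span == (100, 15_200)

    def test_gap_above_cutoff_splits(self):
        # interval gap 15099 > 15000: two loci
        clusters = cluster_hits([_hit(100, 200), _hit(15_300, 15_400)])
        assert len(clusters) == 2

    def test_exact_boundary_gap(self):
        # gap == cutoff merges; cutoff + 1 splits
        at = cluster_hits([_hit(100, 200), _hit(15_201, 15_301)])
        above = cluster_hits([_hit(100, 200), _hit(15_202, 15_302)])
        assert interval_gap(_hit(100, 200), _hit(15_201, 15_301)) == 15_000
        assert len(at) == 1
        assert len(above) == 2

    def test_single_hit_cluster_span(self):
        (c,) = cluster_hits([_hit(500, 900)])
        assert c.span == (500, 900)
        assert c.n_distinct_queries == 1

    def test_overlapping_hits_always_co_cluster(self):
        (c,) = cluster_hits(
            [_hit(100, 5_000), _hit(4_000, 9_000)], RecallConfig(cluster_distance_bp=0)
        )
        assert c.span == (100, 9_000)

    def test_different_sequences_never_merge(self):
        clusters = cluster_hits([_hit(100, 200, "chr1"), _hit(100, 200, "chr2")])
        assert len(clusters) == 2

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_union_find(self, seed):
        rng = np.random.default_rng(seed)
        hits = random_hits(rng, int(rng.integers(2, 200)))
        cutoff = int(rng.choice([0, 1_000, 14_999, 15_000, 15_001, 50_000]))
        got = cluster_hits(hits, RecallConfig(cluster_distance_bp=cutoff))
        assert len(got) == brute_force_cluster_count(hits, cutoff)
        # each hit appears in exactly one cluster
        assert sum(len(c.member_hits) for c in got) == len(hits)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        hits = random_hits(rng, 40)
        counts = [
            len(cluster_hits(hits, RecallConfig(cluster_distance_bp=c)))
            for c in (0, 5_000, 15_000, 40_000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_idempotent_on_cluster_spans(self):
        rng = np.random.default_rng(7)
        hits = random_hits(rng, 60)
        first = cluster_hits(hits)
        spans = [
            _hit(c.span[0], c.span[1], c.target_seq_id) for c in first
        ]
        second = cluster_hits(spans)
        assert [(c.target_seq_id, c.span) for c in second] == [
            (c.target_seq_id, c.span) for c in first
        ]


class TestPlantedLoci:
    def test_gaps_straddling_cutoff(self):
        wide = gen_genome_hits(
            SimGenomeSpec(n_loci=3, inter_locus_gaps=(20_000, 20_000), seed=1)
        )
        narrow = gen_genome_hits(
            SimGenomeSpec(n_loci=3, inter_locus_gaps=(10_000, 10_000), seed=1)
        )
        assert len(cluster_hits(wide.hits)) == wide.expected_cluster_count(15_000) == 3
        assert len(cluster_hits(narrow.hits)) == narrow.expected_cluster_count(15_000) == 1

    def test_single_locus_any_cutoff(self):
        sim = gen_genome_hits(SimGenomeSpec(n_loci=1, inter_locus_gaps=(), seed=3))
        for cutoff in (0, 15_000, 10**6):
            assert len(cluster_hits(sim.hits, RecallConfig(cluster_distance_bp=cutoff))) == 1

    def test_overlapping_planted_loci_rejected(self):
        with pytest.raises(ValueError):
            SimGenomeSpec(n_loci=2, inter_locus_gaps=(-5,))


class TestEmitRegions:
    def test_padding_arithmetic(self):
        (c,) = cluster_hits([_hit(1_000, 5_000)])
        (r,) = emit_regions([c], padding_bp=500)
        assert (r["start"], r["end"]) == (500, 5_500)

    def test_zero_padding_identity(self):
        (c,) = cluster_hits([_hit(1_000, 5_000)])
        (r,) = emit_regions([c], padding_bp=0)
        assert (r["start"], r["end"]) == (1_000, 5_000)

    def test_clamped_at_origin(self):
        (c,) = cluster_hits([_hit(100, 900)])
        (r,) = emit_regions([c], padding_bp=500)
        assert (r["start"], r["end"]) == (1, 1_400)
        assert r["type"] == "region"


class TestAnnotationReconciliation:
    def test_mixed_partition(self):
        clusters = cluster_hits([_hit(100, 2_000), _hit(50_000, 52_000)])
        genes = [{"gene_id": "g1", "seqid": "chr1", "start": 1_500, "end": 4_000}]
        part = reconcile_with_annotation(clusters, genes, ["g1"])
        assert part.counts == {
            "annotated_recovered": 1,
            "unannotated_new": 1,
            "annotation_only": 0,
        }

    def test_no_clusters_all_annotation_only(self):
        genes = [
            {"gene_id": f"g{i}", "seqid": "chr1", "start": i * 100, "end": i * 100 + 50}
            for i in range(1, 4)
        ]
        part = reconcile_with_annotation([], genes, ["g1", "g2", "g3"])
        assert part.counts == {
            "annotated_recovered": 0,
            "unannotated_new": 0,
            "annotation_only": 3,
        }

    def test_planted_loci_partition(self):
        sim = gen_genome_hits(
            SimGenomeSpec(
                n_loci=4, inter_locus_gaps=(20_000, 20_000, 20_000), seed=5
            )
        )
        genes, fam = gen_annotation(sim, [0, 2])
        part = reconcile_with_annotation(cluster_hits(sim.hits), genes, fam)
        assert part.counts == {
            "annotated_recovered": 2,
            "unannotated_new": 2,
            "annotation_only": 0,
        }

    def test_duplicate_annotation_ids_rejected(self):
        genes = [
            {"gene_id": "g1", "seqid": "chr1", "start": 1, "end": 10},
            {"gene_id": "g1", "seqid": "chr1", "start": 20, "end": 30},
        ]
        with pytest.raises(ValueError):
            reconcile_with_annotation([], genes, ["g1"])


def test_unnormalized_coordinates_rejected():
    with pytest.raises(ValueError):
        GenomicHit("q", "chr1", 500, 100)
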