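"""Candidate calling: filter conjunction, locus collapse, seed curation."""

import numpy as np
import pytest

from famcensus.config import ScanConfig
from famcensus.scan import (
    DomainHit,
    ProteinRecord,
    Snf2Candidate,
    collapse_to_loci,
    curate_seed_set,
    extract_atpase_region,
    filter_candidates,
)


def _prot(pid, length, species="sp", gene_id="", desc=""):
    rng = np.random.default_rng(abs(hash(pid)) % 2**31)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    return ProteinRecord(pid, seq, species, gene_id or pid, desc)


def _hits(pid, snf_e=1e-5, hel_e=1e-4, length=900):
    return [
        DomainHit(pid, "SNF2_N", 50, 250, snf_e, 150.0),
        DomainHit(pid, "Helicase_C", 300, min(420, length), hel_e, 90.0),
    ]


class TestFilterCandidates:
    def test_full_evidence_retained(self):
        p = _prot("p1", 900)
        out = filter_candidates([p], _hits("p1"), {"p1": 350.0})
        assert [c.protein.id for c in out] == ["p1"]
        assert out[0].atpase_span == (50, 420)

    def test_short_protein_rejected_despite_domains_and_score(self):
        p = _prot("p1", 150)
        hits = [
            DomainHit("p1", "SNF2_N", 1, 70, 1e-9, 60.0),
            DomainHit("p1", "Helicase_C", 80, 140, 1e-9, 50.0),
        ]
        assert filter_candidates([p], hits, {"p1": 400.0}) == []

    def test_filter_is_pure_conjunction(self):
        """Fixing any single failing condition admits the record."""
        base_cfg = ScanConfig()
        # fails only on length
        short = _prot("s", 150)
        short_hits = [
            DomainHit("s", "SNF2_N", 1, 70, 1e-9, 60.0),
            DomainHit("s", "Helicase_C", 80, 140, 1e-9, 50.0),
        ]
        assert filter_candidates([short], short_hits, {"s": 300.0}, base_cfg) == []
        assert filter_candidates(
            [short], short_hits, {"s": 300.0}, ScanConfig(min_length_aa=100)
        )
        # fails only on missing Helicase_C
        single = _prot("d", 900)
        one_hit = [DomainHit("d", "SNF2_N", 50, 250, 1e-9, 150.0)]
        assert filter_candidates([single], one_hit, {"d": 300.0}, base_cfg) == []
        assert filter_candidates(
            [single], one_hit + [DomainHit("d", "Helicase_C", 300, 420, 1e-9, 90.0)],
            {"d": 300.0}, base_cfg,
        )
        # fails only on bitscore
        weak = _prot("w", 900)
        assert filter_candidates([weak], _hits("w"), {"w": 150.0}, base_cfg) == []
        assert filter_candidates([weak], _hits("w"), {"w": 250.0}, base_cfg)

    def test_evalue_threshold_is_strict(self):
        p = _prot("p1", 900)
        at = filter_candidates([p], _hits("p1", snf_e=1e-3), {"p1": 350.0})
        below = filter_candidates([p], _hits("p1", snf_e=9.9e-4), {"p1": 350.0})
        assert at == [] and len(below) == 1

    def test_planted_truth_recovered_exactly(self, small_proteome):
        out = filter_candidates(
            small_proteome.proteins, small_proteome.domain_hits, small_proteome.scores
        )
        assert {c.protein.id for c in out} == small_proteome.true_ids

    def test_order_invariance(self, small_proteome):
        rng = np.random.default_rng(0)
        prots = list(small_proteome.proteins)
        hits = list(small_proteome.domain_hits)
        rng.shuffle(prots)
        rng.shuffle(hits)
        out = filter_candidates(prots, hits, small_proteome.scores)
        assert {c.protein.id for c in out} == small_proteome.true_ids
        # output order is canonical regardless of input order
        assert [c.protein.id for c in out] == sorted(c.protein.id for c in out)

    def test_unknown_protein_in_hits_is_hard_error(self):
        p = _prot("p1", 900)
        with pytest.raises(KeyError):
            filter_candidates([p], _hits("ghost"), {"p1": 300.0})

    def test_missing_score_treated_as_zero_with_warning(self, caplog):
        p = _prot("p1", 900)
        with caplog.at_level("WARNING"):
            out = filter_candidates([p], _hits("p1"), {})
        assert out == []
        assert any("no profile score" in r.message for r in caplog.records)


class TestCollapseToLoci:
    def _cand(self, pid, length, gene_id):
        p = _prot(pid, length, gene_id=gene_id)
        return Snf2Candidate(protein=p, atpase_span=(1, length))

    def test_longest_isoform_wins(self):
        out = collapse_to_loci(
            [self._cand("g1.1", 800, "g1"), self._cand("g1.2", 750, "g1")]
        )
        assert [c.protein.id for c in out] == ["g1.1"]

    def test_distinct_genes_identity(self):
        cands = [self._cand(f"g{i}.1", 500, f"g{i}") for i in range(4)]
        assert len(collapse_to_loci(cands)) == 4

    def test_equal_length_tie_breaks_lexicographically(self):
        out = collapse_to_loci(
            [self._cand("g1.2", 600, "g1"), self._cand("g1.1", 600, "g1")]
        )
        assert [c.protein.id for c in out] == ["g1.1"]


class TestCurateSeedSet:
    def test_keyword_exclusion_case_insensitive(self):
        p = _prot("p1", 900, desc="Putative DNA helicase")
        assert curate_seed_set([p], _hits("p1")) == []

    def test_clean_description_with_both_domains_retained(self):
        p = _prot("p1", 900, desc="SNF2 ATPase BRAHMA")
        assert [r.id for r in curate_seed_set([p], _hits("p1"))] == ["p1"]

    def test_length_200_is_a_valid_seed(self):
        # seed curation keeps >= 200 aa, unlike the strict candidate filter
        p = _prot("p1", 200)
        hits = [
            DomainHit("p1", "SNF2_N", 1, 90, 1e-9, 60.0),
            DomainHit("p1", "Helicase_C", 100, 190, 1e-9, 50.0),
        ]
        assert len(curate_seed_set([p], hits)) == 1

    def test_enumerated_keyword_fraction(self):
        keywords = ["putative protein", "UNCHARACTERIZED", "predicted helicase"]
        records, hits = [], []
        for i in range(20):
            desc = keywords[i % 3] if i < 7 else "Snf2 ATPase"
            records.append(_prot(f"p{i}", 500, desc=desc))
            hits.extend(_hits(f"p{i}", length=500))
        assert len(curate_seed_set(records, hits)) == 13

    def test_single_domain_protein_excluded(self):
        p = _prot("p1", 900, desc="helicase")
        hits = [DomainHit("p1", "SNF2_N", 50, 250, 1e-9, 150.0)]
        assert curate_seed_set([p], hits) == []


class TestExtractAtpaseRegion:
    def _cand(self, length, span):
        p = _prot("p1", length)
        return Snf2Candidate(protein=p, atpase_span=span)

    def test_flank_arithmetic(self):
        region = extract_atpase_region(self._cand(600, (100, 500)))
        assert len(region) == 461  # residues 70..530
        assert region == self._cand(600, (100, 500)).protein.sequence[69:530]

    def test_clamped_at_n_terminus(self):
        region = extract_atpase_region(self._cand(600, (10, 500)))
        assert len(region) == 530  # residues 1..530

    def test_zero_flank_returns_exact_span(self):
        region = extract_atpase_region(
            self._cand(600, (100, 500)), ScanConfig(flank_aa=0)
        )
        assert len(region) == 401

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError):
            extract_atpase_region(self._cand(600, (0, 0)))
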