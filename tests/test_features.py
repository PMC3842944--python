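"""FoldIndex disorder scoring and architecture summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famcensus.config import DisorderConfig
from famcensus.features import (
    call_disordered_regions,
    disorder_profile,
    foldindex_score,
    summarize_architecture,
)
from famcensus.scan import DomainHit, ProteinRecord


class TestFoldIndexClosedForm:
    @pytest.mark.parametrize(
        "residue,expected",
        [
            ("G", 2.785 * ((-0.4 + 4.5) / 9) - 1.151),  # ~ +0.118, ordered
            ("E", 2.785 * ((-3.5 + 4.5) / 9) - 1.0 - 1.151),  # ~ -1.842
            ("I", 2.785 - 1.151),  # = 1.634
        ],
    )
    def test_homopolymer_matches_hand_computation(self, residue, expected):
        scores = foldindex_score(residue * 101, window=51)
        assert scores == pytest.approx(expected, abs=1e-6)

    def test_reference_values(self):
        assert foldindex_score("G" * 51, 51)[0] == pytest.approx(0.118, abs=5e-4)
        assert foldindex_score("E" * 51, 51)[0] == pytest.approx(-1.842, abs=5e-4)
        assert foldindex_score("I" * 51, 51)[0] == pytest.approx(1.634, abs=1e-6)

    def test_homopolymer_profile_is_constant(self):
        scores = foldindex_score("K" * 200, window=51)
        assert len(scores) == 150
        assert np.allclose(scores, scores[0])

    def test_short_sequence_gets_single_whole_sequence_score(self):
        scores = foldindex_score("GGGG" + "E" * 6, window=51)
        assert len(scores) == 1

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            foldindex_score("G" * 100, window=50)

    @given(st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_hydropathy_at_fixed_charge(self, n_ile, n_gly):
        # replacing G (scaled hydropathy 0.456) by I (1.0) at zero net
        # charge strictly increases the score
        window = 51
        n_ile2 = min(window, n_ile + n_gly + 1)
        seq1 = "I" * n_ile + "G" * (window - n_ile)
        seq2 = "I" * n_ile2 + "G" * (window - n_ile2)
        s1 = foldindex_score(seq1, window)[0]
        s2 = foldindex_score(seq2, window)[0]
        assert s2 > s1

    @given(st.integers(0, 25))
    @settings(max_examples=26, deadline=None, derandomize=True)
    def test_decreasing_in_net_charge_at_fixed_hydropathy(self, n_charged):
        # Q and E have equal Kyte-Doolittle hydropathy (-3.5) but only E is
        # charged, so swapping Q -> E changes |<R>| only
        window = 51
        seq1 = "E" * n_charged + "Q" * (window - n_charged)
        seq2 = "E" * (n_charged + 1) + "Q" * (window - n_charged - 1)
        assert foldindex_score(seq2, window)[0] < foldindex_score(seq1, window)[0]


class TestRegionCalling:
    def test_no_scores_below_cutoff_no_regions(self):
        assert call_disordered_regions([0.1, 0.0, -0.1], cutoff=-0.2) == []

    def test_long_run_called_once(self):
        scores = [0.3] * 10 + [-0.5] * 60 + [0.3] * 10
        regions = call_disordered_regions(scores, cutoff=-0.2, min_region_len=30)
        assert regions == [(11, 70)]

    def test_exact_cutoff_is_ordered(self):
        assert call_disordered_regions([-0.2] * 50, cutoff=-0.2) == []

    def test_short_runs_discarded(self):
        scores = [-0.5] * 10 + [0.5] * 10 + [-0.5] * 40
        regions = call_disordered_regions(scores, cutoff=-0.2, min_region_len=30)
        assert regions == [(21, 60)]

    def test_positions_in_at_most_one_region(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(-1, 1, size=500)
        regions = call_disordered_regions(scores, min_region_len=2)
        covered = []
        for s, e in regions:
            covered.extend(range(s, e + 1))
        assert len(covered) == len(set(covered))
        assert regions == sorted(regions)

    def test_two_disordered_blocks_with_ordered_spacer(self):
        """Two charged low-hydropathy stretches separated by an ordered
        spacer longer than the window give exactly two regions."""
        cfg = DisorderConfig(window=11, min_region_len=5)
        seq = "E" * 60 + "I" * 80 + "E" * 60
        prof = disorder_profile("p", seq, cfg)
        assert len(prof.regions) == 2
        (s1, e1), (s2, e2) = prof.regions
        assert e1 < s2


class TestArchitectureSummary:
    def _protein(self, length=800):
        rng = np.random.default_rng(5)
        return ProteinRecord(
            "p1", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
        )

    def _core(self):
        return [
            DomainHit("p1", "SNF2_N", 100, 300, 1e-9, 200.0),
            DomainHit("p1", "Helicase_C", 350, 480, 1e-9, 120.0),
        ]

    def test_core_domains_only_flags_no_accessory(self):
        summ = summarize_architecture(self._protein(), self._core())
        assert not summ.has_accessory_domains
        assert [e.name for e in summ.elements] == ["ATPase_region"]
        assert summ.elements[0].start == 100 and summ.elements[0].end == 480

    def test_accessory_domains_in_coordinate_order(self):
        hits = self._core() + [
            DomainHit("p1", "HSA", 600, 660, 1e-7, 40.0),
            DomainHit("p1", "BROMO", 10, 80, 1e-8, 50.0),
        ]
        summ = summarize_architecture(self._protein(), hits)
        assert summ.has_accessory_domains
        assert [e.name for e in summ.accessory_domains] == ["BROMO", "HSA"]

    def test_empty_domain_table_gives_disorder_only(self):
        prof = disorder_profile("p1", "E" * 200, DisorderConfig(window=11, min_region_len=5))
        prot = ProteinRecord("p1", "E" * 200)
        summ = summarize_architecture(prot, [], prof)
        assert [e.kind for e in summ.elements] == ["disorder"]
        assert not summ.has_accessory_domains
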