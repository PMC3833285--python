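"""In silico digestion, distribution diagrams, peaks, bands and concordance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from midsat.digest import (
    CutSet,
    FragmentDistribution,
    Peak,
    cross_enzyme_candidates,
    detect_peaks,
    digest_genome,
    find_sites,
    fragment_lengths,
    predict_visible_bands,
)
from midsat.errors import ValidationError
from midsat.genome_io import Genome
from midsat.synth import random_background

from conftest import naive_site_scan


class TestFindSites:
    @pytest.mark.parametrize(
        "seq,enzyme,expected",
        [
            ("ACCGGT", "HpaII", [2]),
            ("AAGATCAAGATCAA", "Kzo9I", [2, 8]),
            ("GGACCGGTCC", "AspS9I", [1, 6]),  # GGACC and GGTCC both match GGNCC
        ],
    )
    def test_documented_cuts(self, panel, seq, enzyme, expected):
        assert find_sites(seq, panel[enzyme]).cuts == expected

    def test_n_runs_produce_no_sites(self, panel):
        assert find_sites("CCNGG" * 10, panel["AspS9I"]).cuts == []

    def test_agrees_with_naive_window_scan(self, panel):
        for seed in range(20):
            seq = random_background(np.random.default_rng(seed), 5000)
            for enz in panel.values():
                assert find_sites(seq, enz).cuts == naive_site_scan(seq, enz)

    def test_overlapping_sites_each_cut(self, panel):
        # GTACGTAC: RsaI GTAC at 0 and 4 -> cuts 2 and 6
        assert find_sites("GTACGTAC", panel["RsaI"]).cuts == [2, 6]


class TestFragmentLengths:
    @pytest.mark.parametrize(
        "cuts,length,expected",
        [
            ([2, 8], 14, [2, 6, 6]),
            ([], 100, [100]),
            ([0, 50], 50, [50]),
        ],
    )
    def test_linear_molecule_model(self, cuts, length, expected):
        assert fragment_lengths(CutSet("s", cuts), length) == expected

    def test_cutset_requires_increasing_positions(self):
        with pytest.raises(ValidationError):
            CutSet("s", [5, 5])


class TestDigestGenome:
    def test_tandem_array_yields_monomer_fragments(self, panel):
        """10 exact copies of a 154 bp unit with one GATC: 9 interior fragments
        of 154 bp plus two terminal fragments summing to 154 bp."""
        rng = np.random.default_rng(3)
        unit = None
        while unit is None:
            cand = random_background(rng, 150)
            if "GATC" not in (cand + cand[:3]):
                unit = cand[:75] + "GATC" + cand[75:]
        g = Genome()
        g.add("s", unit * 10)
        dist = digest_genome(g, panel["Kzo9I"])
        assert dist.counts[154] == 9
        terminals = [L for L in dist.counts if L != 154]
        assert sum(terminals) == 154
        # independent oracle: python str.split on the concrete site
        frags = [len(f) + 0 for f in (unit * 10).split("GATC")]
        oracle = sorted(
            [frags[0]] + [f + 4 for f in frags[1:]]
        )  # re-attach GATC to the downstream fragment (cut offset 0)
        assert oracle == sorted(
            L for L in dist.counts for _ in range(dist.counts[L])
        )

    def test_siteless_enzyme_gives_one_fragment_per_scaffold(self, panel):
        g = Genome()
        g.add("a", "ATATATAT" * 10)
        g.add("b", "ATAT" * 5)
        dist = digest_genome(g, panel["HpaII"])
        assert dist.counts == {80: 1, 20: 1}

    def test_empty_genome_rejected(self, panel):
        with pytest.raises(ValidationError):
            digest_genome(Genome(), panel["HpaII"])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_mass_conservation(self, seed):
        """Sum of length x count equals genome length for every digestion."""
        from midsat.enzymes import load_enzyme_table

        panel = load_enzyme_table()
        g = Genome()
        g.add("s", random_background(np.random.default_rng(seed), 3000))
        for enz in (panel["Kzo9I"], panel["AspS9I"]):
            dist = digest_genome(g, enz)
            assert sum(L * c for L, c in dist.counts.items()) == g.total_length
            cuts = find_sites(g["s"], enz).cuts
            interior = [c for c in cuts if 0 < c < 3000]
            assert dist.n_fragments == len(interior) + 1


class TestDetectPeaks:
    def test_sharp_peak_called(self):
        counts = {154: 9000, 153: 400, 155: 380}
        counts.update({L: 50 for L in range(140, 170) if L not in counts})
        dist = FragmentDistribution(counts, "E", sum(L * c for L, c in counts.items()))
        peaks = detect_peaks(dist, min_count=100, window=5, min_prominence=5)
        assert [p.length for p in peaks] == [154]

    def test_flat_distribution_has_no_peaks(self):
        counts = {L: 500 for L in range(100, 200)}
        dist = FragmentDistribution(counts, "E", sum(L * c for L, c in counts.items()))
        assert detect_peaks(dist, min_count=100, window=5, min_prominence=5) == []

    def test_tie_broken_toward_smaller_length(self):
        counts = {100: 800, 103: 800}
        dist = FragmentDistribution(counts, "E", 1)
        peaks = detect_peaks(dist, min_count=100, window=5, min_prominence=0.1)
        assert [p.length for p in peaks] == [100]

    def test_window_validation(self):
        dist = FragmentDistribution({10: 10}, "E", 100)
        with pytest.raises(ValidationError):
            detect_peaks(dist, window=0)


class TestVisibleBands:
    def test_short_fragments_fall_below_detection(self):
        """Equal counts at 36 and 154 bp: only the longer band carries enough
        mass to be seen on the gel at a suitable threshold."""
        counts = {36: 5000, 154: 5000}
        total = 36 * 5000 + 154 * 5000
        dist = FragmentDistribution(counts, "E", total)
        threshold = (100 * 5000) / total  # between the two mass fractions
        assert predict_visible_bands(dist, threshold) == [154]

    def test_tiny_threshold_returns_all(self):
        dist = FragmentDistribution({36: 10, 154: 10}, "E", 36 * 10 + 154 * 10)
        assert predict_visible_bands(dist, 1e-9) == [36, 154]

    def test_single_fragment_always_visible(self):
        dist = FragmentDistribution({500: 1}, "E", 500)
        assert predict_visible_bands(dist, 0.999) == [500]

    def test_threshold_validation(self):
        dist = FragmentDistribution({10: 1}, "E", 10)
        with pytest.raises(ValidationError):
            predict_visible_bands(dist, 0.0)


class TestCrossEnzymeCandidates:
    def _peaks(self, lengths):
        return [Peak(L, 1000, 1000 * L, 10.0) for L in lengths]

    def test_three_enzyme_concordance(self):
        sets = {
            "HpaII": self._peaks([225]),
            "RsaI": self._peaks([225]),
            "FatI": self._peaks([226]),
        }
        assert cross_enzyme_candidates(sets, 5) == [
            (225, ["FatI", "HpaII", "RsaI"])
        ]

    def test_disjoint_peaks_give_no_candidates(self):
        sets = {"E1": self._peaks([154]), "E2": self._peaks([400])}
        assert cross_enzyme_candidates(sets, 5) == []

    def test_median_of_cluster_members(self):
        sets = {
            "E1": self._peaks([154]),
            "E2": self._peaks([154]),
            "E3": self._peaks([153]),
        }
        assert cross_enzyme_candidates(sets, 2) == [(154, ["E1", "E2", "E3"])]

    def test_requires_two_enzymes(self):
        with pytest.raises(ValidationError):
            cross_enzyme_candidates({"E1": self._peaks([100])}, 5)

    def test_same_enzyme_twice_is_not_support(self):
        sets = {"E1": self._peaks([154, 155]), "E2": self._peaks([400])}
        assert cross_enzyme_candidates(sets, 5) == []
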