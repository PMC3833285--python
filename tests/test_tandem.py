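"""Tandem-array scanning, census bookkeeping and pooled consensi."""

import numpy as np
import pytest

from midsat.errors import ValidationError
from midsat.genome_io import Genome
from midsat.synth import ArraySpec, SynthSpec, generate, random_background
from midsat.tandem import TandemArray, census, pool_consensus, scan_tandem_arrays


def _planted(seed, arrays, background=20_000):
    spec = SynthSpec(seed=seed, background_length=background, arrays=arrays)
    return generate(spec)


class TestScan:
    def test_single_planted_array_recovered(self):
        genome, truth = _planted(
            101, [ArraySpec(period=100, copies=20, substitution_rate=0.01)],
            background=4000,
        )
        arrays = scan_tandem_arrays(genome)
        assert len(arrays) == 1
        (arr,) = arrays
        assert abs(arr.period - 100) <= 1
        assert abs(arr.copy_number - 20) <= 1
        t = truth[0]
        assert abs(arr.start - t[1]) < 50 and abs(arr.end - t[2]) < 50

    def test_random_sequence_has_no_arrays(self):
        for seed in range(5):
            g = Genome()
            g.add("r", random_background(np.random.default_rng(seed), 50_000))
            assert scan_tandem_arrays(g) == []

    def test_two_arrays_two_periods(self):
        genome, _ = _planted(
            7,
            [
                ArraySpec(period=154, copies=12, substitution_rate=0.02),
                ArraySpec(period=225, copies=8, substitution_rate=0.0),
            ],
        )
        arrays = scan_tandem_arrays(genome)
        assert sorted(a.period for a in arrays) == [154, 225]

    def test_periods_stay_inside_configured_range(self):
        genome, _ = _planted(
            13,
            [
                ArraySpec(period=60, copies=30, substitution_rate=0.01),
                ArraySpec(period=225, copies=10, substitution_rate=0.01),
            ],
        )
        arrays = scan_tandem_arrays(genome, min_period=100, max_period=500)
        assert all(100 <= a.period <= 500 for a in arrays)
        assert not any(abs(a.period - 60) <= 2 for a in arrays)

    def test_no_overlapping_arrays_reported(self):
        genome, _ = _planted(
            21, [ArraySpec(period=80, copies=40, substitution_rate=0.0)],
            background=10_000,
        )
        arrays = scan_tandem_arrays(genome)
        arrays.sort(key=lambda a: a.start)
        for a, b in zip(arrays, arrays[1:]):
            assert a.end <= b.start or a.scaffold != b.scaffold

    def test_parameter_validation(self):
        g = Genome()
        g.add("s", "ACGT" * 100)
        with pytest.raises(ValidationError):
            scan_tandem_arrays(g, min_period=6, k=12)
        with pytest.raises(ValidationError):
            scan_tandem_arrays(g, min_period=100, max_period=50)

    def test_divergent_array_census_persists_digestion_peak_dies(self, panel):
        """High unit-to-unit divergence removes the digestion-diagram peak but
        the tandem census still records the family."""
        from midsat.digest import detect_peaks, digest_genome
        from midsat.synth import make_clean_unit

        rng = np.random.default_rng(55)
        unit = make_clean_unit(rng, 172, [("GTAC", 30)])
        low, _ = _planted(
            1, [ArraySpec(unit=unit, copies=40, substitution_rate=0.005)] * 3,
            background=60_000,
        )
        high, _ = _planted(
            2,
            [ArraySpec(unit=unit, copies=40, substitution_rate=0.10,
                       indel_rate=0.01)] * 3,
            background=60_000,
        )
        peak_kw = dict(min_count=40, window=5, min_prominence=5)
        low_peaks = detect_peaks(digest_genome(low, panel["RsaI"]), **peak_kw)
        high_peaks = detect_peaks(digest_genome(high, panel["RsaI"]), **peak_kw)
        assert any(abs(p.length - 172) <= 1 for p in low_peaks)
        assert not any(abs(p.length - 172) <= 3 for p in high_peaks)
        high_arrays = scan_tandem_arrays(high)
        assert sum(
            round(a.copy_number) for a in high_arrays if abs(a.period - 172) <= 3
        ) >= 90


class TestCensus:
    def _array(self, period, copies, scaffold="s", start=0):
        return TandemArray(scaffold, start, start + int(period * copies),
                           period, copies, 99.0, "A" * period, int(copies))

    def test_single_array(self):
        df = census([self._array(154, 6.0)])
        assert df.loc["154", "unit_count"] == 6
        assert df.loc["154", "cluster_count"] == 1

    def test_range_bin_pools_neighbouring_periods(self):
        arrays = [self._array(153, 4.0), self._array(154, 5.0)]
        df = census(arrays, bins=[(153, 154)])
        assert df.loc["153-154", "unit_count"] == 9
        assert df.loc["153-154", "cluster_count"] == 2

    def test_totals_conserved(self):
        rng = np.random.default_rng(2)
        arrays = [
            self._array(int(p), float(c))
            for p, c in zip(rng.integers(40, 500, 30), rng.uniform(3, 50, 30))
        ]
        df = census(arrays)
        assert df["unit_count"].sum() == sum(round(a.copy_number) for a in arrays)
        assert df["cluster_count"].sum() == len(arrays)


class TestPoolConsensus:
    def test_identical_units_up_to_rotation(self):
        unit = random_background(np.random.default_rng(31), 90)
        genome, _ = _planted(
            31,
            [ArraySpec(unit=unit, copies=10)] * 3,
            background=30_000,
        )
        arrays = scan_tandem_arrays(genome)
        assert len(arrays) == 3
        cons = pool_consensus(arrays, (89, 91))
        ref = arrays[0].array_consensus
        assert cons.length == len(ref)
        doubled = ref + ref
        assert cons.sequence in doubled  # equal up to rotation

    def test_single_array_returns_own_consensus(self):
        genome, _ = _planted(41, [ArraySpec(period=120, copies=8)],
                             background=5000)
        arrays = scan_tandem_arrays(genome)
        cons = pool_consensus(arrays, (119, 121))
        assert cons.sequence == arrays[0].array_consensus

    def test_polymorphic_column_becomes_code(self):
        """A 50/50 G/C position resolved per copy yields S in the pooled consensus."""
        rng = np.random.default_rng(77)
        from midsat.synth import make_clean_unit

        unit = make_clean_unit(rng, 100, [])
        unit = unit[:50] + "S" + unit[51:]
        genome, _ = _planted(
            51, [ArraySpec(unit=unit, copies=30)] * 2, background=20_000
        )
        arrays = scan_tandem_arrays(genome)
        cons = pool_consensus(arrays, (99, 101))
        assert "S" in cons.sequence
        assert sum(c not in "ACGT" for c in cons.sequence) <= 3

    def test_empty_range_rejected(self):
        with pytest.raises(ValidationError):
            pool_consensus([], (100, 100))
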