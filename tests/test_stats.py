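import math
from itertools import product

import numpy as np
import pytest
import scipy.stats

from mycoscreen.census import CensusEntry, UniqueVirus
from mycoscreen.roster import HostIsolate
from mycoscreen.stats import (Contingency2x2, coinfection_summary,
                              fisher_exact, method_agreement,
                              prevalence_table, round_half_up, tpm)


def _hosts(n, positives, phylum="Chytridiomycota", **kw):
    return [HostIsolate(f"h{i}", phylum,
                        in_silico_result="positive" if i < positives
                        else "negative", **kw)
            for i in range(n)]


class TestPrevalenceTable:
    def test_counts_and_rounding(self):
        rows = prevalence_table(_hosts(333, 72), "phylum")
        total = rows[-1]
        assert (total.taxon, total.n, total.positives, total.pct) == \
            ("Total", 333, 72, 21.6)

    def test_zero_positives(self):
        rows = prevalence_table(_hosts(10, 0), "phylum")
        assert rows[-1].pct == 0.0

    def test_glomeromycotina_style_rounding(self):
        hosts = [HostIsolate(f"h{i}", "Mucoromycota",
                             subphylum="Glomeromycotina",
                             in_silico_result="positive" if i < 8
                             else "negative") for i in range(9)]
        row = prevalence_table(hosts, "subphylum")[0]
        assert (row.positives, row.n, row.pct) == (8, 9, 88.9)

    def test_combined_screening_is_or(self):
        host = HostIsolate("h", "Cryptomycota", in_vitro_result="positive",
                           in_silico_result="negative")
        assert prevalence_table([host], "phylum")[0].positives == 1

    def test_positives_reconstruct_from_pct(self):
        rng = np.random.default_rng(3)
        hosts = _hosts(146, 24) + _hosts(44, 7, phylum="Blastocladiomycota")
        hosts = [HostIsolate(f"x{i}", h.phylum,
                             in_silico_result=h.in_silico_result)
                 for i, h in enumerate(hosts)]
        for row in prevalence_table(hosts, "phylum"):
            assert round(row.n * row.pct / 100) == row.positives

    def test_unranked_binning(self):
        hosts = [HostIsolate("a", "Cryptomycota",
                             in_silico_result="negative")]
        rows = prevalence_table(hosts, "order")
        assert rows[0].taxon == "unranked"


class TestFisherExact:
    def test_diagonal_two_by_two(self):
        assert fisher_exact(Contingency2x2(2, 0, 0, 2)) == \
            pytest.approx(1 / 3)

    def test_identical_rows_p_one(self):
        assert fisher_exact(Contingency2x2(5, 3, 5, 3)) == pytest.approx(1.0)

    def test_morphology_table_significant(self):
        p = fisher_exact(Contingency2x2(12, 14, 11, 109))
        assert p == pytest.approx(3.3e-5, rel=0.05)
        assert p < 0.00004
        # the printed bound holds under the one-sided convention too
        one_sided = scipy.stats.fisher_exact(
            [[12, 14], [11, 109]], alternative="greater")[1]
        assert one_sided < 0.00004

    def test_matches_scipy_two_sided(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if a + b + c + d == 0:
                continue
            ours = fisher_exact(Contingency2x2(a, b, c, d))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_exhaustive_enumeration_small_tables(self):
        """Against a from-scratch factorial enumeration, all totals <= 30."""
        def oracle(a, b, c, d):
            n, r1, c1 = a + b + c + d, a + b, a + c
            def point(x):  # hypergeometric pmf via factorials
                b_, c_, d_ = r1 - x, c1 - x, n - r1 - c1 + x
                if min(b_, c_, d_) < 0:
                    return 0.0
                return (math.comb(r1, x) * math.comb(n - r1, c1 - x)
                        / math.comb(n, c1))
            p_obs = point(a)
            return sum(point(x) for x in range(0, min(r1, c1) + 1)
                       if point(x) <= p_obs * (1 + 1e-7))

        rng = np.random.default_rng(9)
        tables = [(2, 0, 0, 2), (0, 5, 5, 0), (1, 1, 1, 1), (3, 7, 2, 9),
                  (0, 0, 1, 0), (10, 0, 0, 10), (7, 3, 3, 7)]
        while len(tables) < 120:
            t = tuple(int(x) for x in rng.integers(0, 11, size=4))
            if 0 < sum(t) <= 30:
                tables.append(t)
        for a, b, c, d in tables:
            assert fisher_exact(Contingency2x2(a, b, c, d)) == \
                pytest.approx(oracle(a, b, c, d), abs=1e-10), (a, b, c, d)

    def test_invariant_under_row_and_column_swap(self):
        t = Contingency2x2(3, 8, 6, 2)
        swapped = Contingency2x2(2, 6, 8, 3)  # both rows and columns swapped
        assert fisher_exact(t) == pytest.approx(fisher_exact(swapped))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            Contingency2x2(-1, 2, 3, 4)


class TestCoinfection:
    def test_mean_from_85_over_36(self):
        from mycoscreen.data import coinfection_counts
        counts = coinfection_counts()
        assert (len(counts), sum(counts)) == (36, 85)
        mean, median = coinfection_summary(counts)
        assert mean == 2.4
        assert median == 1.5

    def test_single_host(self):
        entry = CensusEntry("h", (UniqueVirus(("c",), "1", 0.9, False),))
        assert coinfection_summary([entry]) == (1.0, 1.0)

    def test_two_hosts_midpoint_median(self):
        assert coinfection_summary([1, 2]) == (1.5, 1.5)

    def test_empty_census_rejected(self):
        with pytest.raises(ValueError):
            coinfection_summary([0, 0])


class TestMethodAgreement:
    def test_18_of_21(self):
        from mycoscreen.data import agreement_roster
        assert method_agreement(agreement_roster()) == 85.7

    def test_all_concordant(self):
        hosts = _hosts(4, 2)
        hosts = [HostIsolate(h.id, h.phylum,
                             in_vitro_result=h.in_silico_result,
                             in_silico_result=h.in_silico_result)
                 for h in hosts]
        assert method_agreement(hosts) == 100.0

    def test_half_concordant(self):
        hosts = [
            HostIsolate("a", "Cryptomycota", in_vitro_result="positive",
                        in_silico_result="positive"),
            HostIsolate("b", "Cryptomycota", in_vitro_result="positive",
                        in_silico_result="negative"),
        ]
        assert method_agreement(hosts) == 50.0

    def test_requires_doubly_screened(self):
        with pytest.raises(ValueError):
            method_agreement(_hosts(3, 1))


class TestTpm:
    def test_single_transcript(self):
        assert tpm([7], [500])[0] == pytest.approx(1e6)

    def test_symmetric_split(self):
        assert tpm([10, 10], [200, 200]) == pytest.approx([5e5, 5e5])

    def test_length_normalisation(self):
        out = tpm([1, 1], [100, 200])
        assert out == pytest.approx([666666.7, 333333.3], abs=0.5)

    def test_sums_to_one_million(self, rng):
        counts = rng.integers(0, 1000, size=50)
        lengths = rng.integers(100, 5000, size=50)
        assert tpm(counts, lengths).sum() == pytest.approx(1e6, rel=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tpm([0, 0], [100, 100])


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (2.25, 2.3), (2.35, 2.4), (21.62, 21.6), (88.88, 88.9), (0.05, 0.1),
    ])
    def test_half_up_one_decimal(self, x, expected):
        assert round_half_up(x) == expected
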