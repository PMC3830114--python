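"""Trait-by-chromosome tabulation, chi-square tests, homoeolog comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metaqtl import (
    DEFAULT_HOMOEOLOGS,
    compare_homoeologs,
    subgenome_counts,
    tabulate,
    uniformity_chisq,
)
from metaqtl.detection import ClusterCall, HotspotCall
from metaqtl.genome_stats import TraitChromosomeTable

from conftest import placed_records


class TestTabulate:
    def test_counts_by_cell_and_conservation(self):
        recs = placed_records("c1", [5, 10, 15], ["FS", "FS", "Micro"]) + placed_records(
            "c14", [20, 30], ["VW"]
        )
        table = tabulate(recs)
        assert table.counts.loc["c1", "FS"] == 2
        assert table.counts.loc["c1", "Micro"] == 1
        assert table.counts.loc["c14", "VW"] == 2
        assert table.grand_total == len(recs)

    def test_empty_records_give_zero_table(self):
        table = tabulate([])
        assert table.grand_total == 0
        assert table.counts.shape == (26, 43)

    def test_fixture_column_totals(self, fixture_tables):
        table = TraitChromosomeTable.from_counts(fixture_tables.trait_counts)
        totals = table.col_totals
        assert totals["Micro"] == 234
        assert totals["FS"] == 132

    def test_tsv_includes_totals_row(self):
        recs = placed_records("c1", [5, 10], ["FS"])
        text = tabulate(recs).to_tsv()
        assert text.splitlines()[-1].startswith("Total")


class TestUniformityChisq:
    def test_perfect_uniformity_is_zero(self):
        res = uniformity_chisq([5, 5, 5, 5])
        assert res.statistic == 0.0
        assert not res.exceeds

    def test_subgenome_counts_statistic(self):
        # (536-611.5)^2/611.5 * 2 = 18.643...
        res = uniformity_chisq([536, 687])
        assert res.statistic == pytest.approx(18.64, abs=0.01)
        assert res.df == 1
        assert res.critical == pytest.approx(3.84, abs=0.005)
        assert res.exceeds

    def test_26_category_critical_value(self):
        res = uniformity_chisq([47] * 26)
        assert res.df == 25
        assert res.critical == pytest.approx(37.65, abs=0.005)

    @pytest.mark.parametrize("bad", [[5], [0, 0, 0], [3, -1, 2]])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            uniformity_chisq(bad)

    @given(
        counts=st.lists(st.integers(0, 500), min_size=2, max_size=30).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_textbook_computation(self, counts):
        res = uniformity_chisq(counts)
        ref_stat, _ = stats.chisquare(counts)
        assert res.statistic == pytest.approx(float(ref_stat), abs=1e-9)


class TestSubgenomes:
    def test_all_on_c1_leaves_d_empty(self):
        table = tabulate(placed_records("c1", [5, 10, 15], ["FS"]))
        nA, nD, _ = subgenome_counts(table)
        assert (nA, nD) == (3, 0)

    def test_conservation(self, fixture_tables):
        table = TraitChromosomeTable.from_counts(fixture_tables.trait_counts)
        nA, nD, _ = subgenome_counts(table)
        assert nA + nD == table.grand_total

    def test_uniform_table_rarely_significant(self):
        # balanced draws across subgenomes should sit below the critical value
        rng = np.random.default_rng(1234)
        hits = 0
        runs = 40
        for _ in range(runs):
            counts = rng.multinomial(1223, [1 / 26] * 26)
            res = uniformity_chisq([counts[:13].sum(), counts[13:].sum()])
            hits += res.exceeds
        assert hits <= runs * 0.2  # nominal rate 5%

    def test_pairing_covers_every_chromosome_once(self):
        flat = [c for pair in DEFAULT_HOMOEOLOGS.pairs for c in pair]
        assert len(flat) == 26 == len(set(flat))
        sub = DEFAULT_HOMOEOLOGS.subgenome
        for a, d in DEFAULT_HOMOEOLOGS.pairs:
            assert sub[a] == "A" and sub[d] == "D"


def _cluster(chrom, start, end):
    return ClusterCall(chromosome=chrom, start=start, end=end, members=[],
                       name=f"{chrom}-cluster-x")


def _hotspot(chrom, trait, start, end):
    return HotspotCall(chromosome=chrom, trait=trait, start=start, end=end,
                       members=[], name=f"{chrom}-{trait}-Hotspot-x")


class TestHomoeologComparison:
    def test_overlapping_pair_is_shared(self):
        report = compare_homoeologs([_cluster("c7", 0, 25), _cluster("c16", 0, 23)])
        pair = next(p for p in report if (p.chrom_a, p.chrom_d) == ("c7", "c16"))
        assert len(pair.shared) == 1

    def test_distant_hotspots_not_shared_at_default_slack(self):
        calls = [_hotspot("c12", "Micro", 0, 16), _hotspot("c26", "Micro", 28, 45)]
        report = compare_homoeologs(calls)
        pair = next(p for p in report if (p.chrom_a, p.chrom_d) == ("c12", "c26"))
        assert pair.shared == []

    def test_same_trait_hotspot_counted(self):
        calls = [_hotspot("c5", "Micro", 0, 20), _hotspot("c19", "Micro", 0, 25)]
        report = compare_homoeologs(calls)
        pair = next(p for p in report if (p.chrom_a, p.chrom_d) == ("c5", "c19"))
        assert pair.n_shared_same_trait_hotspots == 1

    def test_empty_call_set_gives_empty_report(self):
        report = compare_homoeologs([])
        assert all(p.shared == [] for p in report)

    def test_sharing_symmetric_in_pair_order(self):
        calls = [_cluster("c7", 0, 25), _cluster("c16", 5, 30), _hotspot("c16", "VW", 0, 23)]
        fwd = compare_homoeologs(calls)
        pair = next(p for p in fwd if (p.chrom_a, p.chrom_d) == ("c7", "c16"))
        # reverse roles by swapping the pair definition
        from metaqtl.genome_stats import HomoeologMap

        swapped = HomoeologMap(pairs=(("c16", "c7"),))
        rev = compare_homoeologs(calls, homoeologs=swapped)[0]
        assert len(pair.shared) == len(rev.shared)
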