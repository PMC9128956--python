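"""Interval enrichment statistics against enumeration oracles."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ervregnet.genomic_enrichment import (
    define_active_loci,
    fisher_category_enrichment,
    genes_near_loci,
    great_enrichment,
    permutation_enrichment,
    shuffle_regions,
)
from ervregnet.expression import ExpressionMatrix
from ervregnet.intervals import merge_intervals, total_length


def iv(chrom, start, end, **extra):
    return {"chrom": chrom, "start": start, "end": end, **extra}


def binomial_tail_oracle(ci, cb, li, lb):
    """Exact upper-tail binomial probability via rational enumeration."""
    f = Fraction(li, lb)
    total = Fraction(0)
    for k in range(ci, cb + 1):
        total += math.comb(cb, k) * f**k * (1 - f) ** (cb - k)
    return float(total)


def fisher_two_tailed_oracle(a, b, c, d):
    """Two-tailed Fisher p by hypergeometric enumeration over all tables."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    pmf = {
        k: stats.hypergeom.pmf(k, n, row1, col1)
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    }
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


class TestPermutation:
    def test_poisson_tail_example(self, toy_genome):
        # fold 1.0 with lambda = observed = 5 gives p = P(X >= 5 | 5) ~ 0.5595
        assert stats.poisson.sf(4, 5) == pytest.approx(0.5595, abs=1e-4)

    def test_identical_regions_enriched(self, toy_genome):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.choice(900_000, 50, replace=False))
        regions = pd.DataFrame([iv("chr1", s, s + 500) for s in starts])
        res = permutation_enrichment(
            regions, {"self": regions}, toy_genome, n_perm=50, seed=1
        )
        assert res.loc["self", "observed"] == 50
        assert res.loc["self", "fold"] > 5
        assert res.loc["self", "p"] < 1e-6

    def test_saturating_targets_give_fold_one(self, toy_genome):
        regions = pd.DataFrame([iv("chr1", 1000 * i, 1000 * i + 100) for i in range(20)])
        targets = pd.DataFrame(
            [iv("chr1", 0, toy_genome["chr1"]), iv("chr2", 0, toy_genome["chr2"])]
        )
        res = permutation_enrichment(regions, {"all": targets}, toy_genome, 20, seed=2)
        assert res.loc["all", "fold"] == pytest.approx(1.0)
        assert 0.4 <= res.loc["all", "p"] <= 1.0

    def test_null_fold_near_one(self, toy_genome):
        rng = np.random.default_rng(5)
        regions = shuffle_regions(
            pd.DataFrame([iv("chr1", 0, 400)] * 120), toy_genome, rng
        )
        targets = shuffle_regions(
            pd.DataFrame([iv("chr1", 0, 2000)] * 150), toy_genome, rng
        )
        res = permutation_enrichment(regions, {"t": targets}, toy_genome, 100, seed=6)
        assert res.loc["t", "expected"] >= 20
        assert 0.7 <= res.loc["t", "fold"] <= 1.4

    def test_shuffle_preserves_lengths_and_bounds(self, toy_genome):
        rng = np.random.default_rng(11)
        regions = pd.DataFrame([iv("chr1", 10, 900), iv("chr2", 0, 5000)])
        shuffled = shuffle_regions(regions, toy_genome, rng)
        assert sorted(shuffled["end"] - shuffled["start"]) == [890, 5000]
        for _, row in shuffled.iterrows():
            assert 0 <= row["start"] < row["end"] <= toy_genome[row["chrom"]]


class TestGreat:
    def build_toy(self):
        """Li=1000, Lb=2000, Ci=8, Cb=10 with window 100.

        Five interest TSSs spaced 200 bp apart chain into one merged
        1000 bp window; a far chain adds another 1000 bp of background.
        """
        interest = pd.DataFrame(
            [{"gene": f"gi{i}", "chrom": "chr1", "pos": 10_000 + 200 * i}
             for i in range(5)]
        )
        far = pd.DataFrame(
            [{"gene": f"gb{i}", "chrom": "chr1", "pos": 50_000 + 200 * i}
             for i in range(5)]
        )
        background = pd.concat([interest, far], ignore_index=True)
        peaks = pd.DataFrame(
            [iv("chr1", 10_000 + 50 * i, 10_000 + 50 * i + 10) for i in range(8)]
            + [iv("chr1", 50_000, 50_010), iv("chr1", 50_100, 50_110)]
        )
        return peaks, interest, background

    def test_toy_fold_and_exact_p(self):
        peaks, interest, background = self.build_toy()
        res = great_enrichment(peaks, interest, background, window=100)
        assert (res.li, res.lb, res.ci, res.cb) == (1000, 2000, 8, 10)
        assert res.fold == pytest.approx(1.6)
        assert res.p == pytest.approx(56 / 1024, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        peaks, interest, background = self.build_toy()
        res = great_enrichment(peaks, interest, background, window=100)
        assert res.p == pytest.approx(
            binomial_tail_oracle(res.ci, res.cb, res.li, res.lb), abs=1e-12
        )

    def test_interest_equals_background(self):
        peaks, interest, _ = self.build_toy()
        res = great_enrichment(peaks, interest, interest, window=100)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_window_reported_na(self):
        peaks, interest, background = self.build_toy()
        with pytest.warns(UserWarning, match="zero-length"):
            res = great_enrichment(peaks, interest, background, window=0)
        assert np.isnan(res.fold)

    def test_no_background_peaks_errors(self):
        _, interest, background = self.build_toy()
        lonely = pd.DataFrame([iv("chr1", 900_000, 900_100)])
        with pytest.raises(ValueError, match="background"):
            great_enrichment(lonely, interest, background, window=100)

    def test_li_monotone_in_window(self):
        _, interest, background = self.build_toy()
        lengths = []
        for w in (100, 1000, 10_000, 50_000):
            from ervregnet.genomic_enrichment import _tss_windows

            lengths.append(total_length(_tss_windows(background, w, None)))
        assert lengths == sorted(lengths)

    def test_merge_idempotent(self):
        df = pd.DataFrame(
            [iv("chr1", 0, 10), iv("chr1", 5, 20), iv("chr1", 30, 40), iv("chr2", 0, 5)]
        )
        once = merge_intervals(df)
        twice = merge_intervals(once)
        pd.testing.assert_frame_equal(once, twice)


class TestFisher:
    def make_regions(self, a, b, c, d):
        """a/b in-category with/without overlap, c/d out-of-category."""
        rows, cats = [], []
        pos = 0
        site_rows = []
        for count, cat, hit in ((a, "q", True), (b, "q", False), (c, "bg", True), (d, "bg", False)):
            for _ in range(count):
                rows.append(iv("chr1", pos, pos + 100))
                if hit:
                    site_rows.append(iv("chr1", pos + 10, pos + 20))
                cats.append(cat)
                pos += 1000
        regions = pd.DataFrame(rows)
        return regions, pd.Series(cats, index=regions.index), pd.DataFrame(site_rows)

    def test_odds_ratio_cross_product(self):
        regions, cats, sites = self.make_regions(10, 10, 10, 70)
        res = fisher_category_enrichment(regions, cats, {"s": sites})
        row = res[res["category"] == "q"].iloc[0]
        assert row["odds_ratio"] == pytest.approx(7.0)

    def test_p_matches_hypergeometric_enumeration(self):
        for table in [(3, 2, 1, 6), (5, 1, 2, 8), (0, 4, 6, 2)]:
            a, b, c, d = table
            regions, cats, sites = self.make_regions(a, b, c, d)
            res = fisher_category_enrichment(regions, cats, {"s": sites})
            row = res[res["category"] == "q"].iloc[0]
            assert row["p"] == pytest.approx(
                fisher_two_tailed_oracle(a, b, c, d), rel=1e-9
            )

    def test_zero_overlap_gives_zero_or(self):
        regions, cats, sites = self.make_regions(0, 10, 5, 5)
        res = fisher_category_enrichment(regions, cats, {"s": sites})
        row = res[res["category"] == "q"].iloc[0]
        assert row["odds_ratio"] == 0.0

    def test_category_equals_universe_is_degenerate(self):
        regions, cats, sites = self.make_regions(5, 5, 0, 0)
        cats[:] = "q"
        with pytest.warns(UserWarning, match="degenerate"):
            res = fisher_category_enrichment(regions, cats, {"s": sites})
        assert np.isnan(res.iloc[0]["odds_ratio"])


class TestActiveLoci:
    def _locus_matrix(self, detected_cells, n_cells=1000):
        counts = pd.DataFrame(
            0, index=pd.Index(["L1"], name="feature"),
            columns=[f"c{i}" for i in range(n_cells)],
        )
        counts.iloc[0, :detected_cells] = 1
        meta = pd.DataFrame(
            {"cell_type": "PGCLC"}, index=pd.Index(counts.columns, name="cell_id")
        )
        return ExpressionMatrix(counts, meta)

    def _loci(self):
        return pd.DataFrame([iv("chr1", 100, 600, locus_id="L1")])

    def test_strictly_above_half_percent_is_active(self):
        active = define_active_loci(self._loci(), {"d": self._locus_matrix(6)})
        assert bool(active.loc["L1", "active"])

    def test_exactly_half_percent_is_not_active(self):
        active = define_active_loci(self._loci(), {"d": self._locus_matrix(5)})
        assert not bool(active.loc["L1", "active"])

    def test_peak_overlap_alone_activates(self):
        peaks = pd.DataFrame([iv("chr1", 550, 700)])
        active = define_active_loci(
            self._loci(), {"d": self._locus_matrix(0)}, {"atac": peaks}
        )
        assert bool(active.loc["L1", "active"])

    def test_monotone_in_datasets(self):
        base = define_active_loci(self._loci(), {"d": self._locus_matrix(0)})
        more = define_active_loci(
            self._loci(),
            {"d": self._locus_matrix(0), "e": self._locus_matrix(20)},
        )
        assert more["active"].sum() >= base["active"].sum()


class TestGenesNearLoci:
    def _loci(self):
        return pd.DataFrame([iv("chr1", 149_000, 150_000, locus_id="L1")])

    def test_distance_and_adjacency(self):
        tss = pd.DataFrame(
            [{"gene": "g1", "chrom": "chr1", "pos": 100_000, "strand": "+"}]
        )
        res = genes_near_loci(tss, self._loci(), distance=50_000)
        assert res.loc["g1", "distance"] == 49_000
        assert bool(res.loc["g1", "adjacent"])
        assert res.loc["g1", "nearest_locus"] == "L1"

    def test_threshold_inclusive(self):
        tss = pd.DataFrame(
            [{"gene": "g1", "chrom": "chr1", "pos": 99_000, "strand": "+"}]
        )
        res = genes_near_loci(tss, self._loci(), distance=50_000)
        assert res.loc["g1", "distance"] == 50_000
        assert bool(res.loc["g1", "adjacent"])

    def test_tss_inside_locus_distance_zero(self):
        tss = pd.DataFrame(
            [{"gene": "g1", "chrom": "chr1", "pos": 149_500, "strand": "-"}]
        )
        res = genes_near_loci(tss, self._loci(), distance=50_000)
        assert res.loc["g1", "distance"] == 0

    def test_minimum_over_transcripts(self):
        tss = pd.DataFrame(
            [
                {"gene": "g1", "chrom": "chr1", "pos": 100, "strand": "+"},
                {"gene": "g1", "chrom": "chr1", "pos": 148_000, "strand": "+"},
            ]
        )
        res = genes_near_loci(tss, self._loci(), distance=50_000)
        assert res.loc["g1", "distance"] == 1_000

    def test_distance_sweep_monotone(self):
        tss = pd.DataFrame(
            [{"gene": f"g{i}", "chrom": "chr1", "pos": p, "strand": "+"}
             for i, p in enumerate(range(0, 900_000, 37_000))]
        )
        counts = [
            genes_near_loci(tss, self._loci(), distance=d)["adjacent"].sum()
            for d in (20_000, 50_000, 100_000, 200_000, 500_000)
        ]
        assert counts == sorted(counts)
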