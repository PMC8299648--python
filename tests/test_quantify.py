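import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from oracles import paraclu_oracle, usage_oracle, utpm_oracle
from scapa import quantify
from scapa.preprocess import DedupedTag


def _pileup(entries, chrom="c", strand="+"):
    return pd.DataFrame([(chrom, strand, p, n) for p, n in entries],
                        columns=["chrom", "strand", "pos", "count"])


def _random_pileup(rng, max_positions=12):
    n = int(rng.integers(1, max_positions + 1))
    pos = np.sort(rng.choice(300, size=n, replace=False))
    val = rng.integers(1, 30, size=n)
    return pos, val


class TestParaclu:
    def test_dense_pair_with_outlier(self):
        peaks = quantify.paraclu_cluster(_pileup([(100, 10), (105, 10),
                                                  (300, 1)]))
        assert len(peaks) == 1
        p = peaks.iloc[0]
        assert (p.start, p.end, p.total) == (100, 106, 20)

    def test_single_position_infinite_stability(self):
        peaks = quantify.paraclu_cluster(_pileup([(50, 20)]))
        p = peaks.iloc[0]
        assert (p.start, p.end, p.total) == (50, 51, 20)
        assert math.isinf(p.max_density)

    def test_uniform_coverage_is_unstable(self):
        peaks = quantify.paraclu_cluster(
            _pileup([(100 + i, 1) for i in range(100)]))
        assert peaks.empty

    @pytest.mark.parametrize("trial", range(60))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(9000 + trial)
        pos, val = _random_pileup(rng)
        got = quantify.paraclu_cluster(_pileup(list(zip(pos, val))))
        expected = paraclu_oracle(list(pos), list(map(float, val)))
        got_tuples = sorted(
            (int(r.start), int(r.end) - 1, int(r.total),
             r.min_density, r.max_density)
            for r in got.itertuples(index=False))
        assert len(got_tuples) == len(expected)
        for g, e in zip(got_tuples, expected):
            assert g[:3] == e[:3]
            assert g[3] == pytest.approx(e[3])
            assert g[4] == pytest.approx(e[4])

    def test_strands_clustered_independently(self):
        plus = _pileup([(100, 20)], strand="+")
        minus = _pileup([(100, 20)], strand="-")
        peaks = quantify.paraclu_cluster(pd.concat([plus, minus]))
        assert len(peaks) == 2
        assert set(peaks.strand) == {"+", "-"}


class TestMergePeaks:
    def _peaks(self, ivals, strand="+"):
        return pd.DataFrame([("c", strand, s, e) for s, e in ivals],
                            columns=["chrom", "strand", "start", "end"])

    def test_overlap_merges(self):
        merged = quantify.merge_peaks([self._peaks([(100, 150)]),
                                       self._peaks([(140, 200)])])
        assert list(merged[["start", "end"]].itertuples(index=False,
                                                        name=None)) == \
            [(100, 200)]

    def test_bookended_merge_and_disjoint_kept(self):
        merged = quantify.merge_peaks([self._peaks([(100, 150), (150, 180),
                                                    (200, 220)])])
        assert list(merged[["start", "end"]].itertuples(index=False,
                                                        name=None)) == \
            [(100, 180), (200, 220)]

    def test_idempotent(self, rng):
        ivals = [(int(s), int(s + rng.integers(5, 40)))
                 for s in rng.integers(0, 500, size=20)]
        once = quantify.merge_peaks([self._peaks(ivals)])
        twice = quantify.merge_peaks([once])
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))


GENES = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 400],
                      "end": [300, 700], "strand": ["+", "+"],
                      "gene_id": ["gA", "gB"]})


class TestRestrictAndAssign:
    def test_intergenic_peak_dropped(self):
        peaks = pd.DataFrame({"chrom": ["c", "c"], "strand": ["+", "+"],
                              "start": [100, 320], "end": [150, 360]})
        out = quantify.restrict_to_genes(peaks, GENES)
        assert len(out) == 1 and out.gene_ids.iloc[0] == ["gA"]

    def test_opposite_strand_no_overlap(self):
        peaks = pd.DataFrame({"chrom": ["c"], "strand": ["-"],
                              "start": [100], "end": [150]})
        assert quantify.restrict_to_genes(peaks, GENES).empty

    def _sites(self, positions):
        return pd.DataFrame({"chrom": "c", "strand": "+", "pos": positions,
                             "name": [f"s{i}" for i in range(len(positions))]})

    def test_single_site_peak_assigned(self):
        peaks = pd.DataFrame({"chrom": ["c"], "strand": ["+"],
                              "start": [100], "end": [200]})
        out = quantify.assign_peaks_to_sites(peaks, self._sites([150]))
        assert out.site_pos.iloc[0] == 150

    def test_two_site_peak_split_at_pileup_minimum(self):
        peaks = pd.DataFrame({"chrom": ["c"], "strand": ["+"],
                              "start": [100], "end": [200]})
        pileup = _pileup([(p, 5) for p in range(100, 200)])
        pileup.loc[pileup.pos == 151, "count"] = 1  # the valley
        out = quantify.assign_peaks_to_sites(peaks, self._sites([120, 180]),
                                             pileup=pileup)
        assert list(out[["start", "end", "site_pos"]].itertuples(
            index=False, name=None)) == [(100, 151, 120), (151, 200, 180)]
        # oracle: exhaustive scan for the minimum between the two sites
        between = pileup[(pileup.pos > 120) & (pileup.pos <= 180)]
        assert between.loc[between["count"].idxmin(), "pos"] == 151

    def test_split_tie_breaks_to_midpoint(self):
        peaks = pd.DataFrame({"chrom": ["c"], "strand": ["+"],
                              "start": [100], "end": [200]})
        out = quantify.assign_peaks_to_sites(peaks, self._sites([120, 180]),
                                             pileup=_pileup([]))
        assert list(out.end)[0] == 150  # flat pileup -> midpoint boundary

    def test_siteless_peak_rescued_within_assign_dist(self):
        peaks = pd.DataFrame({"chrom": ["c"], "strand": ["+"],
                              "start": [100], "end": [200]})
        out = quantify.assign_peaks_to_sites(peaks, self._sites([230]),
                                             assign_dist=50)
        assert out.site_pos.iloc[0] == 230

    def test_siteless_peak_beyond_assign_dist_dropped(self):
        peaks = pd.DataFrame({"chrom": ["c"], "strand": ["+"],
                              "start": [100], "end": [200]})
        out = quantify.assign_peaks_to_sites(peaks, self._sites([500]),
                                             assign_dist=50)
        assert out.empty and out.attrs["n_dropped"] == 1

    def test_multi_gene_peak_resolved_by_site(self):
        overlapping = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [0, 150], "end": [300, 700],
             "strand": ["+", "+"], "gene_id": ["gA", "gB"]})
        peaks = pd.DataFrame({"chrom": ["c"], "strand": ["+"],
                              "start": [160], "end": [320]})
        peaks = quantify.restrict_to_genes(peaks, overlapping)
        assert peaks.gene_ids.iloc[0] == ["gA", "gB"]
        peaks = quantify.assign_peaks_to_sites(
            peaks, self._sites([310]))  # site only inside gB's body
        out = quantify.resolve_peak_genes(peaks, overlapping)
        assert out.gene_id.iloc[0] == "gB"


def _tag(cell, end3, umi, strand="+", pa=True):
    return DedupedTag(cell_barcode=cell, umi=umi, chrom="c", strand=strand,
                      end3=end3, polya_flag=pa)


def _peak_frame():
    return pd.DataFrame({"chrom": ["c", "c"], "strand": ["+", "+"],
                         "start": [100, 300], "end": [200, 400],
                         "site_pos": [150, 350], "site_name": ["s0", "s1"],
                         "gene_id": ["gA", "gA"]})


class TestCounting:
    def test_counts_and_boundary_convention(self):
        tags = {"cell1": [_tag("cell1", 150, f"u{i}") for i in range(4)]
                + [_tag("cell1", 200, "edge")]     # end is half-open
                + [_tag("cell1", 199, "in")]}
        adata = quantify.count_isoforms(tags, _peak_frame())
        assert adata.X[0, 0] == 5
        assert adata.uns["n_tags_outside_peaks"] == 1

    def test_every_tag_counts_once(self, rng):
        tags = {"cell1": [_tag("cell1", int(p), f"u{i}")
                          for i, p in enumerate(rng.integers(50, 450, 200))]}
        adata = quantify.count_isoforms(tags, _peak_frame())
        assert adata.X.sum() + adata.uns["n_tags_outside_peaks"] == 200


class TestUsage:
    def _adata(self, X):
        X = np.asarray(X)
        var = _peak_frame()
        var.index = pd.Index(["i0", "i1"], name="isoform")
        return ad.AnnData(X=X, var=var,
                          obs=pd.DataFrame(index=[f"c{i}"
                                                  for i in range(X.shape[0])]))

    def test_direct_arithmetic(self):
        U = quantify.usage(self._adata([[6, 2]]))
        assert list(U.iloc[0]) == pytest.approx([0.75, 0.25])

    def test_undetected_gene_is_na(self):
        U = quantify.usage(self._adata([[0, 0]]))
        assert U.iloc[0].isna().all()

    def test_simplex_and_oracle_agreement(self, rng):
        X = rng.integers(0, 10, size=(30, 2))
        U = quantify.usage(self._adata(X))
        for i in range(30):
            expected = usage_oracle(list(X[i]))
            if expected is None:
                assert U.iloc[i].isna().all()
            else:
                assert list(U.iloc[i]) == pytest.approx(expected, abs=1e-12)
                assert U.iloc[i].sum() == pytest.approx(1.0, abs=1e-9)

    def test_pooling_equivalence(self, rng):
        # usage of the artificial bulk equals the count-weighted mean of
        # the defined single-cell usages
        X = rng.integers(0, 12, size=(50, 2))
        adata = self._adata(X)
        U = quantify.usage(adata)
        bulk = X.sum(axis=0)
        bulk_usage = bulk / bulk.sum()
        totals = X.sum(axis=1)
        defined = totals > 0
        weighted = (U[defined.tolist()].mul(totals[defined], axis=0).sum(axis=0)
                    / totals[defined].sum())
        assert list(weighted) == pytest.approx(list(bulk_usage), abs=1e-12)


class TestUtpm:
    def test_direct_arithmetic(self):
        gc = pd.DataFrame({"gA": [5], "gB": [49995]}, index=["c1"])
        expr, excluded = quantify.utpm(gc)
        assert expr.loc["c1", "gA"] == pytest.approx(100.0)
        assert excluded == []

    def test_per_cell_sum_is_one_million(self, rng):
        gc = pd.DataFrame(rng.integers(0, 50, size=(20, 30)),
                          index=[f"c{i}" for i in range(20)])
        gc.iloc[3] = 0
        expr, excluded = quantify.utpm(gc)
        assert excluded == ["c3"]
        assert np.allclose(expr.sum(axis=1), 1e6, rtol=1e-6)

    def test_oracle_agreement(self, rng):
        counts = {f"g{i}": int(rng.integers(0, 100)) for i in range(10)}
        gc = pd.DataFrame(counts, index=["c1"])
        expr, _ = quantify.utpm(gc)
        expected = utpm_oracle(counts)
        for g, v in expected.items():
            assert expr.loc["c1", g] == pytest.approx(v, abs=1e-9)

    def test_empty_matrix(self):
        expr, excluded = quantify.utpm(pd.DataFrame())
        assert expr.empty and excluded == []

    def test_log_view(self):
        gc = pd.DataFrame({"gA": [10], "gB": [10]}, index=["c1"])
        expr, _ = quantify.utpm(gc, log=True)
        assert expr.loc["c1", "gA"] == pytest.approx(np.log2(5e5 + 1))
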