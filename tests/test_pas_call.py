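import re

import numpy as np
import pandas as pd
import pytest

from oracles import single_linkage_clusters_oracle
from scapa import pas_call
from scapa.pas_call import revcomp
from scapa.preprocess import DedupedTag


def _tag(chrom="c", strand="+", end3=0, pa=True, umi="U"):
    return DedupedTag(cell_barcode="B", umi=umi, chrom=chrom, strand=strand,
                      end3=end3, polya_flag=pa)


def _pileup(entries):
    return pd.DataFrame(entries, columns=["chrom", "strand", "pos", "count"])


UTR = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [200],
                    "strand": ["+"]})


class TestCollectPolyaTags:
    def test_utr_restriction_and_polya_filter(self):
        tags = ([_tag(end3=110 + i, umi=f"a{i}") for i in range(5)]       # in
                + [_tag(end3=300 + i, umi=f"b{i}") for i in range(2)]     # out
                + [_tag(end3=120 + i, pa=False, umi=f"c{i}") for i in range(3)])
        pileup = pas_call.collect_polya_tags(tags, utr3=UTR)
        assert pileup["count"].sum() == 5
        pileup2 = pas_call.collect_polya_tags(tags, restrict_to_utr3=False)
        assert pileup2["count"].sum() == 7

    def test_strand_mismatch_excluded(self):
        tags = [_tag(end3=150, strand="-")]
        pileup = pas_call.collect_polya_tags(tags, utr3=UTR)
        assert pileup.empty

    def test_missing_annotation_is_hard_error(self):
        with pytest.raises(ValueError, match="annotation"):
            pas_call.collect_polya_tags([_tag()], utr3=None)


class TestInternalPriming:
    def test_a_run_downstream_removed(self):
        genome = {"c": "G" * 100 + "X" + "TTAAAAAACGTTAGCGTAGC" + "G" * 50}
        # position 100 ('X'); downstream 20bp has a 6-A run
        pileup = _pileup([("c", "+", 100, 5)])
        assert pas_call.filter_internal_priming(pileup, genome).empty

    def test_max_run_two_retained(self):
        genome = {"c": "G" * 100 + "X" + "AATAATAAGTCGTAGCTAGC" + "G" * 50}
        pileup = _pileup([("c", "+", 100, 5)])
        assert len(pas_call.filter_internal_priming(pileup, genome)) == 1

    def test_minus_strand_looks_at_lower_coordinates(self):
        # for a - strand tag, downstream = lower coords, sense = revcomp
        genome = {"c": "G" * 80 + "T" * 8 + "G" * 12 + "X" + "G" * 50}
        pileup = _pileup([("c", "-", 100, 5)])
        assert pas_call.filter_internal_priming(pileup, genome).empty

    def test_chromosome_end_truncates_window(self):
        genome = {"c": "G" * 100 + "XAA"}  # only 2 nt downstream available
        pileup = _pileup([("c", "+", 100, 5)])
        assert len(pas_call.filter_internal_priming(pileup, genome)) == 1

    def test_monotone_in_min_run(self, rng):
        # raising min_run never removes more positions
        seq = "".join(rng.choice(list("ACGT"), size=2000,
                                 p=[0.4, 0.2, 0.2, 0.2]))
        genome = {"c": seq}
        pileup = _pileup([("c", "+", p, 1) for p in range(0, 1900, 7)])
        kept = [len(pas_call.filter_internal_priming(pileup, genome,
                                                     min_run=r))
                for r in (4, 5, 6, 7, 8)]
        assert kept == sorted(kept)

    def test_appending_a_never_restores(self):
        # once removed, a longer downstream A-run can only keep it removed
        base = "TTAAAAAACGTTAGCGTAGC"
        for extra in range(1, 5):
            seq = "G" * 100 + "X" + base[:-extra] + "A" * extra
            pileup = _pileup([("c", "+", 100, 1)])
            assert pas_call.filter_internal_priming(pileup, {"c": seq}).empty


class TestClusterTags:
    def test_worked_example(self):
        pileup = _pileup([("c", "+", 100, 5), ("c", "+", 112, 3),
                          ("c", "+", 140, 2)])
        clusters = pas_call.cluster_tags(pileup, max_gap=20)
        assert [(c.start, c.end, c.summit, c.total) for c in clusters] == \
            [(100, 113, 100, 8), (140, 141, 140, 2)]

    def test_boundary_gap_inclusive(self):
        pileup = _pileup([("c", "+", 0, 1), ("c", "+", 20, 1),
                          ("c", "+", 40, 1)])
        clusters = pas_call.cluster_tags(pileup, max_gap=20)
        assert len(clusters) == 1

    def test_single_position(self):
        clusters = pas_call.cluster_tags(_pileup([("c", "-", 7, 4)]))
        assert clusters[0].summit == 7 and clusters[0].total == 4

    def test_summit_tie_breaks_five_prime(self):
        plus = pas_call.cluster_tags(_pileup([("c", "+", 10, 3),
                                              ("c", "+", 15, 3)]))
        minus = pas_call.cluster_tags(_pileup([("c", "-", 10, 3),
                                               ("c", "-", 15, 3)]))
        assert plus[0].summit == 10   # 5'-most on + is the lowest coord
        assert minus[0].summit == 15  # 5'-most on - is the highest coord

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_transitive_closure_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        positions = sorted(rng.choice(500, size=rng.integers(2, 25),
                                      replace=False))
        pileup = _pileup([("c", "+", int(p), 1) for p in positions])
        got = [c.positions for c in pas_call.cluster_tags(pileup, max_gap=20)]
        assert got == single_linkage_clusters_oracle(positions, 20)


class TestCallSites:
    def test_normalized_count_arithmetic(self):
        clusters = pas_call.cluster_tags(_pileup([("c", "+", 50, 8)]))
        sites = pas_call.call_sites(clusters, total_polya_tags=10**6,
                                    min_norm_count=5, min_raw_count=3)
        assert len(sites) == 1
        assert sites.norm_count.iloc[0] == pytest.approx(8.0)

    def test_raw_threshold_suppresses(self):
        clusters = pas_call.cluster_tags(_pileup([("c", "+", 50, 2)]))
        sites = pas_call.call_sites(clusters, 10**6, min_norm_count=0,
                                    min_raw_count=3)
        assert sites.empty

    def test_all_below_threshold_no_error(self):
        clusters = pas_call.cluster_tags(_pileup([("c", "+", 50, 1),
                                                  ("c", "+", 500, 1)]))
        assert pas_call.call_sites(clusters, 100, 1000.0, 5).empty

    def test_zero_library_is_hard_error(self):
        with pytest.raises(ValueError):
            pas_call.call_sites([], total_polya_tags=0)


def _sites(rows):
    df = pd.DataFrame(rows, columns=["chrom", "strand", "pos"])
    df["tag_count"] = 10
    df["norm_count"] = 10.0
    df["name"] = [f"s{i}" for i in range(len(df))]
    return df


class TestClassifyVsAnnotation:
    def test_signed_distance_and_status(self):
        sites = _sites([("c", "+", 1000)])
        ann = pd.DataFrame({"chrom": ["c"], "strand": ["+"], "pos": [1004]})
        out, hist = pas_call.classify_vs_annotation(sites, ann)
        assert out.nearest_annotated_dist.iloc[0] == 4
        assert out.status.iloc[0] == "annotated"
        assert hist == {4: 1}

    def test_distance_sign_flips_on_minus_strand(self):
        sites = _sites([("c", "-", 1000)])
        ann = pd.DataFrame({"chrom": ["c"], "strand": ["-"], "pos": [1004]})
        out, _ = pas_call.classify_vs_annotation(sites, ann)
        assert out.nearest_annotated_dist.iloc[0] == -4

    def test_far_site_is_novel(self):
        sites = _sites([("c", "+", 1000)])
        ann = pd.DataFrame({"chrom": ["c"], "strand": ["+"], "pos": [1100]})
        out, hist = pas_call.classify_vs_annotation(sites, ann)
        assert out.status.iloc[0] == "novel"
        assert hist == {100: 1}

    def test_empty_annotation_all_novel(self):
        sites = _sites([("c", "+", 1000), ("c", "-", 50)])
        out, hist = pas_call.classify_vs_annotation(
            sites, pd.DataFrame(columns=["chrom", "strand", "pos"]))
        assert (out.status == "novel").all()
        assert hist == {}

    def test_status_partition_matches_brute_force(self, rng):
        sites = _sites([("c", "+", int(p))
                        for p in sorted(rng.choice(5000, 40, replace=False))])
        ann = pd.DataFrame({"chrom": "c", "strand": "+",
                            "pos": sorted(rng.choice(5000, 25, replace=False))})
        out, _ = pas_call.classify_vs_annotation(sites, ann, match_dist=24)
        for row in out.itertuples(index=False):
            brute = min(abs(int(a) - row.pos) for a in ann.pos)
            assert (row.status == "annotated") == (brute <= 24)


class TestMotifProfile:
    def _genome_with_signal(self, offsets, strand="+", pos=500):
        seq = list("G" * 1000)
        for o in offsets:
            if strand == "+":
                seq[pos + o:pos + o + 6] = list("AATAAA")
            else:
                seq[pos - o - 5:pos - o + 1] = list(revcomp("AATAAA"))
        return {"c": "".join(seq)}

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_peak_at_planted_offset(self, strand):
        genome = self._genome_with_signal([-21], strand=strand)
        sites = _sites([("c", strand, 500)])
        prof = pas_call.motif_profile(sites, genome)
        assert prof.freq[prof.offsets == -21][0] == 1.0
        assert prof.upstream_fraction == 1.0

    def test_absent_motif_zero_profile(self):
        sites = _sites([("c", "+", 500)])
        prof = pas_call.motif_profile(sites, {"c": "G" * 1000})
        assert prof.freq.sum() == 0.0
        assert prof.upstream_fraction == 0.0

    def test_double_occurrence_counted_once_per_site(self):
        genome = self._genome_with_signal([-30, -21])
        sites = _sites([("c", "+", 500)])
        prof = pas_call.motif_profile(sites, genome)
        assert prof.freq[prof.offsets == -30][0] == 1.0
        assert prof.freq[prof.offsets == -21][0] == 1.0
        assert prof.upstream_fraction == 1.0  # site counted once

    def test_out_of_bounds_site_excluded(self):
        sites = _sites([("c", "+", 10), ("c", "+", 500)])
        prof = pas_call.motif_profile(sites, {"c": "G" * 1000})
        assert prof.n_sites == 1 and prof.n_excluded == 1


class TestMergeSiteSets:
    def test_adjacent_sites_merge_to_strongest(self):
        a = _sites([("c", "+", 100)]).assign(tag_count=5, norm_count=5.0)
        b = _sites([("c", "+", 110)]).assign(tag_count=9, norm_count=9.0)
        merged = pas_call.merge_site_sets([a, b], match_dist=24)
        assert len(merged) == 1
        assert merged.pos.iloc[0] == 110
        assert merged.n_sets.iloc[0] == 2

    def test_distant_sites_kept_separate(self):
        a = _sites([("c", "+", 100)])
        b = _sites([("c", "+", 200)])
        merged = pas_call.merge_site_sets([a, b])
        assert len(merged) == 2

    def test_merge_of_identical_sets_is_stable(self):
        a = _sites([("c", "+", 100), ("c", "-", 300)])
        merged = pas_call.merge_site_sets([a, a.copy()])
        assert list(merged.pos) == [100, 300]
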