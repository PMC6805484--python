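import math
import random

import numpy as np
import pytest

from arichclip.annotation import Annotation
from arichclip.errors import ConfigurationError
from arichclip.sitecalling import (
    NBParams,
    RawPeak,
    call_binding_sites,
    call_raw_peaks,
    merge_windows,
    nb_tail,
    reproducibility_filter,
    resize_to_uniform_window,
    sparse_filter,
    weighted_center,
)
from arichclip.tracks import merge_tracks

from conftest import make_gene, make_track


def nb_tail_bruteforce(c, r, p):
    """Independent oracle: P(X >= c) = 1 - sum_{k<c} pmf(k) with the NB pmf
    computed directly from log-gamma."""
    log_terms = []
    for k in range(c):
        lp = (
            math.lgamma(k + r)
            - math.lgamma(r)
            - math.lgamma(k + 1)
            + r * math.log(p)
            + k * math.log1p(-p)
        )
        log_terms.append(lp)
    return 1.0 - sum(math.exp(t) for t in log_terms)


class TestNBTail:
    @pytest.mark.parametrize("r,p", [(0.5, 0.1), (2.0, 0.5), (6.0, 0.85), (0.002, 0.02)])
    def test_agrees_with_bruteforce(self, r, p):
        for c in [0, 1, 2, 5, 10, 50, 200, 1000]:
            assert nb_tail(c, r, p) == pytest.approx(
                nb_tail_bruteforce(c, r, p), abs=1e-10
            )


class TestCallRawPeaks:
    def test_uniform_track_no_peaks(self):
        gene = make_gene(end=2000)
        track = make_track({p: 1 for p in range(0, 2000)})
        peaks = call_raw_peaks(track, Annotation([gene]), NBParams(alpha=0.01))
        assert peaks == []

    def test_single_spike_one_peak(self):
        # NB(mean ~0.05) background with one count-50 position
        rng = np.random.default_rng(0)
        counts = {p: 1 for p in rng.choice(2000, size=100, replace=False)}
        counts[1000] = 50
        gene = make_gene(end=2000)
        track = make_track(counts)
        peaks = call_raw_peaks(track, Annotation([gene]), NBParams())
        assert len(peaks) == 1
        assert peaks[0].start == 1000 and peaks[0].end == 1001

    def test_recovery_of_planted_footprints(self, sim_bundle):
        merged = merge_tracks(sim_bundle["tracks"])
        peaks = call_raw_peaks(merged, sim_bundle["annotation"], NBParams())
        hit = 0
        for site in sim_bundle["truth"].planted_sites:
            if any(
                pk.chrom == site.chrom
                and pk.strand == site.strand
                and pk.start < site.end
                and site.start < pk.end
                for pk in peaks
            ):
                hit += 1
        assert hit / len(sim_bundle["truth"].planted_sites) >= 0.9


class TestWeightedCenter:
    def test_single_position(self):
        assert weighted_center(RawPeak("c", "+", 102, 103, {102: 10})) == 102

    def test_tie_rounds_toward_5prime(self):
        assert weighted_center(RawPeak("c", "+", 10, 12, {10: 5, 11: 5})) == 10
        assert weighted_center(RawPeak("c", "-", 10, 12, {10: 5, 11: 5})) == 11

    def test_weighted_mean(self):
        assert weighted_center(RawPeak("c", "+", 0, 11, {0: 1, 10: 9})) == 9

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            weighted_center(RawPeak("c", "+", 0, 5, {}))


class TestResize:
    def test_center_100(self):
        assert resize_to_uniform_window(100, 10_000) == (96, 105)

    def test_width_one(self):
        assert resize_to_uniform_window(100, 10_000, width=1) == (100, 101)

    def test_near_edge_dropped(self):
        assert resize_to_uniform_window(3, 10_000) is None
        assert resize_to_uniform_window(9_998, 10_000) is None

    def test_even_width_rejected(self):
        with pytest.raises(ConfigurationError):
            resize_to_uniform_window(100, 10_000, width=8)

    def test_overlapping_windows_allowed(self):
        w1 = resize_to_uniform_window(100, 10_000)
        w2 = resize_to_uniform_window(104, 10_000)
        assert w1[1] > w2[0]  # overlap resolved later by merge


class TestSparseFilter:
    @pytest.mark.parametrize("n_covered,keep", [(2, False), (3, True), (9, True)])
    def test_boundary(self, n_covered, keep):
        track = make_track({100 + i: 1 for i in range(n_covered)})
        assert sparse_filter((100, 109), track, "chr1", "+") is keep


class TestMergeWindows:
    def test_identical_windows_idempotent(self):
        track = make_track({100: 5, 101: 3, 104: 2})
        out = merge_windows([(96, 105), (96, 105)], track, "chr1", "+")
        assert out == [(96, 105)]

    def test_half_maximum_center(self):
        # windows centered 100 and 105; all counts at 100
        track = make_track({100: 10})
        out = merge_windows([(96, 105), (101, 110)], track, "chr1", "+")
        assert out == [(96, 105)]

    def test_disjoint_unchanged(self):
        track = make_track({100: 1, 200: 1})
        wins = [(96, 105), (196, 205)]
        assert merge_windows(wins, track, "chr1", "+") == wins

    def test_output_non_overlapping(self):
        rng = np.random.default_rng(1)
        track = make_track({int(p): int(c) for p, c in zip(rng.choice(500, 80, replace=False), rng.integers(1, 9, 80))})
        wins = [(int(c) - 4, int(c) + 5) for c in rng.integers(10, 490, 40)]
        out = merge_windows(wins, track, "chr1", "+")
        for (s1, e1), (s2, e2) in zip(out, out[1:]):
            assert e1 <= s2

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        track = make_track({int(p): int(c) for p, c in zip(rng.choice(300, 60, replace=False), rng.integers(1, 9, 60))})
        wins = [(int(c) - 4, int(c) + 5) for c in rng.integers(10, 290, 25)]
        ref = merge_windows(wins, track, "chr1", "+")
        for seed in range(5):
            shuffled = wins[:]
            random.Random(seed).shuffle(shuffled)
            assert merge_windows(shuffled, track, "chr1", "+") == ref

    def test_idempotent(self):
        track = make_track({100: 4, 103: 2, 107: 6})
        once = merge_windows([(96, 105), (100, 109), (104, 113)], track, "chr1", "+")
        assert merge_windows(once, track, "chr1", "+") == once


class TestAssignGeneRegion:
    def test_single_gene_utr3(self):
        from arichclip.sitecalling import assign_gene_region

        gene = make_gene(end=1000, cds=[(100, 700)], utr5=[(0, 100)], utr3=[(700, 1000)])
        ann = Annotation([gene])
        assert assign_gene_region((800, 809), ann, "chr1", "+") == ("G1", "3UTR")
        assert assign_gene_region((300, 309), ann, "chr1", "+") == ("G1", "CDS")
        assert assign_gene_region((50, 59), ann, "chr1", "+") == ("G1", "5UTR")

    def test_two_genes_excluded(self):
        from arichclip.sitecalling import assign_gene_region

        g1 = make_gene("G1", end=1000)
        g2 = make_gene("G2", start=500, end=1500)
        ann = Annotation([g1, g2])
        gid, reason = assign_gene_region((700, 709), ann, "chr1", "+")
        assert gid == "" and reason == "multiple_gene_overlap"

    def test_intergenic_excluded(self):
        from arichclip.sitecalling import assign_gene_region

        ann = Annotation([make_gene(end=1000)])
        gid, reason = assign_gene_region((5000, 5009), ann, "chr1", "+")
        assert gid == "" and reason == "no_gene_overlap"

    def test_non_coding_gene_ignored(self):
        from arichclip.sitecalling import assign_gene_region

        nc = make_gene("NC1", end=1000, gene_type="lncRNA")
        gid, reason = assign_gene_region((100, 109), Annotation([nc]), "chr1", "+")
        assert gid == "" and reason == "no_gene_overlap"

    def test_intron_label(self):
        from arichclip.sitecalling import assign_gene_region

        gene = make_gene(end=1000, exons=[(0, 200), (800, 1000)], cds=[(0, 200), (800, 1000)])
        ann = Annotation([gene])
        assert assign_gene_region((400, 409), ann, "chr1", "+") == ("G1", "intron")

    def test_region_precedence_utr3_over_cds(self):
        from arichclip.sitecalling import assign_gene_region

        gene = make_gene(end=1000, cds=[(0, 700)], utr3=[(700, 1000)])
        ann = Annotation([gene])
        # window straddling the CDS/3'UTR boundary -> 3'UTR by precedence
        assert assign_gene_region((696, 705), ann, "chr1", "+")[1] == "3UTR"


class TestReproducibilityFilter:
    def test_boundary(self):
        tracks = [make_track({100: 3}, replicate=f"r{i}") for i in range(3)]
        assert reproducibility_filter((96, 105), tracks, "chr1", "+", 3)
        tracks[2] = make_track({100: 2}, replicate="r2")
        assert not reproducibility_filter((96, 105), tracks, "chr1", "+", 3)

    def test_zero_threshold_always_keeps(self):
        tracks = [make_track({}, replicate="r0")]
        assert reproducibility_filter((0, 9), tracks, "chr1", "+", 0)

    def test_single_replicate(self):
        tracks = [make_track({100: 5})]
        assert reproducibility_filter((96, 105), tracks, "chr1", "+", 3)
        assert not reproducibility_filter((96, 105), tracks, "chr1", "+", 6)


class TestCallBindingSites:
    def test_final_sites_shape(self, sim_bundle):
        sites, funnel = call_binding_sites(
            sim_bundle["tracks"], sim_bundle["annotation"], sim_bundle["contig_lengths"]
        )
        by_cs = {}
        for s in sites:
            assert s.end - s.start == 9
            assert s.gene_id and s.region in {"3UTR", "5UTR", "CDS"}
            assert s.merged_count == sum(s.rep_counts.values())
            by_cs.setdefault((s.chrom, s.strand), []).append((s.start, s.end))
        for wins in by_cs.values():
            wins.sort()
            for (s1, e1), (s2, e2) in zip(wins, wins[1:]):
                assert e1 <= s2

    def test_monotone_in_min_events(self, sim_bundle):
        counts = []
        for min_events in (0, 3, 6, 12):
            sites, _ = call_binding_sites(
                sim_bundle["tracks"],
                sim_bundle["annotation"],
                sim_bundle["contig_lengths"],
                min_events=min_events,
            )
            counts.append(len(sites))
        assert counts == sorted(counts, reverse=True)

    def test_monotone_in_alpha(self, sim_bundle):
        counts = []
        for alpha in (0.05, 0.01, 0.001):
            sites, _ = call_binding_sites(
                sim_bundle["tracks"],
                sim_bundle["annotation"],
                sim_bundle["contig_lengths"],
                NBParams(alpha=alpha),
            )
            counts.append(len(sites))
        assert counts == sorted(counts, reverse=True)
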