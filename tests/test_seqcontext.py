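import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arichclip.annotation import Annotation
from arichclip.genome import GenomeStore
from arichclip.seqcontext import (
    ARichStretch,
    StretchSearchParams,
    find_arich_stretch,
    find_stretch_in_sequence,
    kmer_positional_profile,
    kmer_zscores,
    longest_a_run,
    merge_neighboring_stretches,
    stratify_sob_by_lca,
)
from arichclip.sitecalling import BindingSite

from conftest import make_gene

PARAMS = StretchSearchParams()


def oracle_stretch(seq, params=PARAMS):
    """Literal brute-force enumeration of the maximization search.

    For each window size, enumerate every placement, take max A-content
    (ties: smaller offset); apply the three keep-thresholds; then pick the
    survivor by LCA, then weighted A-content, then smaller size, then
    smaller offset.
    """
    candidates = []
    for w in range(params.min_window, params.max_window + 1):
        best = None
        for off in range(0, len(seq) - w + 1):
            window = seq[off : off + w]
            a = window.count("A") / w
            if best is None or a > best[0]:
                best = (a, off, window)
        if best is None:
            continue
        a, off, window = best
        n_a = window.count("A")
        lca = 0
        run = 0
        for ch in window:
            run = run + 1 if ch == "A" else 0
            lca = max(lca, run)
        weighted = a * n_a
        ok_a = a >= params.min_a_content
        ok_w = weighted >= params.min_weighted_a
        ok_l = lca >= params.min_lca
        keep = (ok_a and ok_w and ok_l) if params.exclusion_mode == "any" else (ok_a or ok_w or ok_l)
        if keep:
            candidates.append((off, w, a, lca, weighted))
    if not candidates:
        return None
    return max(candidates, key=lambda c: (c[3], c[4], -c[1], -c[0]))


class TestFindStretchInSequence:
    def test_all_c_returns_none(self):
        assert find_stretch_in_sequence("C" * 55, PARAMS) is None

    def test_30a_block(self):
        seq = "A" * 30 + "C" * 25
        off, w, a, lca, weighted = find_stretch_in_sequence(seq, PARAMS)
        assert (off, w, lca) == (0, 30, 30)
        assert a == 1.0

    def test_12a_at_offset_2(self):
        seq = "CC" + "A" * 12 + "C" * 41
        off, w, a, lca, weighted = find_stretch_in_sequence(seq, PARAMS)
        assert (off, w) == (2, 12)
        assert a == 1.0 and lca == 12 and weighted == 12.0

    def test_short_sequence(self):
        assert find_stretch_in_sequence("AAAA", PARAMS) is None  # < min window
        assert find_stretch_in_sequence("A" * 12, PARAMS) == (0, 12, 1.0, 12, 12.0)

    @given(
        st.integers(0, 2**32 - 1),
        st.floats(min_value=0.1, max_value=0.9),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_oracle(self, seed, a_frac):
        rng = np.random.default_rng(seed)
        probs = [a_frac] + [(1 - a_frac) / 3] * 3
        seq = "".join(rng.choice(list("ACGT"), size=55, p=probs))
        assert find_stretch_in_sequence(seq, PARAMS) == oracle_stretch(seq)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_returned_stretch_passes_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=55, p=[0.5, 1 / 6, 1 / 6, 1 / 6]))
        hit = find_stretch_in_sequence(seq, PARAMS)
        if hit is not None:
            off, w, a, lca, weighted = hit
            assert a >= PARAMS.min_a_content
            assert weighted >= PARAMS.min_weighted_a
            assert lca >= PARAMS.min_lca
            assert 8 <= w <= 30

    def test_all_fail_exclusion_mode(self):
        params = StretchSearchParams(exclusion_mode="all")
        # pure 8-A run: passes under 'all' (lca ok) though weighted_a = 8 < 11
        seq = "C" * 10 + "A" * 8 + "C" * 37
        assert find_stretch_in_sequence(seq, PARAMS) is None
        hit = find_stretch_in_sequence(seq, params)
        assert hit is not None and hit[1] == 8


def make_site(center, strand="+", sid="s1", chrom="chr1"):
    return BindingSite(sid, chrom, strand, center - 4, center + 5, "G1", "3UTR", {})


class TestFindArichStretchGenomic:
    def test_plus_strand_coordinates(self):
        seq = "C" * 100 + "C" * 2 + "A" * 12 + "C" * 200
        genome = GenomeStore({"chr1": seq})
        st_ = find_arich_stretch(make_site(100), genome)
        assert (st_.start, st_.end) == (102, 114)
        assert st_.lca == 12 and st_.site_ids == ["s1"]

    def test_minus_strand_mirror(self):
        # site center 300 on the minus strand; downstream = genomic left;
        # A on the minus strand = T on the stored plus strand. 12 T's are
        # planted at genomic 287..298, i.e. transcript offset 2 from center.
        genome = GenomeStore({"chr1": "C" * 287 + "T" * 12 + "C" * 101})
        st_ = find_arich_stretch(make_site(300, strand="-"), genome)
        assert st_ is not None
        assert (st_.start, st_.end) == (287, 299)
        assert st_.lca == 12

    def test_none_when_no_a(self):
        genome = GenomeStore({"chr1": "C" * 400})
        assert find_arich_stretch(make_site(100), genome) is None


def stretch(start, end, lca, weighted, sids, strand="+"):
    return ARichStretch("chr1", strand, start, end, 1.0, lca, weighted, list(sids))


class TestMergeNeighboringStretches:
    def test_identical_linked_to_both(self):
        out = merge_neighboring_stretches(
            [stretch(10, 22, 12, 12, ["s1"]), stretch(10, 22, 12, 12, ["s2"])]
        )
        assert len(out) == 1
        assert out[0].site_ids == ["s1", "s2"]

    def test_higher_lca_wins(self):
        out = merge_neighboring_stretches(
            [stretch(10, 22, 12, 12, ["s1"]), stretch(15, 27, 8, 11, ["s2"])]
        )
        assert len(out) == 1
        assert out[0].lca == 12 and out[0].start == 10
        assert out[0].site_ids == ["s1", "s2"]

    def test_disjoint_kept(self):
        out = merge_neighboring_stretches(
            [stretch(10, 22, 12, 12, ["s1"]), stretch(50, 62, 8, 11, ["s2"])]
        )
        assert len(out) == 2

    def test_non_overlapping_subset_invariant(self):
        rng = np.random.default_rng(3)
        stretches = [
            stretch(int(s), int(s) + int(w), int(l), float(l), [f"s{i}"])
            for i, (s, w, l) in enumerate(
                zip(rng.integers(0, 300, 40), rng.integers(8, 31, 40), rng.integers(4, 20, 40))
            )
        ]
        out = merge_neighboring_stretches(stretches)
        keys = {(s.start, s.end) for s in stretches}
        out_sorted = sorted(out, key=lambda s: s.start)
        for s in out:
            assert (s.start, s.end) in keys
        for a, b in zip(out_sorted, out_sorted[1:]):
            assert a.end <= b.start


class TestKmerPositionalProfile:
    def test_planted_kmer_frequency_one(self):
        seq = "C" * 200 + "C" * 10 + "AAAA" + "C" * 200
        genome = GenomeStore({"chr1": seq})
        prof = kmer_positional_profile([make_site(200)], genome, ["AAAA"], halfwindow=50)
        assert prof.loc[10, "AAAA"] == 1.0
        assert prof.loc[0, "AAAA"] == 0.0

    def test_absent_kmer_zero_profile(self):
        genome = GenomeStore({"chr1": "C" * 400})
        prof = kmer_positional_profile([make_site(200)], genome, ["AAAA"], halfwindow=50)
        assert (prof["AAAA"] == 0).all()

    def test_minus_strand_offsets(self):
        # AAAA planted 10 nt downstream of a minus-strand site => TTTT on the
        # plus-strand genome, genomic left of the center
        seq = "C" * 187 + "TTTT" + "C" * 9 + "C" * 200
        genome = GenomeStore({"chr1": seq})
        prof = kmer_positional_profile(
            [make_site(200, strand="-")], genome, ["AAAA"], halfwindow=50
        )
        assert prof.loc[10, "AAAA"] == 1.0

    def test_uniform_background_rate(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=40_000))
        genome = GenomeStore({"chr1": seq})
        sites = [make_site(int(c), sid=f"s{i}") for i, c in enumerate(rng.integers(100, 39_900, 400))]
        prof = kmer_positional_profile(sites, genome, ["ACGT"], halfwindow=50)
        # mean frequency ~ (1/4)^4; allow generous MC slack
        assert prof["ACGT"].mean() == pytest.approx(0.25**4, rel=0.5)


@pytest.fixture(scope="module")
def planted_genome():
    # one plus-strand gene; AAAA planted 20 nt downstream of every site
    rng = np.random.default_rng(5)
    seq = list("".join(rng.choice(list("CGT"), size=30_000)))
    gene = make_gene(end=30_000, cds=[(0, 2000)], utr3=[(2000, 30_000)])
    sites = []
    for i, c in enumerate(range(2500, 27_000, 500)):
        sites.append(make_site(c, sid=f"s{i}"))
        seq[c + 20 : c + 24] = list("AAAA")
    return GenomeStore({"chr1": "".join(seq)}), Annotation([gene]), sites


class TestKmerZScores:

    def test_planted_aaaa_downstream_z(self, planted_genome):
        genome, ann, sites = planted_genome
        zs = kmer_zscores(sites, genome, ann, bg_windows=200, bg_repeats=30, seed=1)
        row = zs[(zs.kmer == "AAAA") & (zs.region == "downstream_flank")].iloc[0]
        assert row.z is not None and row.z > 5

    def test_seed_deterministic(self, planted_genome):
        genome, ann, sites = planted_genome
        z1 = kmer_zscores(sites, genome, ann, bg_windows=100, bg_repeats=10, seed=7)
        z2 = kmer_zscores(sites, genome, ann, bg_windows=100, bg_repeats=10, seed=7)
        assert z1.equals(z2)

    def test_zero_sd_flagged(self, planted_genome):
        genome, ann, sites = planted_genome
        zs = kmer_zscores(sites, genome, ann, bg_windows=50, bg_repeats=5, seed=2)
        flagged = zs[zs.bg_sd == 0]
        assert flagged.z.isna().all()


class FakeSob:
    def __init__(self, mean):
        self.mean_sob = mean
        self.defined = True


class TestStratifySob:
    def test_constant_sob(self):
        sites = [make_site(100 * i, sid=f"s{i}") for i in range(1, 5)]
        sob = {s.site_id: FakeSob(3.0) for s in sites}
        stretches = [stretch(95, 110, 8, 11, ["s1", "s2"])]
        df = stratify_sob_by_lca(sites, sob, stretches)
        assert set(df.mean_sob) == {3.0}
        assert (df.sd_sob == 0).all()

    def test_no_stretch_bookkeeping(self):
        sites = [make_site(100, sid="s1"), make_site(300, sid="s2")]
        sob = {"s1": FakeSob(1.0), "s2": FakeSob(2.0)}
        stretches = [stretch(95, 110, 8, 11, ["s1"])]
        df = stratify_sob_by_lca(sites, sob, stretches).set_index("lca_bin")
        assert df.loc["no_stretch", "n"] == 1
        assert df.loc[8, "n"] == 1
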