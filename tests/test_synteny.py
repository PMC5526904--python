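"""Outgroup anchoring and sliding-window syntenic-block detection."""

import numpy as np
import pytest

from wgdtrace.homology import HitRecord
from wgdtrace.simulate import simulate_wgd_gene_orders
from wgdtrace.synteny import (
    GeneLocus,
    ParalogFamily,
    anchor_paralog_families,
    detect_syntenic_blocks,
    shared_pair_count,
)

from _oracles import longest_monotone_subsequence_oracle


def region(chrom, gene_ids, families):
    return [
        GeneLocus(g, chrom, i, "+", family_id=f)
        for i, (g, f) in enumerate(zip(gene_ids, families))
    ]


def pairs_of(blocks):
    out = set()
    for b in blocks:
        out |= b.pair_ids
    return out


class TestAnchoring:
    def test_family_split_by_different_anchors(self):
        fam = ParalogFamily("F", ("P1", "P2", "P3"))
        hits = [
            HitRecord("P1", "O1", 1e-50, 300.0),
            HitRecord("P2", "O1", 1e-40, 250.0),
            HitRecord("P3", "O2", 1e-30, 200.0),
        ]
        out = anchor_paralog_families([fam], hits)
        assert len(out) == 1
        assert set(out[0].member_ids) == {"P1", "P2"}
        assert out[0].anchor_id == "O1"  # P3's subgroup is a singleton

    def test_member_without_hit_below_cutoff_discarded(self):
        fam = ParalogFamily("F", ("P1", "P2"))
        hits = [
            HitRecord("P1", "O1", 1e-50, 300.0),
            HitRecord("P2", "O1", 1e-9, 100.0),  # above 1e-10: no anchor
        ]
        assert anchor_paralog_families([fam], hits) == []

    def test_shared_anchor_keeps_family_intact(self):
        fam = ParalogFamily("F", ("P1", "P2", "P3"))
        hits = [HitRecord(p, "O5", 1e-50, 300.0) for p in fam.member_ids]
        out = anchor_paralog_families([fam], hits)
        assert len(out) == 1
        assert out[0].family_id == "F"
        assert out[0].anchor_id == "O5"
        assert set(out[0].member_ids) == {"P1", "P2", "P3"}


class TestDetection:
    def test_direct_block(self):
        fams = [f"f{i}" for i in range(10)]
        a = region("A", [f"a{i}" for i in range(10)], fams)
        b = region("B", [f"b{i}" for i in range(10)],
                   [fams[i] if i in (0, 2, 6) else None for i in range(10)])
        a = [l if l.order_index in (0, 2, 6) else
             GeneLocus(l.gene_id, l.chrom, l.order_index, l.strand, None)
             for l in a]
        blocks = detect_syntenic_blocks(a, b, window_size=10, min_pairs=3)
        assert len(blocks) == 1
        assert blocks[0].orientation == "direct"
        assert blocks[0].n_pairs == 3

    def test_inverted_block(self):
        a = region("A", ["a1", "a2", "a3"], ["f1", "f2", "f3"])
        b = region("B", ["b3", "b2", "b1"], ["f3", "f2", "f1"])
        blocks = detect_syntenic_blocks(a, b, window_size=10, min_pairs=3)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"
        assert blocks[0].n_pairs == 3

    def test_no_anchored_pairs_gives_empty(self):
        a = region("A", ["a1", "a2"], ["f1", "f2"])
        b = region("B", ["b1", "b2"], ["g1", "g2"])
        assert detect_syntenic_blocks(a, b, window_size=10, min_pairs=2) == []

    def test_parameter_validation(self):
        a = region("A", ["a1"], ["f1"])
        with pytest.raises(ValueError):
            detect_syntenic_blocks(a, a, window_size=1)
        with pytest.raises(ValueError):
            detect_syntenic_blocks(a, a, min_pairs=1)

    def test_symmetry_under_region_swap(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = 12
            perm = rng.permutation(n)
            fams = [f"f{i}" for i in range(n)]
            a = region("A", [f"a{i}" for i in range(n)], fams)
            b = region("B", [f"b{i}" for i in range(n)],
                       [fams[p] for p in perm])
            fwd = detect_syntenic_blocks(a, b, window_size=20, min_pairs=3)
            rev = detect_syntenic_blocks(b, a, window_size=20, min_pairs=3)
            fwd_pairs = {frozenset(p) for bl in fwd for p in bl.pair_ids}
            rev_pairs = {frozenset(p) for bl in rev for p in bl.pair_ids}
            assert fwd_pairs == rev_pairs
            assert sorted(bl.orientation for bl in fwd) == sorted(
                bl.orientation for bl in rev
            )

    def test_first_block_matches_exhaustive_lms_oracle(self):
        """The largest detected block equals the longest monotone
        subsequence found by exhaustive search (small instances)."""
        rng = np.random.default_rng(7)
        for _ in range(8):
            n = 9
            perm = rng.permutation(n)
            fams = [f"f{i}" for i in range(n)]
            a = region("A", [f"a{i}" for i in range(n)], fams)
            b = region("B", [f"b{i}" for i in range(n)],
                       [fams[p] for p in perm])
            blocks = detect_syntenic_blocks(a, b, window_size=30, min_pairs=2)
            coord_pairs = [
                (i, int(np.nonzero(perm == i)[0][0])) for i in range(n)
            ]
            inc = longest_monotone_subsequence_oracle(coord_pairs, +1)
            dec = longest_monotone_subsequence_oracle(coord_pairs, -1)
            best_len = max(len(inc), len(dec))
            if not blocks:
                assert best_len < 2 or best_len < 2
                continue
            largest = max(blocks, key=lambda bl: bl.n_pairs)
            assert largest.n_pairs == best_len

    def test_blocks_monotone_invariant_and_null_rate_low(self):
        """Uniformly shuffled sparse anchors: every reported block is still
        monotone and the expected spurious-block count stays low."""
        rng = np.random.default_rng(123)
        total_blocks = 0
        n_trials = 20
        for _ in range(n_trials):
            n, n_shared = 40, 10  # only 10 anchored families between regions
            perm = rng.permutation(n)
            shared = set(rng.choice(n, size=n_shared, replace=False))
            fams_a = [f"f{i}" if i in shared else None for i in range(n)]
            a = region("A", [f"a{i}" for i in range(n)], fams_a)
            b = region("B", [f"b{i}" for i in range(n)],
                       [fams_a[p] for p in perm])
            blocks = detect_syntenic_blocks(a, b, window_size=100,
                                            min_pairs=3)
            for bl in blocks:
                ar = [x.order_index for x, _ in bl.pairs]
                br = [y.order_index for _, y in bl.pairs]
                assert ar == sorted(ar)
                sign = 1 if bl.orientation == "direct" else -1
                assert all(
                    sign * (br[i + 1] - br[i]) > 0 for i in range(len(br) - 1)
                )
            total_blocks += len(blocks)
        # a random arrangement of 10 anchors yields on average at most ~1
        # monotone chain of >= 3 pairs (LIS of k random points ~ 2*sqrt(k))
        assert total_blocks / n_trials <= 2.0

    def test_self_comparison_excludes_overlapping_spans(self):
        # one chromosome carrying two copies of a 3-gene cassette
        fams = ["f1", "f2", "f3", None, "f1", "f2", "f3"]
        genes = [f"g{i}" for i in range(7)]
        loci = [
            GeneLocus(g, "X", i, "+", family_id=f)
            for i, (g, f) in enumerate(zip(genes, fams))
        ]
        blocks = detect_syntenic_blocks(loci, loci, window_size=10,
                                        min_pairs=3)
        assert blocks, "duplicated cassette should be detected"
        for bl in blocks:
            (a0, a1), (b0, b1) = bl.span_a, bl.span_b
            assert a1 < b0 or b1 < a0
            for x, y in bl.pairs:
                assert x.gene_id != y.gene_id


class TestPlantedRecovery:
    @pytest.mark.parametrize("retention,n_inv", [(1.0, 0), (0.5, 1)])
    def test_planted_pairs_recovered(self, retention, n_inv):
        ra, rb, fams, truth = simulate_wgd_gene_orders(
            80, retention=retention, n_inversions=n_inv, seed=9
        )
        blocks = detect_syntenic_blocks(ra, rb, fams, window_size=100,
                                        min_pairs=3)
        true_pairs = {tuple(p) for p in truth.parameters["true_pairs"]}
        detected = pairs_of(blocks)
        assert len(detected & true_pairs) / len(true_pairs) >= 0.9
        assert len(detected & true_pairs) / len(detected) >= 0.9
        if retention == 1.0 and n_inv == 0:
            assert len(blocks) == 1
            assert blocks[0].orientation == "direct"
            assert blocks[0].n_pairs == 80

    def test_retention_zero_empty(self):
        ra, rb, fams, truth = simulate_wgd_gene_orders(20, retention=0.0,
                                                       seed=1)
        assert truth.parameters["true_pairs"] == []
        assert detect_syntenic_blocks(ra, rb, fams) == []

    def test_single_inversion_detected_as_inverted_block(self):
        ra, rb, fams, truth = simulate_wgd_gene_orders(
            40, retention=1.0, n_inversions=1, seed=12
        )
        blocks = detect_syntenic_blocks(ra, rb, fams, window_size=100,
                                        min_pairs=3)
        assert any(b.orientation == "inverted" for b in blocks)
        detected = pairs_of(blocks)
        true_pairs = {tuple(p) for p in truth.parameters["true_pairs"]}
        assert detected == true_pairs
        assert shared_pair_count(blocks) == len(true_pairs)
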