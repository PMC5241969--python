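import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regmutnet.core_model.types import (
    ChromatinNet,
    GenomicInterval,
    MotifHit,
    PWM,
    TFNetwork,
)
from regmutnet.motif_pipeline import (
    MotifPairCategory,
    ScanConfig,
    chromatin_motif_pair_analysis,
    classify_motif_pair,
    concordance_by_motif_category,
    interacting_tf_baseline,
    motif_pair_concordance,
    motif_pair_interaction_enrichment,
    scan_motifs,
    scramble_chromatin_network,
)
from regmutnet.synthetic_data import SimConfig, simulate_chromatin_dataset

from conftest import make_mut
from oracles import brute_force_scan

BASES = "ACGT"


def consensus_pwm(consensus, tf="X", p=0.97):
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for k, b in enumerate(consensus):
        mat[k, BASES.index(b)] = p
    return PWM(tf, mat)


def random_pwm(rng, width, tf="R"):
    mat = rng.dirichlet(np.ones(4), size=width)
    return PWM(tf, mat)


class TestScanner:
    def test_background_pwm_scores_zero(self):
        pwm = PWM("bg", np.full((4, 4), 0.25))
        rng = np.random.default_rng(0)
        seq = "".join(BASES[i] for i in rng.integers(4, size=200))
        assert scan_motifs(seq, pwm, ScanConfig(threshold=6)) == []
        hits = scan_motifs(seq, pwm, ScanConfig(threshold=0))
        assert all(h.score == pytest.approx(0.0) for h in hits)

    def test_consensus_worked_example(self):
        pwm = consensus_pwm("ACGT")
        expected = 4 * math.log(0.97 / 0.25)     # ~5.4233
        hits5 = scan_motifs("ACGT", pwm, ScanConfig(threshold=5))
        assert any(h.strand == "+" and h.score == pytest.approx(expected) for h in hits5)
        assert scan_motifs("ACGT", pwm, ScanConfig(threshold=6)) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        width = int(rng.integers(2, 9))
        pwm = random_pwm(rng, width)
        seq = "".join(BASES[i] for i in rng.integers(4, size=150))
        threshold = float(rng.uniform(-2, 3))
        hits = scan_motifs(seq, pwm, ScanConfig(threshold=threshold))
        expected = brute_force_scan(seq, pwm.matrix, pwm.background, threshold)
        got = sorted((h.interval.start, h.strand, round(h.score, 9)) for h in hits)
        exp = sorted((s, st_, round(sc, 9)) for s, st_, sc in expected)
        assert [(s, st_) for s, st_, _ in got] == [(s, st_) for s, st_, _ in exp]
        for (_, _, a), (_, _, b) in zip(got, exp):
            assert a == pytest.approx(b, abs=1e-9)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, 5)
        seq = "".join(BASES[i] for i in rng.integers(4, size=100))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        fwd = scan_motifs(seq, pwm, ScanConfig(threshold=-5))
        rev = scan_motifs(rc, pwm, ScanConfig(threshold=-5))
        # hit at start s strand + in seq <-> hit at len-w-s strand - in rc
        w = pwm.width
        fwd_keys = sorted((h.interval.start, h.strand, round(h.score, 8)) for h in fwd)
        mapped = sorted(
            (len(seq) - w - h.interval.start, "+-"[h.strand == "+"], round(h.score, 8))
            for h in rev
        )
        assert fwd_keys == mapped

    def test_windows_with_n_skipped(self):
        pwm = consensus_pwm("ACGT")
        hits = scan_motifs("ACNTACGT", pwm, ScanConfig(threshold=-100))
        starts = {h.interval.start for h in hits}
        assert starts == {3, 4}    # windows 0..2 contain the N

    def test_empty_sequence(self):
        assert scan_motifs("", consensus_pwm("ACGT"), ScanConfig()) == []

    def test_pwm_wider_than_sequence(self):
        with pytest.raises(ValueError, match="wider"):
            scan_motifs("AC", consensus_pwm("ACGT"), ScanConfig())

    def test_zero_probability_needs_pseudocount(self):
        mat = np.zeros((2, 4))
        mat[:, 0] = 1.0
        pwm = PWM("z", mat)
        with pytest.raises(ValueError, match="pseudocount"):
            scan_motifs("ACGT", pwm, ScanConfig(pseudocount=0.0))
        assert scan_motifs("ACGT", pwm, ScanConfig(threshold=100)) == []

    def test_offset_applied(self):
        pwm = consensus_pwm("ACGT")
        (hit,) = [h for h in scan_motifs("ACGT", pwm, ScanConfig(threshold=5),
                                         chrom="chr7", offset=1000)
                  if h.strand == "+"]
        assert hit.interval == GenomicInterval("chr7", 1000, 1004)


def hit(tf, start=0, end=10, chrom="chr1", strand="+"):
    return MotifHit(tf=tf, interval=GenomicInterval(chrom, start, end),
                    strand=strand, score=9.0)


class TestClassifyMotifPair:
    net = TFNetwork({"X", "Y", "Z"}, [("X", "Y")])

    def test_same_site(self):
        assert (
            classify_motif_pair([hit("X")], [hit("X")], self.net)
            is MotifPairCategory.SAME_MOTIF_SAME_POSITION
        )

    def test_same_tf_different_position(self):
        assert (
            classify_motif_pair([hit("X", 0, 10)], [hit("X", 50, 60)], self.net)
            is MotifPairCategory.SAME_MOTIF_DIFFERENT_POSITION
        )

    def test_tfs_interact(self):
        assert (
            classify_motif_pair([hit("X")], [hit("Y", 50, 60)], self.net)
            is MotifPairCategory.DIFFERENT_MOTIFS_TFS_INTERACT
        )

    def test_tfs_do_not_interact(self):
        assert (
            classify_motif_pair([hit("X")], [hit("Z", 50, 60)], self.net)
            is MotifPairCategory.DIFFERENT_MOTIFS_TFS_DO_NOT_INTERACT
        )

    def test_excluded_without_hits(self):
        assert classify_motif_pair([], [hit("X")], self.net) is None

    def test_precedence_same_site_over_interaction(self):
        a = [hit("X"), hit("Z", 100, 110)]
        b = [hit("X"), hit("Y", 200, 210)]
        assert (
            classify_motif_pair(a, b, self.net)
            is MotifPairCategory.SAME_MOTIF_SAME_POSITION
        )

    @pytest.mark.parametrize("ha,hb", [
        ([hit("X")], [hit("Y", 50, 60)]),
        ([hit("X")], [hit("X", 50, 60)]),
        ([hit("X"), hit("Z", 5, 15)], [hit("Y", 50, 60)]),
    ])
    def test_symmetry(self, ha, hb):
        assert classify_motif_pair(ha, hb, self.net) == classify_motif_pair(hb, ha, self.net)


class TestScramble:
    def _net(self, seed):
        cfg = SimConfig(seed=seed, n_pairs_same_anchor=5, n_pairs_interacting=15,
                        n_pairs_non_interacting=5, edges_per_anchor=3)
        return simulate_chromatin_dataset(cfg).net

    @pytest.mark.parametrize("seed", range(10))
    def test_degree_multiset_preserved(self, seed):
        net = self._net(0)
        scrambled = scramble_chromatin_network(net, seed=seed)
        assert scrambled.anchor_degrees() == net.anchor_degrees()
        # target interval multiset preserved per chromosome
        assert sorted(t for _, t in scrambled.edges) == sorted(t for _, t in net.edges)

    def test_edges_stay_intra_chromosomal(self):
        net = self._net(1)
        scrambled = scramble_chromatin_network(net, seed=11)
        for aid, t in scrambled.edges:
            assert scrambled.anchors[aid].chrom == t.chrom

    def test_deterministic(self):
        net = self._net(2)
        a = scramble_chromatin_network(net, seed=42)
        b = scramble_chromatin_network(net, seed=42)
        assert sorted(a.edges) == sorted(b.edges)

    def test_actually_scrambles(self):
        net = self._net(3)
        scrambled = scramble_chromatin_network(net, seed=0)
        assert sorted(scrambled.edges) != sorted(net.edges)


class TestInteractionEnrichment:
    def test_baseline_with_and_without_self_pairs(self):
        net = TFNetwork({"A", "B"}, [("A", "B")])
        assert interacting_tf_baseline(net, include_self_pairs=True) == pytest.approx(1 / 3)
        assert interacting_tf_baseline(net, include_self_pairs=False) == pytest.approx(1.0)

    def test_worked_enrichment_two(self):
        net = TFNetwork({"A", "B"}, [("A", "B")])
        hits_by_region = {
            "r1": [hit("A")], "r2": [hit("B", 50, 60)],
            "r3": [hit("A")], "r4": [hit("B", 70, 80)],
            "r5": [hit("A")], "r6": [hit("A", 90, 100)],
        }
        pairs = [("r1", "r2"), ("r3", "r4"), ("r5", "r6")]
        r = motif_pair_interaction_enrichment(pairs, hits_by_region, net,
                                              include_self_pairs=True)
        assert r.observed_fraction == pytest.approx(2 / 3)
        assert r.enrichment == pytest.approx(2.0)

    def test_complete_network_saturates(self):
        tfs = ["A", "B", "C", "D"]
        net = TFNetwork(tfs, [(a, b) for i, a in enumerate(tfs) for b in tfs[i + 1:]])
        hits_by_region = {"r1": [hit("A")], "r2": [hit("C", 30, 40)]}
        r = motif_pair_interaction_enrichment([("r1", "r2")], hits_by_region, net,
                                              include_self_pairs=False)
        assert r.baseline == pytest.approx(1.0)
        assert r.enrichment == pytest.approx(r.observed_fraction)

    def test_no_pairs_errors(self):
        net = TFNetwork({"A"}, [("A", "A")])
        with pytest.raises(ValueError, match="no cross-region"):
            motif_pair_interaction_enrichment([("r1", "r2")], {}, net)

    def test_empirical_null_p(self):
        net = TFNetwork({"A", "B"}, [("A", "B")])
        hits_by_region = {"r1": [hit("A")], "r2": [hit("B", 50, 60)]}
        r = motif_pair_interaction_enrichment(
            [("r1", "r2")], hits_by_region, net,
            null_fractions=[0.0, 0.0, 1.0, 0.5],
        )
        assert r.scramble_p == pytest.approx((1 + 1) / 5)
        assert r.scramble_baseline == pytest.approx(0.375)

    def test_random_assignment_enrichment_near_one(self):
        rng = np.random.default_rng(0)
        tfs = [f"T{i}" for i in range(20)]
        edges = [(a, b) for i, a in enumerate(tfs) for b in tfs[i + 1:]
                 if rng.random() < 0.3]
        net = TFNetwork(tfs, edges)
        hits_by_region = {}
        pairs = []
        for k in range(300):
            ra, rb = f"r{k}a", f"r{k}b"
            for rid in (ra, rb):
                chosen = rng.choice(20, size=3, replace=False)
                hits_by_region[rid] = [hit(tfs[i], 10 * i, 10 * i + 8) for i in chosen]
            pairs.append((ra, rb))
        r = motif_pair_interaction_enrichment(pairs, hits_by_region, net,
                                              include_self_pairs=False)
        assert r.enrichment == pytest.approx(1.0, abs=0.15)


class TestMotifConcordance:
    def _pairs(self, cat_counts):
        """cat_counts: {category: (n, k_sharing)}"""
        out = []
        idx = 0
        for cat, (n, k) in cat_counts.items():
            for i in range(n):
                share = i < k
                a = make_mut(f"p{idx}a", pos=1 + 2 * idx, diseases={"D1"})
                b = make_mut(f"p{idx}b", pos=2 + 2 * idx,
                             diseases={"D1"} if share else {"D2"})
                out.append((a, b, cat))
                idx += 1
        return out

    def test_all_same_position_share(self):
        pairs = self._pairs({
            MotifPairCategory.SAME_MOTIF_SAME_POSITION: (5, 5),
            MotifPairCategory.DIFFERENT_MOTIFS_TFS_DO_NOT_INTERACT: (4, 1),
        })
        conc = concordance_by_motif_category(pairs)
        assert conc[MotifPairCategory.SAME_MOTIF_SAME_POSITION].fraction == 1.0

    def test_worked_binomial(self):
        pairs = self._pairs({
            MotifPairCategory.DIFFERENT_MOTIFS_TFS_INTERACT: (10, 9),
            MotifPairCategory.DIFFERENT_MOTIFS_TFS_DO_NOT_INTERACT: (10, 5),
        })
        conc = concordance_by_motif_category(pairs)
        # 9/10 vs null 0.5 -> (C(10,9) + 1)/1024 = 11/1024
        assert conc[MotifPairCategory.DIFFERENT_MOTIFS_TFS_INTERACT].p == pytest.approx(
            11 / 1024, abs=1e-12
        )

    def test_empty_reference_errors(self):
        pairs = self._pairs({MotifPairCategory.SAME_MOTIF_SAME_POSITION: (3, 3)})
        with pytest.raises(ValueError, match="reference"):
            concordance_by_motif_category(pairs)

    def test_scope_validation(self):
        with pytest.raises(ValueError, match="scope"):
            motif_pair_concordance([], {}, TFNetwork(set(), []), scope="bogus")

    def test_scope_interacting_requires_net(self):
        with pytest.raises(ValueError, match="requires"):
            motif_pair_concordance([], {}, TFNetwork(set(), []), scope="interacting")


class TestChromatinMotifAnalysis:
    def test_end_to_end_with_scramble(self):
        cfg = SimConfig(seed=7, n_pairs_same_anchor=5, n_pairs_interacting=25,
                        n_pairs_non_interacting=10, edges_per_anchor=2)
        d = simulate_chromatin_dataset(cfg)
        # attach interacting-TF hits to the planted interacting pairs
        tfnet = TFNetwork({"X", "Y", "Z", "W"}, [("X", "Y")])
        hits_by_mut = {}
        for ida, idb, cat in d.planted_pairs:
            if cat == "interacting":
                hits_by_mut[ida] = [hit("X")]
                hits_by_mut[idb] = [hit("Y", 50, 60)]
            else:
                hits_by_mut[ida] = [hit("Z")]
                hits_by_mut[idb] = [hit("W", 50, 60)]
        r = chromatin_motif_pair_analysis(
            d.mutations, d.net, hits_by_mut, tfnet, n_scrambles=20, seed=3
        )
        assert r.observed_fraction == pytest.approx(1.0)
        assert r.enrichment > 1.0
        assert r.scramble_p is not None and 0 < r.scramble_p <= 1
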