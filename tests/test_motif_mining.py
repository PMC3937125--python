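"""Motif enumeration, degree-preserving shuffles, PWM scanning and the
binomial overlap test."""

import itertools

import numpy as np
import pytest

from micffl.errors import ConfigurationError
from micffl.motif_mining import (
    PFM,
    RegulatoryNetwork,
    enrichment_test,
    enumerate_micffls,
    overlap_binomial_test,
    promoter_window,
    pwm_scan,
    read_jaspar,
    reverse_complement,
    shuffle_mirna_layer,
    shuffle_tf_layer,
)
from micffl.synthetic_data import NetworkSpec, generate_network, random_pfm


def brute_force_micffls(net, min_support=1):
    """O(n^3) oracle: loop over every (miRNA, TF, target) triple."""
    msup = {(r.mirna, r.gene): r.support
            for r in net.mirna_edges.itertuples(index=False)}
    tf_pairs = {(r.tf, r.gene) for r in net.tf_edges.itertuples(index=False)}
    mirnas = {m for m, _ in msup}
    tfs = {f for f, _ in tf_pairs}
    genes = net.genes
    out = set()
    for m, f, t in itertools.product(mirnas, tfs, genes):
        if f == t:
            continue
        if (msup.get((m, f), 0) >= min_support
                and msup.get((m, t), 0) >= min_support
                and (f, t) in tf_pairs):
            out.add((m, f, t))
    return out


class TestEnumeration:
    def test_single_triangle(self):
        net = RegulatoryNetwork.from_edges(
            [("m", "F", 4), ("m", "G", 4)], [("F", "G")]
        )
        ffls = enumerate_micffls(net)
        assert len(ffls) == 1
        assert (ffls[0].mirna, ffls[0].tf, ffls[0].target) == ("m", "F", "G")

    def test_support_filter(self):
        net = RegulatoryNetwork.from_edges(
            [("m", "F", 4), ("m", "G", 3)], [("F", "G")]
        )
        assert len(enumerate_micffls(net, min_support=3)) == 1
        assert len(enumerate_micffls(net, min_support=4)) == 0

    def test_self_regulation_excluded(self):
        net = RegulatoryNetwork.from_edges(
            [("m", "F", 4)], [("F", "F")], genes={"F"}
        )
        assert enumerate_micffls(net) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        spec = NetworkSpec(n_mirnas=12, n_tfs=6, n_genes=50,
                           mirna_degree=("poisson", 8.0),
                           tf_degree=("poisson", 10.0), seed=seed)
        net, _ = generate_network(spec)
        for ms in (1, 3):
            fast = {(f.mirna, f.tf, f.target)
                    for f in enumerate_micffls(net, ms)}
            assert fast == brute_force_micffls(net, ms)

    def test_order_independence(self, rng):
        net, _ = generate_network(NetworkSpec(n_mirnas=8, n_tfs=4,
                                              n_genes=30, seed=4))
        shuffled = RegulatoryNetwork(
            net.mirna_edges.sample(frac=1, random_state=3),
            net.tf_edges.sample(frac=1, random_state=5),
            net.genes,
        )
        assert enumerate_micffls(net) == enumerate_micffls(shuffled)

    def test_duplicate_edges_rejected(self):
        with pytest.raises(ConfigurationError):
            RegulatoryNetwork.from_edges(
                [("m", "G", 1), ("m", "G", 2)], [("F", "G")]
            )

    def test_support_range_enforced(self):
        with pytest.raises(ConfigurationError):
            RegulatoryNetwork.from_edges([("m", "G", 5)], [("F", "G")])


class TestShuffles:
    @pytest.fixture
    def net(self):
        return generate_network(NetworkSpec(n_mirnas=10, n_tfs=5,
                                            n_genes=40, seed=6))[0]

    def test_mirna_shuffle_preserves_degrees_and_tf_layer(self, net):
        sh = shuffle_mirna_layer(net, seed=9)
        before = net.mirna_edges.groupby("mirna").size().sort_index()
        after = sh.mirna_edges.groupby("mirna").size().sort_index()
        assert before.equals(after)
        assert sh.tf_edges.equals(net.tf_edges)
        assert (sh.mirna_edges["support"] == 4).all()
        assert not sh.mirna_edges.duplicated(["mirna", "gene"]).any()

    def test_tf_shuffle_preserves_degrees_and_mirna_layer(self, net):
        sh = shuffle_tf_layer(net, seed=9)
        before = net.tf_edges.groupby("tf").size().sort_index()
        after = sh.tf_edges.groupby("tf").size().sort_index()
        assert before.equals(after)
        assert sh.mirna_edges.equals(net.mirna_edges)

    def test_seed_determinism(self, net):
        a = shuffle_mirna_layer(net, seed=5).mirna_edges
        b = shuffle_mirna_layer(net, seed=5).mirna_edges
        assert a.equals(b)

    def test_endpoints_outside_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            RegulatoryNetwork.from_edges(
                [("m", "a", 4), ("m", "b", 4), ("m", "c", 4)],
                [("F", "a")], genes={"a", "b"},
            )

    def test_full_degree_shuffle_returns_whole_universe(self):
        net = RegulatoryNetwork.from_edges(
            [("m", "a", 4), ("m", "b", 4), ("m", "c", 4)],
            [("F", "a")], genes={"a", "b", "c"},
        )
        sh = shuffle_mirna_layer(net, seed=1)
        assert set(sh.mirna_edges["gene"]) == {"a", "b", "c"}


class TestEnrichment:
    def test_z_score_formula_consistency(self):
        net, _ = generate_network(NetworkSpec(n_mirnas=10, n_tfs=5,
                                              n_genes=40, n_planted_ffls=20,
                                              seed=8))
        res = enrichment_test(net, "mirna", n_perm=50, seed=2)
        assert res.z == pytest.approx(
            (res.n_real - res.null_mean) / res.null_sd
        )
        assert 0 < res.p_upper <= 1 and 0 < res.p_lower <= 1

    def test_degenerate_null_flagged(self):
        net = RegulatoryNetwork.from_edges(
            [("m", "g1", 4)], [("F", "g2")], genes={"g1", "g2", "F"}
        )
        res = enrichment_test(net, "tf", n_perm=30, seed=1)
        assert res.n_real == 0
        assert res.z is None and "degenerate_null" in res.flags

    def test_same_observed_count_for_both_layers(self):
        net, _ = generate_network(NetworkSpec(n_mirnas=10, n_tfs=5,
                                              n_genes=40, n_planted_ffls=15,
                                              seed=3))
        a = enrichment_test(net, "mirna", n_perm=5, seed=1)
        b = enrichment_test(net, "tf", n_perm=5, seed=1)
        assert a.n_real == b.n_real

    def test_invalid_arguments(self):
        net, _ = generate_network(NetworkSpec(seed=1))
        with pytest.raises(ValueError):
            enrichment_test(net, "genes")
        with pytest.raises(ValueError):
            enrichment_test(net, "mirna", n_perm=0)


class TestPwmScan:
    def test_consensus_is_perfect_hit(self):
        pfm = random_pfm(8, seed=1)
        seq = "T" * 10 + pfm.consensus + "T" * 10
        # guard against accidental matches in the poly-T flanks
        hits = dict(pwm_scan(pfm, seq, 0.99).hits)
        assert hits[10] == pytest.approx(1.0)

    def test_all_n_sequence_has_no_hits(self):
        pfm = random_pfm(6, seed=2)
        res = pwm_scan(pfm, "N" * 100, 0.5)
        assert len(res) == 0

    def test_short_sequence_flagged(self):
        pfm = random_pfm(8, seed=3)
        res = pwm_scan(pfm, "ACGT", 0.7)
        assert len(res) == 0
        assert "sequence_shorter_than_motif" in res.flags

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            pwm_scan(random_pfm(4), "ACGTACGT", 0.0)

    def test_matches_per_window_rescoring(self, rng):
        """Hit set identical to exhaustive brute-force window scoring."""
        pfm = random_pfm(8, seed=4)
        lo = pfm.log_odds
        span = pfm.max_score - pfm.min_score
        seq = "".join(rng.choice(list("ACGT"), size=500))
        got = dict(pwm_scan(pfm, seq, 0.7).hits)
        expected = {}
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        for pos in range(len(seq) - 8 + 1):
            s = sum(lo[code[seq[pos + j]], j] for j in range(8))
            rel = (s - pfm.min_score) / span
            if rel >= 0.7:
                expected[pos] = rel
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k])

    def test_log_odds_matches_biopython(self):
        """Cross-check the scoring matrix against Bio.motifs' PSSM."""
        from Bio import motifs
        from Bio.Seq import Seq

        pfm = random_pfm(6, seed=5)
        m = motifs.Motif(
            alignment=None,
            counts={b: list(pfm.counts[i]) for i, b in enumerate("ACGT")},
        )
        m.pseudocounts = pfm.pseudocount
        m.background = dict(zip("ACGT", pfm.background))
        pssm = m.pssm
        ours = pfm.log_odds
        for i, b in enumerate("ACGT"):
            assert np.allclose(ours[i], np.array(pssm[b]), atol=1e-10)
        # window score parity on the consensus
        score = float(pssm.calculate(Seq(pfm.consensus)))
        assert score == pytest.approx(pfm.max_score, abs=1e-5)

    def test_read_jaspar_round_trip(self, tmp_path):
        path = tmp_path / "motif.jaspar"
        path.write_text(
            ">MA0000.1 TEST\n"
            "A [ 10  0  3 ]\n"
            "C [  0 12  3 ]\n"
            "G [  1  0  3 ]\n"
            "T [  1  0  3 ]\n"
        )
        pfm = read_jaspar(path)
        assert pfm.width == 3
        assert pfm.consensus[:2] == "AC"


class TestPromoterWindow:
    def test_plus_strand_window(self):
        iv = promoter_window(1000, "+")
        assert (iv.start, iv.end) == (100, 1100)
        assert iv.length == 1000 and not iv.clipped

    def test_minus_strand_window_mirrors(self):
        iv = promoter_window(1000, "-")
        assert iv.length == 1000
        assert (iv.start, iv.end) == (901, 1901)

    def test_clipping_flagged(self):
        iv = promoter_window(100, "+")
        assert iv.clipped and iv.start == 0 and iv.end == 200

    def test_minus_strand_scan_equals_revcomp_scan(self, rng):
        """Scanning the reverse complement of a window with the PFM equals
        scanning the window with the reverse-complement PFM."""
        pfm = random_pfm(8, seed=6)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        fwd = pwm_scan(pfm.reverse_complement(), seq, 0.7)
        rev = pwm_scan(pfm, reverse_complement(seq), 0.7)
        mapped = sorted(len(seq) - 8 - p for p, _ in rev)
        assert sorted(fwd.positions) == mapped

    def test_strand_validation(self):
        with pytest.raises(ValueError):
            promoter_window(100, "x")


class TestOverlapBinomial:
    def test_zero_hits_is_certain(self):
        assert overlap_binomial_test(0, 10, 0.3) == pytest.approx(1.0)

    def test_single_trial(self):
        assert overlap_binomial_test(1, 1, 0.5) == pytest.approx(0.5)

    def test_matches_exact_tail_summation(self):
        """30 hits out of 499 pairs with expectation < 1: p below 1e-20,
        agreeing with direct summation of the binomial tail."""
        from math import comb

        n, k, p = 499, 30, 1.6e-3  # expectation ~0.8 pairs
        ours = overlap_binomial_test(k, n, p)
        exact = sum(
            comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
        )
        assert ours == pytest.approx(exact, rel=1e-6)
        assert ours < 1e-20

    def test_validation(self):
        with pytest.raises(ValueError):
            overlap_binomial_test(5, 3, 0.5)
        with pytest.raises(ValueError):
            overlap_binomial_test(1, 3, 0.0)


class TestPfmValidation:
    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            PFM(np.ones((3, 5)))
        with pytest.raises(ValueError):
            PFM(-np.ones((4, 5)))

    def test_background_must_normalize(self):
        with pytest.raises(ValueError):
            PFM(np.ones((4, 4)), background=(0.5, 0.5, 0.5, 0.5))

    def test_reverse_complement_involution(self):
        pfm = random_pfm(7, seed=9)
        back = pfm.reverse_complement().reverse_complement()
        assert np.array_equal(back.counts, pfm.counts)
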