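"""Protospacer search, PAM profiles, conservation and the coincidence test."""

import numpy as np
import pytest

from crisprome import protospacers as pr
from crisprome import simulate as sim
from crisprome.iupac import reverse_complement

from oracles import coverage_by_marking, protospacer_window_scan


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestSearch:
    def test_planted_exact_protospacer(self):
        rng = np.random.default_rng(1)
        genome = random_seq(rng, 3000)
        hits = pr.find_protospacers(genome[700:735], genome)
        assert [(h.start, h.end, h.strand) for h in hits] == [(700, 735, "+")]
        assert hits[0].identity == 1.0
        assert hits[0].flank_5 == genome[690:700]
        assert hits[0].flank_3 == genome[735:745]

    def test_reverse_complement_hit(self):
        rng = np.random.default_rng(2)
        genome = random_seq(rng, 3000)
        hits = pr.find_protospacers(reverse_complement(genome[700:735]), genome)
        assert [(h.start, h.strand) for h in hits] == [(700, "-")]
        # flanks are oriented to the protospacer strand
        assert hits[0].flank_5 == reverse_complement(genome[735:745])
        assert hits[0].flank_3 == reverse_complement(genome[690:700])

    def test_genome_shorter_than_spacer(self):
        assert pr.find_protospacers("ACGT" * 10, "ACGTACG") == []

    def test_mismatched_hit_meets_identity_gate(self):
        rng = np.random.default_rng(3)
        genome = random_seq(rng, 2000)
        spacer = list(genome[400:440])
        for i in (0, 20, 39):
            spacer[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[spacer[i]]
        hits = pr.find_protospacers("".join(spacer), genome)
        match = [h for h in hits if h.start == 400]
        assert match and match[0].identity == pytest.approx(37 / 40)

    def test_agrees_with_sliding_window_oracle(self):
        """Seeded search equals the exhaustive scan (which encodes the same
        perfect-word hit condition) on random genome/spacer draws."""
        rng = np.random.default_rng(4)
        genome = random_seq(rng, 5000)
        params = pr.MatchParams()
        index = pr.GenomeIndex(genome, "g", params)
        spacers = []
        for i in range(60):  # random spacers: mostly no hits
            spacers.append(random_seq(rng, int(rng.integers(25, 61))))
        for i in range(40):  # planted with 0-5 substitutions, both strands
            L = int(rng.integers(25, 61))
            s = int(rng.integers(0, 5000 - L))
            sp = list(genome[s : s + L])
            for j in rng.choice(L, int(rng.integers(0, 6)), replace=False):
                sp[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sp[j]]
            sp = "".join(sp)
            spacers.append(sp if rng.random() < 0.5 else reverse_complement(sp))
        for sp in spacers:
            got = {(h.start, h.strand): h.identity for h in index.search(sp)}
            expect = protospacer_window_scan(sp, genome)
            assert got == expect

    def test_seed_guarantee_condition(self):
        # 3 mismatches on 25 nt can split all runs below 8
        assert not pr.seed_guaranteed(25, 0.85, 8)
        assert pr.seed_guaranteed(60, 0.97, 8)


class TestDedupe:
    def test_overlapping_hits_merge_to_best(self):
        h1 = pr.ProtospacerHit("c1", "g", 100, 135, "+", 0.97, "", "")
        h2 = pr.ProtospacerHit("c2", "g", 110, 145, "+", 0.88, "", "")
        h3 = pr.ProtospacerHit("c3", "g", 300, 335, "+", 0.9, "", "")
        kept = pr.dedupe_hits([h1, h2, h3])
        assert [h.cluster_id for h in kept] == ["c1", "c3"]

    def test_opposite_strands_not_merged(self):
        h1 = pr.ProtospacerHit("c1", "g", 100, 135, "+", 0.97, "", "")
        h2 = pr.ProtospacerHit("c2", "g", 100, 135, "-", 0.88, "", "")
        assert len(pr.dedupe_hits([h1, h2])) == 2


class TestPam:
    def _hit(self, f5, f3):
        return pr.ProtospacerHit("c", "g", 0, 35, "+", 1.0, f5, f3)

    def test_identical_flanks_give_their_consensus(self):
        hits = [self._hit("GGGGGGGCCA", "TTTTTTTTTT")] * 4
        prof = pr.pam_consensus(hits)
        assert prof["flank_5"][1] == "GGGGGGGCCA"
        assert prof["flank_3"][1] == "TTTTTTTTTT"

    def test_random_flanks_give_all_n(self):
        rng = np.random.default_rng(8)
        hits = [
            self._hit(random_seq(rng, 10), random_seq(rng, 10)) for _ in range(300)
        ]
        assert set(pr.pam_consensus(hits)["flank_5"][1]) == {"N"}

    def test_planted_pam_recovered(self):
        """A CCA motif just 5' of the protospacer in 90% of sites shows up
        in the consensus; other positions stay N."""
        rng = np.random.default_rng(9)
        hits = []
        for i in range(200):
            f5 = random_seq(rng, 7) + ("CCA" if i % 10 else random_seq(rng, 3))
            hits.append(self._hit(f5, random_seq(rng, 10)))
        cons = pr.pam_consensus(hits)["flank_5"][1]
        assert cons[-3:] == "CCA"
        assert set(cons[:-3]) == {"N"}

    def test_requires_two_hits(self):
        with pytest.raises(ValueError):
            pr.pam_consensus([self._hit("A" * 10, "C" * 10)])


class TestConservation:
    def test_identical_genomes_fully_conserved(self):
        track = pr.classify_conservation("ACGT" * 100, "ACGT" * 100)
        assert track.identical.all()
        assert track.span_is_conserved(0, 400)

    def test_single_substitution_makes_span_variable(self):
        a = "ACGT" * 100
        b = a[:200] + ("A" if a[200] != "A" else "C") + a[201:]
        track = pr.classify_conservation(a, b)
        assert track.span_is_conserved(0, 200)
        assert not track.span_is_conserved(180, 215)

    def test_gap_column_is_not_conserved(self):
        track = pr.classify_conservation("ACGTACGT", "ACG-ACGT")
        assert not track.span_is_conserved(2, 5)

    def test_span_fractions_match_exhaustive_scan(self):
        dp = sim.generate_diverged_pair(10_000, 0.92, 10, seed=5)
        track = pr.classify_conservation(dp.genome_a, dp.genome_b)
        L = 35
        starts = np.arange(10_000 - L + 1)
        fast = track.spans_conserved(starts, np.full_like(starts, L))
        slow = np.array(
            [all(track.identical[s : s + L]) for s in starts]
        )
        assert (fast == slow).all()

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pr.classify_conservation("ACGT", "ACG")


class TestCoincidence:
    def _setup(self, seed=0, enrichment=1.0, n_obs=64):
        dp = sim.generate_diverged_pair(
            20_000, 0.92, n_obs, variable_enrichment=enrichment, seed=seed
        )
        track = pr.classify_conservation(dp.genome_a, dp.genome_b)
        spans = [(r.start, r.end) for r in dp.protospacers.itertuples()]
        return dp, track, spans

    def test_deterministic_given_seed(self):
        _, track, spans = self._setup(seed=3)
        r1 = pr.coincidence_test(spans, track, seed=42)
        r2 = pr.coincidence_test(spans, track, seed=42)
        assert r1 == r2

    def test_null_split_gives_large_p(self):
        # observed counts drawn to match the simulated proportions exactly
        _, track, _ = self._setup(seed=4)
        probe = pr.coincidence_test([(0, 35)], track, spacer_lengths=[35], n_sim=10_000, seed=7)
        frac_c = probe.sim_conserved / probe.n_sim
        n_obs = 200
        obs_c = int(round(frac_c * n_obs))
        # synthesise spans with exactly that split
        starts = np.arange(track.n_columns - 35)
        flags = track.spans_conserved(starts, np.full_like(starts, 35))
        cons = starts[flags][:obs_c]
        var = starts[~flags][: n_obs - obs_c]
        spans = [(int(s), int(s) + 35) for s in np.concatenate([cons, var])]
        res = pr.coincidence_test(spans, track, n_sim=10_000, seed=8)
        assert res.p_value > 0.2
        assert res.chi_square < 2.0

    def test_label_swap_invariance(self):
        from scipy import stats

        obs = [30, 70]
        exp = np.array([0.4, 0.6]) * 100
        chi_a, _ = stats.chisquare(obs, f_exp=exp)
        chi_b, _ = stats.chisquare(obs[::-1], f_exp=exp[::-1])
        assert chi_a == pytest.approx(chi_b)

    def test_published_style_counts_reproduce_statistic(self):
        """Goodness of fit of an observed (22, 42) split against simulated
        proportions (5674, 4326) gives a chi-square near 13."""
        from scipy import stats

        expected = np.array([5674, 4326]) / 10_000 * 64
        chi2, p = stats.chisquare([22, 42], f_exp=expected)
        assert chi2 == pytest.approx(13.04, abs=0.01)
        assert p < 0.01

    def test_degenerate_track_rejected(self):
        track = pr.classify_conservation("ACGT" * 30, "ACGT" * 30)
        with pytest.raises(ValueError):
            pr.coincidence_test([(0, 35)], track)


class TestCoverage:
    def test_no_hits(self):
        assert pr.genome_protospacer_coverage([], 200) == 0.0

    def test_interval_union(self):
        assert pr.genome_protospacer_coverage([(0, 50), (25, 100)], 200) == 0.5

    def test_matches_per_base_marking(self):
        rng = np.random.default_rng(12)
        intervals = []
        for _ in range(1000):
            s = int(rng.integers(0, 9965))
            intervals.append((s, s + 35))
        got = pr.genome_protospacer_coverage(intervals, 10_000)
        assert got == pytest.approx(coverage_by_marking(intervals, 10_000))
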