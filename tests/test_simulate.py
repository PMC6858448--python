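"""Synthetic community generator: determinism, planted structure, noise."""

import io as _io

import numpy as np
import pytest
from Bio import SeqIO
from scipy.stats import gaussian_kde

from crisprome import simulate as sim


def fasta_bytes(records):
    buf = _io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def fastq_bytes(records):
    buf = _io.StringIO()
    SeqIO.write(records, buf, "fastq")
    return buf.getvalue()


SMALL = dict(
    n_host_strains=3,
    n_viral_genomes=2,
    repeat_consensus_by_type={"A": sim.DEFAULT_REPEATS["A"]},
)


class TestCommunity:
    def test_determinism_byte_identical(self):
        t1, f1 = sim.generate_community(sim.CommunityConfig(**SMALL, seed=5))
        t2, f2 = sim.generate_community(sim.CommunityConfig(**SMALL, seed=5))
        assert fasta_bytes(f1) == fasta_bytes(f2)
        assert t1.adjacency == t2.adjacency
        r1, tab1 = sim.generate_amplicon_reads(t1, sim.ReadSimParams(depth=0.5, seed=9))
        r2, tab2 = sim.generate_amplicon_reads(t2, sim.ReadSimParams(depth=0.5, seed=9))
        assert fastq_bytes(r1) == fastq_bytes(r2)
        assert tab1.equals(tab2)

    def test_no_viruses_means_no_mini_arrays(self):
        truth, _ = sim.generate_community(
            sim.CommunityConfig(**{**SMALL, "n_viral_genomes": 0}, seed=1)
        )
        assert truth.mini_arrays == {}

    def test_all_arrays_respect_length_bounds(self):
        cfg = sim.CommunityConfig(**SMALL, seed=2)
        truth, _ = sim.generate_community(cfg)
        lo, hi = cfg.array_length_range
        for arr in truth.host_arrays.values():
            assert lo <= len(arr.spacer_ids) <= hi
        for arr in truth.mini_arrays.values():
            assert len(arr.spacer_ids) in (1, 2)

    def test_no_duplicate_spacers_within_or_across_arrays(self):
        truth, _ = sim.generate_community(sim.CommunityConfig(**SMALL, seed=3))
        all_ids = [s for a in truth.arrays.values() for s in a.spacer_ids]
        assert len(all_ids) == len(set(all_ids))
        seqs = list(truth.spacer_sequences.values())
        assert len(seqs) == len(set(seqs))

    def test_adjacency_set_matches_arrays(self):
        truth, _ = sim.generate_community(sim.CommunityConfig(**SMALL, seed=4))
        expected = set()
        for arr in truth.arrays.values():
            expected.update(zip(arr.spacer_ids, arr.spacer_ids[1:]))
        assert truth.adjacency == expected

    def test_mini_array_coordinates_point_at_the_array(self):
        truth, _ = sim.generate_community(sim.CommunityConfig(**SMALL, seed=6))
        for aid, arr in truth.mini_arrays.items():
            start, end = truth.mini_array_coords[aid]
            genome = truth.viral_genomes[arr.replicon_id]
            repeat = truth.repeat_realizations[(arr.replicon_id, arr.repeat_type)]
            segment = genome[start:end]
            assert segment.startswith(repeat) and segment.endswith(repeat)
            for sid in arr.spacer_ids:
                assert truth.spacer_sequences[sid] in segment

    def test_invalid_configs_rejected(self):
        with pytest.raises(sim.ConfigError):
            sim.CommunityConfig(array_length_range=(2, 10))
        with pytest.raises(sim.ConfigError):
            sim.CommunityConfig(repeat_consensus_by_type={"A": "ACGQ"})
        with pytest.raises(sim.ConfigError):
            sim.LogNormalMixture((0.0,), (1.0,), (0.7,))

    def test_three_component_mixture_has_three_modes(self):
        """10,000 draws from the default mixture: KDE on log10 abundance
        shows exactly 3 local maxima."""
        rng = np.random.default_rng(17)
        draws = sim.DEFAULT_ABUNDANCE.sample(rng, 10_000)
        logv = np.log10(draws)
        kde = gaussian_kde(logv)
        grid = np.linspace(logv.min(), logv.max(), 512)
        dens = kde(grid)
        peaks = np.flatnonzero(
            (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        )
        assert len(peaks) == 3


class TestReads:
    def test_chimera_free_pairs_are_true_adjacencies(self, clean_scenario):
        sc = clean_scenario
        adj_seq = {
            (sc.truth.spacer_sequences[a], sc.truth.spacer_sequences[b])
            for a, b in sc.truth.adjacency
        }
        for p in sc.pair_table.itertuples():
            assert (p.first, p.second) in adj_seq

    def test_error_free_spacers_verbatim(self, clean_scenario):
        sc = clean_scenario
        planted = set(sc.truth.spacer_sequences.values())
        assert set(sc.spacer_table["sequence"]) <= planted

    def test_unit_conservation(self, clean_scenario):
        """Truth table rows equal the spacer-repeat units emitted."""
        sc = clean_scenario
        per_read = sc.truth_units.groupby("read_id").size()
        assert per_read.sum() == len(sc.truth_units)
        assert (per_read >= 1).all() and (per_read <= 3).all()

    def test_chimera_rate_within_binomial_noise(self, planted_scenario):
        sc = planted_scenario
        junctions = sc.truth_units[sc.truth_units.unit_index > 0]
        n = len(junctions)
        frac = junctions["chimeric_junction"].mean()
        c = sc.params.chimera_rate
        sd = np.sqrt(c * (1 - c) / n)
        assert abs(frac - c) <= 3 * sd

    def test_substitution_count_within_binomial_noise(self):
        """Mismatches of emitted reads vs their rebuilt error-free templates
        follow Binomial(total bases, substitution rate)."""
        truth, _ = sim.generate_community(sim.CommunityConfig(**SMALL, seed=7))
        rate = 0.01
        params = sim.ReadSimParams(
            depth=1.0, substitution_rate=rate, chimera_rate=0.0, seed=8
        )
        reads, table = sim.generate_amplicon_reads(truth, params)
        by_read = {r.id: r for r in reads}
        total = mism = 0
        repeat_of = truth.repeat_realizations
        arr_of = truth.arrays
        for rid, grp in table.groupby("read_id"):
            grp = grp.sort_values("unit_index")
            first_arr = arr_of[grp.iloc[0]["array_id"]]
            repeat = repeat_of[(first_arr.replicon_id, first_arr.repeat_type)]
            parts = [params.primer_fwd, repeat]
            for row in grp.itertuples():
                parts.append(truth.spacer_sequences[row.spacer_id])
                parts.append(repeat)
            parts.append(params.primer_rev)
            template = "".join(parts)[: params.read_length]
            seq = str(by_read[rid].seq)
            assert len(seq) == len(template)
            total += len(seq)
            mism += sum(1 for a, b in zip(seq, template) if a != b)
        sd = np.sqrt(total * rate * (1 - rate))
        assert abs(mism - total * rate) <= 3 * sd

    def test_read_length_shorter_than_unit_rejected(self):
        truth, _ = sim.generate_community(sim.CommunityConfig(**SMALL, seed=7))
        with pytest.raises(sim.ConfigError):
            sim.generate_amplicon_reads(truth, sim.ReadSimParams(read_length=30, seed=1))


class TestDivergedPair:
    def test_realized_identity_hits_target(self):
        for target in (0.92, 0.95, 0.85):
            dp = sim.generate_diverged_pair(20_000, target, 10, seed=1)
            assert abs(dp.realized_identity - target) <= 0.01
            # positional identity of the two sequences
            ident = np.mean(
                [a == b for a, b in zip(dp.genome_a, dp.genome_b)]
            )
            assert ident == pytest.approx(dp.realized_identity)

    def test_near_identical_limit(self):
        dp = sim.generate_diverged_pair(10_000, 0.999, 5, seed=2)
        mismatching = sum(a != b for a, b in zip(dp.genome_a, dp.genome_b))
        assert mismatching <= 0.001 * 10_000 + 0.5

    def test_identity_one_rejected(self):
        with pytest.raises(sim.ConfigError):
            sim.generate_diverged_pair(1000, 1.0, 5)

    def test_null_enrichment_matches_start_proportions(self):
        """With enrichment 1 the conserved/variable split of placements
        follows the feasible-start class proportions within binomial noise."""
        dp = sim.generate_diverged_pair(
            50_000, 0.92, 400, variable_enrichment=1.0, seed=3
        )
        from crisprome import protospacers as pr

        track = pr.classify_conservation(dp.genome_a, dp.genome_b)
        L = 35
        starts = np.arange(50_000 - L + 1)
        frac_var = 1 - track.spans_conserved(starts, np.full_like(starts, L)).mean()
        obs_var = (dp.protospacers["label"] == "variable").mean()
        sd = np.sqrt(frac_var * (1 - frac_var) / 400)
        assert abs(obs_var - frac_var) <= 3.5 * sd

    def test_enrichment_shifts_placements_to_variable(self):
        null = sim.generate_diverged_pair(20_000, 0.92, 200, 1.0, seed=4)
        enr = sim.generate_diverged_pair(20_000, 0.92, 200, 5.0, seed=4)
        assert (enr.protospacers["label"] == "variable").mean() > (
            null.protospacers["label"] == "variable"
        ).mean()

    def test_truth_labels_match_realized_divergence(self):
        dp = sim.generate_diverged_pair(10_000, 0.92, 100, 3.0, seed=5)
        a, b = dp.genome_a, dp.genome_b
        for row in dp.protospacers.itertuples():
            has_sub = any(
                a[i] != b[i] for i in range(row.start, row.end)
            )
            assert (row.label == "variable") == has_sub
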