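"""Shared fixtures: planted communities at two scales.

The full-scale scenario (20 long arrays of 10-30 spacers, 5 mini-arrays,
chimera rate 1%, substitution rate 0.5%, depth sized so every adjacency is
expected in >= 40 read pairs and every mini-array in >= 400 reads) is built
once per session; several tests score different aspects of it against the
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import crisprome.arrays as ar
import crisprome.cluster as cl
import crisprome.extract as ex
import crisprome.miniarrays as mi
import crisprome.simulate as sim

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@dataclass
class Scenario:
    config: sim.CommunityConfig
    params: sim.ReadSimParams
    truth: sim.GroundTruth
    reads: list
    truth_units: pd.DataFrame
    spacer_table: pd.DataFrame
    pair_table: pd.DataFrame
    summary: ex.ExtractionSummary
    clusters: list
    assignment: dict
    graph: object
    filtered: object
    edge_report: pd.DataFrame

    @property
    def cluster_of_spacer_id(self) -> dict:
        return {
            sid: self.assignment.get(seq)
            for sid, seq in self.truth.spacer_sequences.items()
        }

    @property
    def true_cluster_edges(self) -> set:
        m = self.cluster_of_spacer_id
        return {
            (m[a], m[b])
            for a, b in self.truth.adjacency
            if m[a] is not None and m[b] is not None
        }


def build_scenario(
    community_seed=11,
    read_seed=12,
    n_host_strains=20,
    n_viral_genomes=5,
    mini_array_sizes=(1, 2, 1, 2, 2),
    substitution_rate=0.005,
    chimera_rate=0.01,
    min_pair_coverage=40.0,
    min_viral_reads=400.0,
    quality_mean=35.0,
    quality_sd=3.0,
) -> Scenario:
    config = sim.CommunityConfig(
        n_host_strains=n_host_strains,
        array_length_range=(10, 30),
        repeat_consensus_by_type={"A": sim.DEFAULT_REPEATS["A"]},
        n_viral_genomes=n_viral_genomes,
        mini_array_sizes=mini_array_sizes,
        abundance_model=sim.LogNormalMixture(
            (np.log(300.0), np.log(450.0), np.log(675.0)),
            (0.2, 0.2, 0.2),
            (1 / 3, 1 / 3, 1 / 3),
        ),
        seed=community_seed,
    )
    truth, _ = sim.generate_community(config)
    base = sim.ReadSimParams(seed=read_seed)
    depth = sim.coverage_targeted_depth(
        truth, base, min_pair_coverage=min_pair_coverage, min_viral_reads=min_viral_reads
    )
    params = sim.ReadSimParams(
        depth=depth,
        substitution_rate=substitution_rate,
        chimera_rate=chimera_rate,
        quality_mean=quality_mean,
        quality_sd=quality_sd,
        seed=read_seed,
    )
    reads, truth_units = sim.generate_amplicon_reads(truth, params)
    motifs = {
        "A": (
            ex.DegenerateMotif("A", sim.DEFAULT_REPEATS["A"]),
            (
                ex.DegenerateMotif("primer_fwd", params.primer_fwd),
                ex.DegenerateMotif("primer_rev", params.primer_rev),
            ),
        )
    }
    spacer_table, pair_table, summary = ex.extract_sample(
        reads, motifs, ex.ExtractionParams(), sample_id="sim"
    )
    clusters, assignment = cl.cluster_spacers(spacer_table)
    cluster_pairs = pd.DataFrame(
        {
            "first": pair_table["first"].map(assignment),
            "second": pair_table["second"].map(assignment),
        }
    )
    nodes = sorted({assignment[s] for s in spacer_table["sequence"]})
    graph = ar.build_pair_graph(cluster_pairs, nodes=nodes)
    filtered, edge_report = ar.filter_chimeric_edges(graph)
    return Scenario(
        config=config,
        params=params,
        truth=truth,
        reads=reads,
        truth_units=truth_units,
        spacer_table=spacer_table,
        pair_table=pair_table,
        summary=summary,
        clusters=clusters,
        assignment=assignment,
        graph=graph,
        filtered=filtered,
        edge_report=edge_report,
    )


@pytest.fixture(scope="session")
def planted_scenario() -> Scenario:
    """Full-scale planted community (the main recovery benchmark)."""
    return build_scenario()


@pytest.fixture(scope="session")
def clean_scenario() -> Scenario:
    """Small error-free, chimera-free community for exactness checks."""
    return build_scenario(
        community_seed=21,
        read_seed=22,
        n_host_strains=4,
        n_viral_genomes=2,
        mini_array_sizes=(1, 2),
        substitution_rate=0.0,
        chimera_rate=0.0,
        min_pair_coverage=15.0,
        min_viral_reads=60.0,
        quality_mean=38.0,
        quality_sd=2.0,
    )
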