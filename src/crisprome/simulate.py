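"""Synthetic CRISPRome communities with planted ground truth.

The simulator emulates the data-generating process behind repeat-anchored
CRISPR spacer amplicon sequencing of a thermoacidophilic archaeal community:

* host strains carrying long CRISPR arrays (one per requested repeat-type
  consensus, each strain fixing one concrete realization of the degenerate
  IUPAC consensus),
* viral genomes carrying a leader-preceded mini-CRISPR array of 1-2 spacers,
* merged amplicon reads of 1-3 repeat/spacer units flanked by PCR primers,
  with substitution errors, Phred+33 quality scores, and a controlled rate
  of chimeric junctions (PCR template switches joining spacers that are not
  adjacent in any real array),
* strain abundances drawn from a multimodal log-normal mixture, and
* pairs of diverged viral genomes whose protospacers are enriched in the
  variable regions of their alignment.

Every generated object is accompanied by machine-readable ground truth
(arrays, adjacencies, per-read spacer provenance, chimera flags), so that
extraction recall, chimera filtering, array reconstruction and mini-array
calling can all be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import iupac

__all__ = [
    "ConfigError",
    "GenerationError",
    "LogNormalMixture",
    "CommunityConfig",
    "ReadSimParams",
    "ArrayTruth",
    "GroundTruth",
    "DivergedPair",
    "generate_community",
    "generate_amplicon_reads",
    "generate_diverged_pair",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class GenerationError(RuntimeError):
    """A requested synthetic structure cannot be realized."""


@dataclass(frozen=True)
class LogNormalMixture:
    """Mixture of log-normal components (means/sds on the natural-log scale)."""

    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if not (len(self.means) == len(self.sds) == len(self.weights)):
            raise ConfigError("mixture component lists must have equal length")
        if not self.means:
            raise ConfigError("mixture needs at least one component")
        if any(w < 0 for w in self.weights) or abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigError("mixture weights must be non-negative and sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ConfigError("mixture sds must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        return np.exp(rng.normal(np.asarray(self.means)[comp], np.asarray(self.sds)[comp]))


#: default repeat consensuses (synthetic, IUPAC-degenerate) for four repeat
#: types, in the 24-27 nt range typical of Sulfolobales CRISPR repeats
DEFAULT_REPEATS: dict[str, str] = {
    "A": "GATAATCTMTTATAGRATTGAAAG",
    "B": "CTTTCAATTCYTTTHGGGATTAATC",
    "C": "GTATAGTCCMTTTAYGGAATTGAAAG",
    "D": "ATTACTTTTCTCTTATGAGACTAGTAC",
}

DEFAULT_ABUNDANCE = LogNormalMixture(
    means=(np.log(30.0), np.log(300.0), np.log(3000.0)),
    sds=(0.4, 0.4, 0.4),
    weights=(0.3, 0.4, 0.3),
)


@dataclass(frozen=True)
class CommunityConfig:
    n_host_strains: int = 20
    array_length_range: tuple[int, int] = (10, 30)
    repeat_consensus_by_type: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REPEATS)
    )
    spacer_length_range: tuple[int, int] = (32, 42)
    n_viral_genomes: int = 5
    mini_array_sizes: tuple[int, ...] | None = None  # None: drawn from {1, 2}
    leader_length: int = 120
    viral_genome_length: int = 3000
    abundance_model: LogNormalMixture = DEFAULT_ABUNDANCE
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.array_length_range
        if lo < 4 or hi < lo:
            raise ConfigError("long arrays need at least 4 spacers and a valid range")
        slo, shi = self.spacer_length_range
        if slo < 1 or shi < slo:
            raise ConfigError("invalid spacer length range")
        if self.n_host_strains < 1:
            raise ConfigError("need at least one host strain")
        if not self.repeat_consensus_by_type:
            raise ConfigError("need at least one repeat consensus")
        for label, pattern in self.repeat_consensus_by_type.items():
            try:
                iupac.validate(pattern, f"repeat consensus {label!r}")
            except iupac.IupacError as exc:
                raise ConfigError(str(exc)) from None
        if self.mini_array_sizes is not None:
            if any(k not in (1, 2) for k in self.mini_array_sizes):
                raise ConfigError("mini-arrays carry exactly 1 or 2 spacers")
            if self.n_viral_genomes and len(self.mini_array_sizes) != self.n_viral_genomes:
                raise ConfigError("mini_array_sizes must match n_viral_genomes")


# Fluidigm-style common tag sequences used as default amplicon primers
DEFAULT_PRIMER_FWD = "ACACTGACGACATGGTTCTA"
DEFAULT_PRIMER_REV = "TACGGTAGCAGAGACTTGGT"


@dataclass(frozen=True)
class ReadSimParams:
    """Amplicon read simulation parameters.

    ``depth`` is expressed in reads per abundance unit: the total read count
    is ``round(depth * total_abundance)`` and reads are then assigned to
    replicons by a single multinomial draw over abundance fractions.
    """

    depth: float = 2.0
    read_length: int = 250
    units_per_read: dict[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.45, 3: 0.20}
    )
    substitution_rate: float = 0.005
    chimera_rate: float = 0.01
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    primer_fwd: str = DEFAULT_PRIMER_FWD
    primer_rev: str = DEFAULT_PRIMER_REV
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        probs = list(self.units_per_read.values())
        if any(k not in (1, 2, 3) for k in self.units_per_read):
            raise ConfigError("units per read must be 1, 2 or 3")
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("unit probabilities must lie in [0,1] and sum to 1")
        for name in ("substitution_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        iupac.validate(self.primer_fwd, "forward primer")
        iupac.validate(self.primer_rev, "reverse primer")


@dataclass
class ArrayTruth:
    array_id: str
    replicon_id: str
    repeat_type: str
    spacer_ids: list[str]
    kind: str  # "host" | "viral"


@dataclass
class GroundTruth:
    """Planted community: arrays, spacer sequences and true adjacencies.

    Coordinates are 0-based, half-open.  ``adjacency`` holds every ordered
    pair of spacers that are neighbours in some array, leader-proximal first.
    """

    arrays: dict[str, ArrayTruth] = field(default_factory=dict)
    spacer_sequences: dict[str, str] = field(default_factory=dict)
    repeat_realizations: dict[tuple[str, str], str] = field(default_factory=dict)
    adjacency: set[tuple[str, str]] = field(default_factory=set)
    abundance: dict[str, float] = field(default_factory=dict)
    replicon_kind: dict[str, str] = field(default_factory=dict)
    viral_genomes: dict[str, str] = field(default_factory=dict)
    mini_array_coords: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def mini_arrays(self) -> dict[str, ArrayTruth]:
        return {k: a for k, a in self.arrays.items() if a.kind == "viral"}

    @property
    def host_arrays(self) -> dict[str, ArrayTruth]:
        return {k: a for k, a in self.arrays.items() if a.kind == "host"}

    def spacer_class(self) -> dict[str, str]:
        """Map spacer id -> source class ("long" host array or "mini" array)."""
        out: dict[str, str] = {}
        for arr in self.arrays.values():
            cls = "mini" if arr.kind == "viral" else "long"
            for sid in arr.spacer_ids:
                out[sid] = cls
        return out


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def _unique_spacer(rng, length_range, seen: set[str]) -> str:
    lo, hi = length_range
    while True:
        s = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        if s not in seen:
            seen.add(s)
            return s


def generate_community(config: CommunityConfig):
    """Generate a planted community.

    Returns ``(truth, fasta_records)`` where the records hold every host
    array sequence (repeat/spacer concatenation) and every viral genome.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    records: list[SeqRecord] = []
    seen: set[str] = set()
    sid_counter = 0

    def new_spacer() -> str:
        nonlocal sid_counter
        sid = f"s{sid_counter:05d}"
        sid_counter += 1
        truth.spacer_sequences[sid] = _unique_spacer(rng, config.spacer_length_range, seen)
        return sid

    lo, hi = config.array_length_range
    for i in range(config.n_host_strains):
        strain = f"strain{i:03d}"
        truth.replicon_kind[strain] = "host"
        for rtype, consensus in config.repeat_consensus_by_type.items():
            repeat = iupac.instantiate(consensus, rng)
            truth.repeat_realizations[(strain, rtype)] = repeat
            n_sp = int(rng.integers(lo, hi + 1))
            spacer_ids = [new_spacer() for _ in range(n_sp)]
            aid = f"{strain}_arr{rtype}"
            truth.arrays[aid] = ArrayTruth(aid, strain, rtype, spacer_ids, "host")
            truth.adjacency.update(zip(spacer_ids, spacer_ids[1:]))
            seq = repeat + "".join(
                truth.spacer_sequences[s] + repeat for s in spacer_ids
            )
            records.append(
                SeqRecord(Seq(seq), id=aid, description=f"host array type {rtype}")
            )

    # strain abundances: multimodal log-normal mixture
    ab = config.abundance_model.sample(rng, config.n_host_strains)
    for i, a in enumerate(ab):
        truth.abundance[f"strain{i:03d}"] = float(a)

    # viral genomes: leader followed by repeat-spacer(-repeat-spacer)-repeat.
    # Viral abundances are drawn from the top mixture component: the viruses
    # this emulates dominate the enrichment cultures they were observed in.
    rtypes = list(config.repeat_consensus_by_type)
    top = int(np.argmax(config.abundance_model.means))
    for j in range(config.n_viral_genomes):
        vid = f"virus{j:03d}"
        truth.replicon_kind[vid] = "virus"
        k = (
            config.mini_array_sizes[j]
            if config.mini_array_sizes is not None
            else int(rng.choice([1, 2]))
        )
        rtype = rtypes[j % len(rtypes)]
        repeat = iupac.instantiate(config.repeat_consensus_by_type[rtype], rng)
        truth.repeat_realizations[(vid, rtype)] = repeat
        spacer_ids = [new_spacer() for _ in range(k)]
        aid = f"{vid}_mini"
        truth.arrays[aid] = ArrayTruth(aid, vid, rtype, spacer_ids, "viral")
        truth.adjacency.update(zip(spacer_ids, spacer_ids[1:]))
        array_seq = repeat + "".join(
            truth.spacer_sequences[s] + repeat for s in spacer_ids
        )
        insert = _random_seq(rng, config.leader_length) + array_seq
        flank = config.viral_genome_length - len(insert)
        if flank < 0:
            raise GenerationError("viral genome too short for leader + mini-array")
        left = int(rng.integers(0, flank + 1))
        genome = (
            _random_seq(rng, left) + insert + _random_seq(rng, flank - left)
        )
        start = left + config.leader_length
        truth.mini_array_coords[aid] = (start, start + len(array_seq))
        truth.viral_genomes[vid] = genome
        truth.abundance[vid] = float(
            np.exp(
                rng.normal(
                    config.abundance_model.means[top], config.abundance_model.sds[top]
                )
            )
        )
        records.append(
            SeqRecord(Seq(genome), id=vid, description=f"viral genome, {k}-spacer mini-array")
        )
    return truth, records


def _mutate(rng, seq_bytes: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return seq_bytes
    hit = rng.random(seq_bytes.shape[0]) < rate
    n = int(hit.sum())
    if n == 0:
        return seq_bytes
    out = seq_bytes.copy()
    # substitute with a uniformly chosen *different* base
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = BASES[BASES != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def generate_amplicon_reads(truth: GroundTruth, params: ReadSimParams):
    """Simulate merged amplicon reads from a planted community.

    Each read is ``primer + repeat + (spacer + repeat) * k + primer`` with
    k in {1, 2, 3}, truncated to ``read_length``.  Chimeric junctions switch
    the template to a spacer drawn abundance-proportionally from a different
    array.  Returns ``(records, truth_table)``; the truth table has one row
    per emitted spacer unit with columns read_id, unit_index, spacer_id,
    array_id, chimeric_junction (the junction into this unit was a template
    switch) and extractable (spacer plus both flanking repeats fit within
    the read length).
    """
    if not truth.arrays:
        raise ConfigError("community has no arrays")
    rng = np.random.default_rng(params.seed)
    replicons = sorted(truth.abundance)
    ab = np.array([truth.abundance[r] for r in replicons], dtype=float)
    fracs = ab / ab.sum()
    n_reads = int(round(params.depth * ab.sum()))
    counts = rng.multinomial(n_reads, fracs)

    arrays_by_replicon: dict[str, list[ArrayTruth]] = {}
    for arr in truth.arrays.values():
        arrays_by_replicon.setdefault(arr.replicon_id, []).append(arr)
    for r in arrays_by_replicon:
        arrays_by_replicon[r].sort(key=lambda a: a.array_id)

    # per-array sampling weights for chimeric template switches
    all_arrays = sorted(truth.arrays.values(), key=lambda a: a.array_id)
    arr_weights = np.array(
        [
            truth.abundance[a.replicon_id] / len(arrays_by_replicon[a.replicon_id])
            for a in all_arrays
        ]
    )
    arr_weights = arr_weights / arr_weights.sum()

    ks = sorted(params.units_per_read)
    kp = np.array([params.units_per_read[k] for k in ks])

    min_unit = min(len(r) for r in truth.repeat_realizations.values()) * 2
    if params.read_length < min_unit:
        raise ConfigError("read_length shorter than one repeat+spacer unit")

    records: list[SeqRecord] = []
    rows: list[tuple] = []
    read_no = 0
    for ri, replicon in enumerate(replicons):
        for _ in range(int(counts[ri])):
            read_id = f"read{read_no:07d}"
            read_no += 1
            arrs = arrays_by_replicon.get(replicon)
            if not arrs:
                continue
            arr = arrs[int(rng.integers(len(arrs)))]
            avail = [k for k in ks if k <= len(arr.spacer_ids)]
            p = kp[: len(avail)] / kp[: len(avail)].sum()
            k = int(rng.choice(avail, p=p))
            pos = int(rng.integers(0, len(arr.spacer_ids) - k + 1))
            repeat = truth.repeat_realizations[(arr.replicon_id, arr.repeat_type)]

            units: list[tuple[str, str, bool]] = []  # (spacer_id, array_id, chimeric)
            cur_arr, cur_pos = arr, pos
            for u in range(k):
                chimeric = False
                if u > 0:
                    if params.chimera_rate > 0 and rng.random() < params.chimera_rate:
                        # PCR template switch to a different array
                        while True:
                            j = int(rng.choice(len(all_arrays), p=arr_weights))
                            if all_arrays[j].array_id != cur_arr.array_id:
                                break
                        cur_arr = all_arrays[j]
                        cur_pos = int(rng.integers(len(cur_arr.spacer_ids)))
                        chimeric = True
                    else:
                        cur_pos += 1
                        if cur_pos >= len(cur_arr.spacer_ids):
                            break
                units.append((cur_arr.spacer_ids[cur_pos], cur_arr.array_id, chimeric))

            parts = [params.primer_fwd, repeat]
            unit_spans: list[tuple[int, int]] = []
            cursor = len(params.primer_fwd) + len(repeat)
            for sid, _, _ in units:
                sp = truth.spacer_sequences[sid]
                parts.append(sp)
                unit_spans.append((cursor, cursor + len(sp)))
                cursor += len(sp)
                parts.append(repeat)
                cursor += len(repeat)
            parts.append(params.primer_rev)
            amplicon = "".join(parts)

            seq_bytes = np.frombuffer(amplicon.encode("ascii"), dtype=np.uint8)
            seq_bytes = _mutate(rng, seq_bytes, params.substitution_rate)
            seq = seq_bytes[: params.read_length].tobytes().decode("ascii")
            quals = np.clip(
                np.rint(rng.normal(params.quality_mean, params.quality_sd, len(seq))),
                2,
                41,
            ).astype(int)

            for u, ((sid, aid, chim), (s0, s1)) in enumerate(zip(units, unit_spans)):
                extractable = (s1 + len(repeat)) <= params.read_length
                rows.append((read_id, u, sid, aid, chim, extractable))

            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = quals.tolist()
            records.append(rec)

    table = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "unit_index",
            "spacer_id",
            "array_id",
            "chimeric_junction",
            "extractable",
        ],
    )
    return records, table


def coverage_targeted_depth(
    truth: GroundTruth,
    params: ReadSimParams,
    min_pair_coverage: float = 40.0,
    min_viral_reads: float = 400.0,
    margin: float = 1.15,
) -> float:
    """Depth (reads per abundance unit) ensuring planted-structure coverage.

    Sized so that every true spacer adjacency is expected in at least
    ``min_pair_coverage`` read pairs (using the worst-case terminal-junction
    window probability) and every viral genome receives at least
    ``min_viral_reads`` reads, with a safety ``margin``.
    """
    ks = sorted(params.units_per_read)
    kp = np.array([params.units_per_read[k] for k in ks])
    # per-read probability that a window covers a terminal junction of an
    # n-junction array: windows of k units have n - k + 2 start positions
    need = 0.0
    arrays_by_replicon: dict[str, list[ArrayTruth]] = {}
    for arr in truth.arrays.values():
        arrays_by_replicon.setdefault(arr.replicon_id, []).append(arr)
    for replicon, arrs in arrays_by_replicon.items():
        ab = truth.abundance[replicon]
        if truth.replicon_kind[replicon] == "virus":
            need = max(need, min_viral_reads / ab)
            continue
        for arr in arrs:
            n_sp = len(arr.spacer_ids)
            if n_sp < 2:
                continue
            avail = [k for k in ks if k <= n_sp]
            p = kp[: len(avail)] / kp[: len(avail)].sum()
            # worst junction: the terminal one, covered only by windows
            # starting at the boundary
            p_term = sum(
                pk * min(k - 1, 1) / (n_sp - k + 1)
                for k, pk in zip(avail, p)
                if k >= 2
            )
            if p_term <= 0:
                continue
            reads_needed = min_pair_coverage / p_term * len(arrs)
            need = max(need, reads_needed / ab)
    return float(need * margin)


@dataclass
class DivergedPair:
    """Two related genomes, their (gapless) alignment and protospacer truth."""

    genome_a: str
    genome_b: str
    protospacers: pd.DataFrame  # start, end, strand, label
    realized_identity: float

    @property
    def alignment(self) -> tuple[str, str]:
        return self.genome_a, self.genome_b


def generate_diverged_pair(
    base_length: int,
    target_identity: float,
    n_protospacers: int,
    variable_enrichment: float = 1.0,
    seed: int = 0,
    protospacer_length: int = 35,
    variable_fraction: float = 0.45,
    mean_block_length: float = 300.0,
) -> DivergedPair:
    """Generate two genomes at a controlled alignment identity.

    Divergence between closely related virus strains is clustered: long
    conserved blocks alternate with variable regions rather than mutations
    falling uniformly along the genome.  The generator therefore partitions
    the genome into alternating conserved/variable blocks (exponential
    lengths, ``variable_fraction`` of columns variable in expectation) and
    introduces all substitutions at uniformly drawn columns of the variable
    blocks.  The true alignment is the positional pairing (no indels), so
    realized identity is exact up to rounding of the substitution count.

    Protospacer placements are sampled over all feasible starts, weighting
    starts whose span touches at least one diverged column by
    ``variable_enrichment`` (an odds ratio; 1.0 means uniform).  Each
    placement is truth-labelled conserved/variable.
    """
    if not 0.5 < target_identity < 1.0:
        raise ConfigError("target_identity must lie in (0.5, 1.0)")
    if variable_enrichment <= 0:
        raise ConfigError("variable_enrichment must be positive")
    if protospacer_length > base_length:
        raise ConfigError("protospacer longer than genome")
    if not 0.0 < variable_fraction <= 1.0:
        raise ConfigError("variable_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    a = rng.choice(BASES, size=base_length)
    n_sub = int(round((1.0 - target_identity) * base_length))

    # alternating conserved/variable blocks with exponential lengths
    mean_v = mean_block_length
    mean_c = mean_block_length * (1.0 - variable_fraction) / variable_fraction
    in_variable = np.zeros(base_length, dtype=bool)
    pos = 0
    block_is_variable = bool(rng.random() < variable_fraction)
    while pos < base_length:
        mean = mean_v if block_is_variable else mean_c
        blen = max(1, int(round(rng.exponential(mean))))
        if block_is_variable:
            in_variable[pos : pos + blen] = True
        pos += blen
        block_is_variable = not block_is_variable
    variable_cols = np.flatnonzero(in_variable)
    if n_sub > variable_cols.size:
        raise GenerationError(
            "substitution budget exceeds variable columns; raise variable_fraction"
        )
    sub_pos = rng.choice(variable_cols, size=n_sub, replace=False)
    b = a.copy()
    for i in sub_pos:
        choices = BASES[BASES != a[i]]
        b[i] = choices[rng.integers(3)]
    diverged = np.zeros(base_length, dtype=bool)
    diverged[sub_pos] = True

    # classify every feasible start by whether its span touches divergence
    span_subs = np.convolve(diverged.astype(int), np.ones(protospacer_length, dtype=int))
    span_subs = span_subs[protospacer_length - 1 : base_length]
    variable_start = span_subs > 0
    if variable_enrichment != 1.0 and not variable_start.any():
        raise GenerationError("enrichment requested but alignment has no variable spans")

    weights = np.where(variable_start, float(variable_enrichment), 1.0)
    weights = weights / weights.sum()
    n_starts = variable_start.shape[0]
    if n_protospacers > n_starts:
        raise GenerationError("more protospacers requested than feasible starts")
    starts = rng.choice(n_starts, size=n_protospacers, replace=False, p=weights)
    starts.sort()
    df = pd.DataFrame(
        {
            "start": starts,
            "end": starts + protospacer_length,
            "strand": "+",
            "label": np.where(variable_start[starts], "variable", "conserved"),
        }
    )
    return DivergedPair(
        genome_a=a.tobytes().decode("ascii"),
        genome_b=b.tobytes().decode("ascii"),
        protospacers=df,
        realized_identity=1.0 - n_sub / base_length,
    )
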