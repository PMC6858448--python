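# Methods

This note documents the models, parameter choices and numerical decisions
behind `crisprome`, and what the synthetic-data validation does and does
not establish.

## Spacer extraction

Reads are scanned for the degenerate CRISPR repeat consensus (IUPAC
alphabet) with a Hamming-style matcher: a window matches when every
position's base set intersects the pattern symbol's set, and at most
`max_mismatch_repeat` positions fail (default 3; primers default 2;
sequencing platforms and natural repeat diversity both motivate a non-zero
allowance). Overlapping hits are resolved greedily left to right, lower
mismatch count winning at equal starts — deterministic and adequate because
genuine repeat hits in amplicons are non-overlapping by construction. If
the reverse complement of a read carries more repeat hits than the forward
orientation, the read is flipped before extraction, so all spacer and pair
observations are reported in repeat orientation.

Spacers are the substrings strictly between consecutive accepted repeat
hits (plus primer-to-repeat segments when a primer hit flanks the repeat
block). Filters follow the standard protocol for this assay: length within
[25, 60] nt and every base with Phred strictly above 20 (Q21+; the strict
reading of "higher than 20"). Pairs are emitted only for spacers at
*adjacent* unit indices that both survive filtering: if an interior spacer
is removed, its neighbours are not joined, because a fabricated adjacency
would contaminate the array graph, whereas a missing one merely costs
coverage.

Indel-tolerant motif matching is out of scope (substitution-only matching
reflects the mismatch framing of the assay); reads are treated as
already-merged single amplicon sequences.

## Identity for clustering

Spacers are clustered greedily against centroids in descending abundance
order (ties broken lexicographically); a sequence joins the first centroid
with identity ≥ 0.85, else founds a new cluster. Identity uses a global
alignment with free terminal gaps (match +1, mismatch −1, internal gap −1;
terminal gaps unpenalised) and is defined as

    identity = matches / max(core_columns, min(len_a, len_b))

where core columns exclude terminal gaps. The `min(len)` floor is a
deliberate design decision: under pure score maximisation with free end
gaps, two unrelated spacers sharing a short perfect terminal overlap admit
a degenerate "dovetail" optimum whose core is only that overlap, which
would score identity 1.0 and collapse unrelated clusters. The floor caps
such overlaps at `overlap/min(len)` while leaving the intended cases
untouched: containment of a shorter spacer scores 1.0, equal-length
sequences score Hamming identity (e.g. 5 substitutions in a 35-mer give
30/35 ≈ 0.857), and internal gaps count against identity, consistent with
the zero-end-gap-penalty convention. The dynamic program is verified
against exhaustive alignment enumeration on short strings in the test
suite, and runs as a numba kernel (≈ µs per pair) so that clustering a
full sample needs no heuristic pre-filters and the greedy semantics stay
exact.

Cross-repeat-type intersection (primer-specificity control) uses the same
alignment machinery, counting a counterpart when the optimal alignment has
at most 2 errors (mismatches + internal gaps + uncovered bases of the
shorter sequence).

## Diversity summaries

Good's coverage is computed on clusters: `C = 1 − N_rare/N_clusters` with
rare = observed once or twice. Shannon entropy is reported in nats. Chao1
is `S_obs + F₁²/(2F₂)`, switching to the bias-corrected
`S_obs + F₁(F₁−1)/(2(F₂+1))` when doubletons are absent (avoids division
by zero; standard practice). The lost-spacer interval half-width is
`z(0.975)·√(lost(1−lost)/N)`, zero by construction at lost ∈ {0, 1}.

## Array graph and chimera filtering

Pairs accumulate into a directed graph with exact multiplicities as edge
weights. For each edge (u, v) the filter compares its weight w against 5%
of S_out(u) (sum of u's outgoing weights) and 5% of S_in(v) (sum of v's
incoming weights), using pre-filter sums in a single pass — one test per
edge, no iteration.

Whether an edge should be removed when *either* sum test fires or only
when *both* fire is a genuine modelling choice. The package defaults to
**either**, for a structural reason: a chimeric edge whose head is an
array-leader spacer (true in-degree 0) has an incoming sum composed
entirely of chimeric traffic, so the both-sums rule can never remove it —
in planted-truth simulations at realistic coverage, dozens of chimeric
edges survive the both-rule while the either-rule removes all of them with
zero true-edge losses (true arrays are simple paths, so a true edge always
dominates both of its endpoint sums). The both-rule remains available
(`rule="both"`) for communities where independent arrays share terminal
spacers, the one situation in which the head-side test alone could delete
a rare array's sole edge.

Arrays are reported as all maximal source-to-sink paths of the filtered
graph (branches produce one path per branch; isolated nodes are length-1
paths). Cycles — expected only from noise — are broken at their
minimum-weight edge, ties resolved lexicographically, and logged.
Eccentricity (the spacer count of the longest path through a node) is
computed by forward/backward longest-path dynamic programming over the
DAG and verified against exhaustive path enumeration on random DAGs.
Component grouping across samples uses Pearson correlation of
log10(count+1) mean profiles with single-linkage grouping at r ≥ 0.9.

## Mini-array completeness tests

The per-sample pair probability p is the fraction of spacer *observations*
that occur in reads carrying ≥ 2 spacers. Under read independence, a
spacer that truly sits inside a longer array and was sequenced N times
avoids all pairing with probability (1−p)^N — the completeness P-value for
1-spacer candidates. For 2-spacer candidates whose pair was sequenced N
times, the probability that the pair is a truncated fragment open on at
least one side is (1−0.5^(N−1))², giving P = 1−(1−0.5^(N−1))². The
implementation evaluates the algebraically identical expansion
`x(2−x), x = 0.5^(N−1)`, because the literal `1−(1−x)²` cancels to exactly
0 in double precision once x < 2⁻⁵³ (N ≳ 55).

Candidates are restricted to reconstructed paths of 1–2 spacers whose
nodes have eccentricity ≤ 2 (the screen separating mini-array components
from long-array fragments). A call requires both P < α (default 0.01) and
the conservative fixed abundance threshold (100 for singles, 20 for
pairs); the principled minimum N that the formulas imply (7 and 9 at
p = 0.5, α = 0.01) is also exposed, but the stricter fixed gate decides.
Note the N = 1 two-spacer P-value is exactly 1, so with a strict
inequality the smallest callable pair abundance is 2 even as α → 1.

## Protospacer mapping and the coincidence test

The spacer-vs-genome matcher is seed-and-extend: exact 8-mer seeds on both
strands, ungapped extension to the full spacer length, hits kept at
identity ≥ 0.85 over the whole spacer (an e-value gate is redundant under
this full-length identity definition and is not computed). A hit therefore
requires that one perfect 8-mer survives; for short spacers at the
identity floor the pigeonhole principle does not guarantee this
(`seed_guaranteed` reports the condition), and the test-suite oracle
encodes exactly the same hit definition, so matcher and exhaustive window
scan agree identically. Overlapping same-strand hits (≥ 50% of the shorter
span) are merged keeping the highest identity. PAM profiles are
positional base frequencies of the 10-nt flanks oriented to the
protospacer strand; the consensus reports a base where its frequency among
non-N observations exceeds 0.5, else N.

Conservation of a two-genome alignment is per-column: a protospacer span
is *conserved* iff every column in it is identical and ungapped in both
genomes (a 50-bp windowed identity track is also emitted for plotting).
The coincidence test simulates `n_sim` = 10,000 spacers at uniform random
alignment starts, lengths resampled with replacement from the observed
spacer lengths, classifies them the same way, and compares the observed
conserved/variable split to the simulated proportions with a chi-square
goodness of fit (df = 1, expected counts scaled to the observed total). A
2×2 contingency chi-square of observed vs simulated counts is reported
alongside, since published analyses of this design are ambiguous about the
variant used; the goodness-of-fit result is primary. Type-I error at
α = 0.05 is calibrated to [0.03, 0.07] over 500 null replicates in the
acceptance suite.

## Spacer tiling

All-vs-all matching connects two spacers when their best shared-8-mer
diagonal (either strand) reaches identity > 0.7 over the *overlap* —
overlap-denominator by design, since spacers tiling a genome overlap only
partially. Each component is laid out along a maximum-identity spanning
tree rooted at the highest-degree node; orientations and offsets propagate
through the tree, and every non-tree edge is checked for consistency. A
conflicting edge splits the component at the weakest conflicting edge
(logged) — this deterministic rule replaces the manual alignment curation
of the original workflow. Consensus is the per-column majority, ties going
to the alphabetically smallest base; on noise-free planted tilings the
consensus equals the source sequence exactly.

## Synthetic communities

The simulator generates the statistical structure the analysis assumes:

* **Hosts.** Each strain carries one long array (≥ 4, default 10–30
  spacers) per requested repeat type; each strain fixes one concrete
  realization of the degenerate consensus (repeats vary between genomes
  but are locally constant). Spacers are unique random sequences of
  32–42 nt (within the 25–60 filter window with margin).
* **Viruses.** Each viral genome (default 3 kb) carries one leader
  (default 120 nt) followed by a mini-array of 1–2 spacers in
  repeat–spacer(–repeat–spacer)–repeat layout, at a random position.
* **Abundances.** Strain abundances come from a log-normal mixture
  (default 3 components at means 30/300/3000, σ = 0.4 on the log scale —
  a multimodal community with rare, intermediate and dominant strains);
  viral abundances are drawn from the top component, emulating the
  dominance of these viruses in enrichment cultures.
* **Reads.** A read is primer + repeat + (spacer+repeat)×k + primer with
  k ∈ {1,2,3} (default probabilities 0.35/0.45/0.20), truncated to 250 nt
  (merged single reads; paired-end merging is not modelled). Read counts
  are multinomial over replicon abundances at fixed total depth (no PCR
  bias model). Substitution errors (default 0.5%) replace a base with a
  uniformly chosen different base; no indels. Quality scores are
  truncated-normal Phred (mean 35, σ 3, floor 2). Chimeras (default 1% per
  junction) switch the template to an abundance-proportionally chosen
  different array, mimicking PCR template switching; the truth table flags
  every chimeric junction and records per-unit provenance.
* **Diverged pairs.** Two genomes at a target alignment identity
  (substitutions only, so the alignment is the positional pairing and the
  realized identity is exact). Divergence is *clustered*: alternating
  conserved/variable blocks (exponential lengths, default 45% variable,
  300 nt mean variable block) receive all substitutions — the block
  structure that makes a ~50/50 conserved/variable span split possible at
  92% identity, as observed between closely related virus strains.
  Protospacer placements weight variable-span starts by an odds ratio.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: PCR efficiency and primer bias, indel
sequencing errors, paired-end merging artifacts, spacers shared between
strains or repeated within arrays, repeat-proximal spacer similarity, and
real phylogenetic structure in spacer sequences.

## Validation scenario sizes

The planted-truth benchmark uses 20 host strains × 1 repeat type (20 long
arrays of 10–30 spacers), 5 viral mini-arrays (sizes 1,2,1,2,2), chimera
rate 1%, substitution rate 0.5%, and a narrow three-mode abundance mixture
(means 300/450/675, σ = 0.2). Read depth is derived *a priori* from a
coverage target rather than chosen by hand: the smallest depth such that
every true adjacency is expected in ≥ 40 read pairs (worst-case terminal
junction) and every mini-array in ≥ 400 reads, with a 15% margin — about
83,000 reads. Against this planted truth the pipeline achieves 100% array
adjacency recovery, removes all chimeric edges with zero true-edge losses,
and calls exactly the five planted mini-arrays at the fixed thresholds.
Oracle-equivalence checks run on 5 kb genomes (protospacer search), 200
random DAGs of ≤ 12 nodes (eccentricity), and 2 kb sequences (motif
scanning); statistical calibration uses 500 null and 100 enriched
replicates on 20 kb diverged pairs at 92% identity with 64 placements
each.

## Known limitations

* Greedy centroid clustering is order-dependent by design (abundance
  order); it reproduces the standard tool's behaviour class, not any
  specific binary's internals.
* Maximal-path enumeration is exponential in pathological branching
  graphs; real pair graphs are near-linear after filtering, but heavily
  contaminated inputs should be filtered first.
* The coincidence test relies on the chi-square approximation; with very
  few observed hits (expected class counts < 5) an exact test would be
  preferable.
* Protospacer extension is ungapped; protospacers with indels relative to
  the spacer are not found.
* The either-rule chimera filter can delete the sole edge of a rare array
  whose head spacer is shared with a dominant array; use `rule="both"`
  when arrays are known to share terminal spacers.
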