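# Methods

## LZ production complexity (lzcore)

A sequence S over {A,C,G,T} is generated step by step from the empty
state.  Each step finds the longest prefix of the remaining suffix that
occurs in the sequence starting at an earlier position — the occurrence
may extend past the current position, i.e. the copy source can run into
symbols being written during the same step (this is what makes `AAAAAA`
parse as `A.AAAAA`) — copies it, and appends the next symbol.  The final
step may end mid-copy and append nothing, but still counts.  `c(S)` is the
number of steps.

The implementation extends each component one symbol at a time with a
C-level substring search over the prefix (`str.find` bounded so that the
occurrence must *start* before the current position), worst-case O(L²); an
independent O(L³) scan over all earlier start positions lives in the test
suite as the oracle, and the two agree on 10⁴ random sequences of length
≤ 30 plus targeted low-entropy repeats.

Input policy: sequences are upper-cased, `U` is mapped to `T` with a
warning, and IUPAC ambiguity codes are rejected by default (silently
enlarging the alphabet would change complexity values); a `strip` policy
deletes ambiguous positions and logs the count.  The empty sequence has
complexity 0 internally but is rejected at every public entry point.

## RCM distance (rcm)

`d(S1,S2) = [(c(S1S2)−c(S1)) + (c(S2S1)−c(S2))] / [½(c(S1S2)+c(S2S1))]`
with plain concatenation (no separator symbol).  The measure is symmetric
and bounded by [0, 2].  The self-distance is strictly positive —
empirically `c(SS) = c(S)+1` on every sequence tested, giving
`d(S,S) = 2/(c+1)` — but emitted matrices write 0.0 on the diagonal, which
both neighbor joining and the PHYLIP square format require; the matrix
writer documents the discrepancy.  Only this normalisation is implemented;
a registry seam (`DISTANCE_FUNCTIONS`) exists for alternative RCM
normalisations, which historically produce the same topologies.

The matrix builder computes each single-sequence complexity once and each
ordered concatenation once; results are identical to independent pairwise
calls (tested), so pairs could be evaluated concurrently without changing
output.

## Perturbation resampling (perturb)

Counts: `n_total = round(k·L)`; `n_del = n_ins = round(n_total/3)`;
`n_sub = n_total − 2·n_del`.  This satisfies all three constraints that
define the scheme — equal thirds up to rounding (|del−sub| ≤ 1,
|sub−ins| ≤ 1) and del == ins, which together with the pool mechanics force
exact length and base-composition conservation.  Totals of 1 or 2 are
rejected so each mutation class gets at least one event; in practice this
means the 1% level needs sequences of ≳252 bp.

Phases act on the evolving sequence in order: distinct uniform positions
are deleted into the pool; distinct uniform positions are swapped with
uniformly drawn pool bases (no rejection — a draw may silently reproduce
the resident base, which keeps the composition bookkeeping unbiased); the
pool is then drained one base at a time into independent uniform slots
(L+1 choices on the current sequence).  Conservation is enforced by hard
assertions on every call, not only in tests.

Randomness: `numpy` `SeedSequence` substreams keyed by
`(plan seed, replicate index, crc32(sequence id))`, so any single replicate
of any sequence regenerates in isolation and one sequence's replicates are
unaffected by the rest of the dataset.

## Trees (phylo)

*Container*: `dendropy.Tree`.  All comparisons run on canonical
bipartitions (side not containing the smallest leaf label, trivial splits
excluded), computed by a single postorder pass.

*Neighbor joining*: standard Saitou–Nei Q-criterion with the usual
branch-length formulas; ties broken deterministically by the lowest
(row, column) pair in working order (row-major argmin).  Negative branch
lengths are reported as computed — hiding them would hide a real property
of distance-based reconstructions on non-additive matrices; an optional
clamp zeroes a negative length and moves the difference to the sibling
branch of the same join (in the terminal 3-branch join, to the longest
branch).  On additive matrices NJ recovers topology and branch lengths to
1e-9 (tested on 100 random 5–20-taxon trees); on noisy matrices it matches
scikit-bio's independent implementation topologically.

*Robinson–Foulds*: symmetric difference of bipartition sets; `normalized`
divides by 2(n−3).  Verified against two independent routes: networkx
edge-removal connectivity and dendropy `treecompare`.

*MRe consensus*: splits in > 50% of trees, then remaining splits in order
(count descending, ties by sorted label tuple — the documented greedy
order) added when compatible with everything retained.  Compatibility in
the canonical representation is nested-or-disjoint.  The tree is assembled
by nesting clades largest-first; each internal node's label is the split's
occurrence count.  Retained splits are asserted pairwise compatible on
every call.  Consensus trees may be multifurcating; RF on them counts only
resolved splits.

## Sequence evolution (evolve)

Generators are built analytically — K2P with transition/transversion rate
ratio κ (default 2.0, a typical plant-marker value), F84 with frequency
vector π and within-group bias κ — normalised to one expected substitution
per site per unit branch length, and exponentiated per branch
(`scipy.linalg.expm`; the textbook K2P closed form is the test oracle, and
F84 detailed balance π_i P_ij = π_j P_ji holds to 1e-10).  The root is
drawn i.i.d. from π with deterministic length by default (`length_jitter`
adds ±5%-style uniform jitter).

Indels: per branch, Poisson(indel_rate·L/2) deletion and insertion events,
geometric lengths (mean 2), uniform positions; inserted bases are drawn
from π.  Every site carries a homology key (an exact `Fraction` position
plus a uniqueness counter), so the returned alignment is the one implied
by the logged history; ordering of non-homologous insertions in the same
slot is arbitrary but deterministic.  The pipeline itself never uses the
alignment — it exists so alignment-based methods can be benchmarked
externally on identical data.

The **rose-like preset** is this package's stand-in for the historical
benchmark generator it emulates in simplified form (site-homogeneous
rates, geometric indels): balanced 16-taxon topology, mean length 500,
indel_rate 0.01, and the per-edge branch length solved (brentq on the
analytic p-distance) so sister leaves have 95% expected substitution
identity — a low-divergence regime.  F84 uses mildly AT-rich frequencies
(0.3, 0.2, 0.2, 0.3).  Under this preset RCM+NJ recovers the true topology
essentially always (the benchmark means the acceptance script prints are
0.0 at 200 families per model); the preset is an approximation of an
external simulator whose exact defaults are not public, so benchmark
numbers are comparable in design but not calibrated to reproduce any
particular historical figure.

## Experiment drivers (cli_workflow)

Both pipelines stream one replicate/family at a time, derive all
randomness from one master seed through named substreams
(master → per-rate/per-model → per-replicate → per-sequence), refuse to
overwrite non-empty output directories without `force`, and write a JSON
manifest (version, config, config hash, resolved seeds) sufficient to
reproduce the run byte-for-byte — manifests deliberately contain no
timestamps.  Failures abort with the stage name and replicate index.
Logging goes to stderr only.

## Problem sizes and what the tests show

The test suite runs the benchmark at 200 families per model (16 taxa,
length 500) and the robustness experiment on one simulated 16-taxon family
of length 300 with 100 replicates per rate across 5 seeds — sizes chosen
as desk-scale versions of the full designs (2000+ families; 1000
replicates on 506–817 bp markers).  Passing them shows the machinery is
correct and the qualitative behaviour (monotone degradation with mutation
rate, consensus stability at low rates, near-perfect recovery in the
low-divergence regime) is right; it does not certify accuracy on real
markers, whose composition bias, rate heterogeneity and indel structure
the simulator does not model (no gamma rates, no codon structure, no
context-dependent indels).

## Known limitations

- Complexity-based distances lose signal on very short sequences (the
  vocabulary is too small); the measure is intended for ≳100 bp.
- The RCM self-distance/diagonal mismatch is a convention, documented
  above.
- MRe greedy order among equally frequent splits follows this package's
  documented tie-break; other implementations may retain a different (but
  equally valid) compatible set.
- The simulator's indel process is not calibrated against any empirical
  indel model; it exists to make lengths vary realistically, not to study
  indel evolution.
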