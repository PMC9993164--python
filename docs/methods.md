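# Methods

## Model and estimands

`symdelta` treats a dataset as M joint observations of N discrete
variables and asks, model-free, which small tuples of variables are
statistically interdependent. All quantities are functionals of the
empirical (plug-in) joint distribution of a tuple, expressed through
Shannon entropies in bits:

- `H(S) = −Σ p log2 p` over the non-empty cells of the joint count table
  of variable subset S (0·log 0 = 0).
- Mutual information `I(X,Y) = H(X) + H(Y) − H(X,Y)`.
- Interaction information by McGill's recursion,
  `I(X,Y,Z) = I(X,Y) − I(X,Y|Z)` and
  `I(W,X,Y,Z) = I(X,Y,Z) − I(X,Y,Z|W)`; implemented through the
  equivalent alternating inclusion–exclusion over subset entropies
  (+ for odd-sized subsets, − for even). Under this sign convention a
  balanced XOR triple yields I3 = −1 bit and a balanced four-way parity
  yields I4 = +1 bit; both identities are fixed by brute-force oracles in
  the test suite, not assumed.
- Asymmetric delta `ΔX = I(X,Y,Z) − I(Y,Z)`: the change in interaction
  information from adding the target variable.
- Symmetric delta `Δ̄ = ΔX·ΔY·ΔZ` (bits³), and the four-variable product
  analogue D4 (bits⁴). Δ̄ vanishes whenever any tuple variable is
  independent of the rest; searches rank by |Δ̄|, preserving the sign in
  output (negative three-way values = synergy).

Delta products are taken in bits. The unit choice propagates into D3/D4
magnitudes (a nats convention would rescale them by ln2 per factor); MI
values are unit-checked against published genotype contingency tables,
delta magnitudes are a documented convention.

No bias correction is applied (plug-in estimates throughout); negative
MI of floating-point origin is clamped to zero only in written output,
never inside delta arithmetic, where exact cancellation matters.

## Missing data

Missing entries (sentinel −1, configurable) are handled per tuple by
complete-case restriction: a sample contributes to a tuple's counts only
if it is observed in *every* variable of that tuple, giving the tuple's
effective sample size n. All entropy terms of one measure — including
marginals — are computed on this shared effective sample set, keeping
every term of the measure on a single probability space (and preserving
MI ≥ 0). A variable's bin count B is inferred over the whole variable
(max code + 1), so a symbol absent from some restriction still occupies
a cell of the distribution; empty cells contribute nothing.

Whether marginals should instead use each variable's own observed
samples is genuinely open; the shared-space convention was chosen
because it is the only one under which the measure identities above hold
exactly, and it reproduces the pattern of per-SNP effective-n variation
seen in published contingency tables.

## Counting engine

Two interchangeable algorithms produce identical joint count tables
(cross-checked cell-for-cell by a 200-case randomized property test):

- **bitset** — each variable is recast as B presence bitsets of length M
  packed into 64-bit words (bit i of plane b set iff sample i has code
  b) plus a validity bitset; a joint cell is the popcount of the AND of
  one plane per variable. The pass count for a d-tuple is Π Bᵢ, each
  pass linear in M/64 words; tail bits beyond M are kept zero.
- **vector** — one pass over samples accumulating a flattened histogram,
  skipping samples missing in any restriction variable.

`auto` picks bitset when Π Bᵢ · ⌈M/64⌉ is small relative to M, vector
otherwise. Joint entropies are memoized in a per-worker LRU cache
(default 2²⁰ entries). The cache key is the sorted subset indices plus
the sorted indices of restriction variables that actually carry missing
values — exactly the information that determines the value — so a cache
hit is always bit-identical to a fresh computation, and entries are
shared across tuples whenever their complete-case masks coincide.

## Search space and parallelism

A TupleSpace is built from named, pairwise-disjoint variable groups and
ordered templates of group slots (orders 2–4). Distinct-group slots
enumerate their cross product in row-major order (last slot fastest); a
run of slots repeating one group enumerates strictly increasing member
combinations, since the measures are permutation-symmetric and ordered
duplicates would only repeat work; mixed templates combine both rules.
A group may repeat only in adjacent slots — non-adjacent repetition is
rejected rather than given ad-hoc semantics, which also guarantees no
tuple contains a variable twice. Multiple templates concatenate in
listed order.

The enumeration is a strict total order with O(d) unranking (mixed-radix
across blocks, combinatorial within a block), so the space partitions
into contiguous, equally sized (±1) working sets and each worker can
seek directly to its start: no inter-worker communication, no shared
state (each worker owns its entropy cache). Workers are threads; the
merge sorts by (|value| desc, tuple rank asc), making output
bitwise-identical for any worker count — asserted for 1, 2 and 7
workers, and for cache on vs off.

Tuples whose effective sample set is empty are excluded from results and
counted in a skipped-tuples log line; scored + skipped always equals the
space's tuple count.

## Permutation significance

For the top of a ranking (default: top 200), p-values come from
shuffling designated variables over the full sample vector (missing
entries ride along, preserving each variable's missingness pattern
marginally; the complete-case mask is re-derived per permutation).
Non-designated variables are untouched, so their mutual joint counts —
e.g. linkage between genotype variables — are preserved exactly.
Designated variables are shuffled independently of one another: for a
pairwise phenotype scan the phenotype alone is permuted; for an anchored
three-way screen, phenotype and anchor are each permuted, testing the
null that large deltas cannot arise from arbitrary *pairwise* structure
among the three.

The estimator is `p = (b+1)/(n+1)` with tail "statistic ≥ observed" for
MI and "|statistic| ≥ |observed|" for the deltas (matching the magnitude
ranking); its floor at n = 10,000 permutations is 1/10001 ≈ 0.0001, and
under a true null it is uniform (checked by a Kolmogorov–Smirnov screen
over 500 replicates at n = 99). Each tuple uses an RNG substream derived
from the master seed and the sorted tuple indices, so p-values are
independent of evaluation order and worker count. P-values are
unadjusted for multiple testing — the tool's output is an exploratory
ranking. Re-sorting after attachment is by (p asc, |value| desc), so
floor-p ties order by signal strength.

## Synthetic data

Two generators make every stage testable without restricted data. They
define the package's study conditions; their defaults are fixed here and
not tuned per experiment.

**Functional-dependency test set** (default 90 variables × 1,000
samples): one third strong pairs, one third weak pairs, one third XOR
triples. A pair is X uniform on {0,1,2} and Y = (2X) mod 3 — `f(X)=2X`
realized as an injective relabeling, since information measures see
symbol identity, not arithmetic — with Y symbols corrupted at rate 0.05
(strong) or 0.30 (weak) by uniform replacement. A triple is X, Y uniform
binary with Z = XOR(X,Y) corrupted at 0.05. The noise rates and sample
size are package defaults chosen so the three blocks separate cleanly in
ranking while the weak block stays visibly noisier than the strong one.
A manifest of planted relationships accompanies the data; recovery tests
are manifest-blind searches.

**Genotype screen** (default 2,778 cases + 2,778 controls × 1,000 SNPs):
genotypes coded 0 = major homozygote, 1 = minor homozygote, 2 =
heterozygote, −1 missing; background SNPs drawn per-sample under
Hardy–Weinberg at minor-allele frequencies uniform on [0.05, 0.5];
entries masked missing at rate 0.01. The anchor SNP's allele frequency
is shifted ±0.15 between cases and controls (a strong marginal
association, MI ≈ 0.1 bits). The modifier is purely epistatic: with
phenotype S and anchor carrier status A, its carrier probability is
c ± d·(1−α_S) for carriers and c ∓ d·α_S for non-carriers (c = 0.30,
d = 0.15, α_S the realized carrier rate given S, sign flipping with S).
The α-weighted offsets make the modifier's phenotype marginal exactly
flat — pairwise modifier–phenotype MI is ~0 in population — while the
anchor-conditional dependence flips with phenotype, the XOR-like pattern
the three-way delta exists to detect. Offsets bounded by ±d keep the
construction feasible for any realized α. Setting d = 0 reduces the
modifier to background (null calibration).

Neither generator models linkage disequilibrium, population
stratification, covariates, or genotyping-error structure; passing
recovery tests therefore demonstrates the engine's sensitivity to
planted dependence under clean sampling, not robustness to confounding
in real cohorts.

## Problem sizes and numerics

The packaged experiments run at desk scale: the recovery experiments
scan 435-to-4,060-tuple spaces; the modifier-screen experiment uses
5,556 samples × 1,000 SNPs over 50 replicate seeds; permutation
calibration uses 500 replicates × 99 permutations. The combinatorial
machinery itself is exact at any scale (tuple-count arithmetic is tested
at the 10¹¹-tuple order); only the scoring work scales with the space.

Exact identities (XOR deltas, factorizing-joint zeros, permutation
symmetry) are asserted to 1e−12; cross-route equalities (entropy
expansion vs conditional decomposition) to 1e−10; published MI
reproductions to 1e−6 absolute, their printed precision. Ties in
rankings break by tuple rank for determinism. Degenerate inputs have
defined behavior: empty effective sample sets raise for single measures
and are skipped-and-counted inside searches; all-missing variables
produce all-zero bitplanes; single-cell tables have zero entropy.
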