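# Methods

## Model

Each single-end read is split into a fixed-length UMI prefix `b_i` and a
sample sequence `r_i` (a two-file UMI/detagged arrangement is also
accepted). Reads are modeled as independent draws from a one-step hidden
Markov chain: hidden state 1 is the true UMI `u_s` (probability `η_s`),
hidden state 2 the haplotype `h_k` attached to it (probability `γ_sk`), and
the two observations are noisy emissions of `u_s` and `h_k`. In a perfect
experiment Γ is a 0/1 matrix — one haplotype per UMI; UMI collisions and
highly amplified early PCR errors manifest as rows with two or more
positive entries. Fitting maximizes the observed log likelihood minus the
penalty `ρ Σ log(1 + γ_sk/ω)`. With `ω = 1e-20` the penalty is ℓ0-like:
each positive transition pays a roughly constant cost `ρ·log(1/ω)`, so a
transition survives only when the reads it explains contribute more — in
practice, when its expected amplified read count `c_sk = Σ_i e_isk` exceeds
`ρ`. ρ is therefore interpretable as the molecular count that separates
error molecules from real ones.

Assumptions worth stating plainly: reads are exchangeable given the pools;
every true molecule was sequenced without error at least once (used to
restrict Γ's support, see Approximations); errors before UMI tagging
(e.g. cDNA synthesis) are invisible to the model; chimeras are not modeled.

## Emission model

`Pr(X | Y)` factorizes into an indel term and per-column substitution
terms over the global alignment of observed `X` to candidate `Y`:

* Indels: the number of indel *events* `d` (maximal gap runs) follows a
  Poisson with mean `δ·l` (`l` = alignment length), truncated at
  `d_max = 4`; indel events beyond 4 per read are negligible at the
  per-position rates seen in Illumina amplicon data (~2e-5). Indel columns
  contribute substitution probability 1. UMIs are emitted indel-free
  (`d = 0`): they are short, early-read, high-quality segments.
* Substitutions: `Pr(X_j | Y_j; q_j)` is a 4×4×quality table. The default
  is PHRED-consistent (`Pr(correct) = 1 − 10^(−q/10)`, error mass split
  evenly over the three alternatives, error probability capped at 0.75).
  The estimated table tallies (true, observed, quality-bin) events with
  add-one smoothing from UMI-defined clusters, using quality bins of width
  2 to control sparsity; bins with no real observations for a given true
  base fall back to the PHRED default at the bin's representative quality
  so emissions stay quality-aware outside the sampled range. `δ` is
  estimated as total indel events over total aligned positions.

Alignments use unit-cost edit distance. The banded dynamic program breaks
ties deterministically (diagonal over deletion over insertion on
traceback), so emissions are reproducible. Two fast paths keep the
quadratic DP off the hot loop: equal-length pairs whose edit distance
(edlib) equals their Hamming distance take the gap-free alignment, which is
what the tie-breaking would select anyway; and equal-length pairs more than
16 mismatches apart are aligned gap-free without the edit-distance check.
The latter is an approximation — unrelated random sequences usually admit
a slightly cheaper gapped alignment — but at that divergence the emission
is below e^-100 under either alignment and contributes nothing to any
posterior; treating it as substitutions keeps the batched and per-pair
code paths bit-identical.

## Candidate pools and initialization

Both pools come from a greedy expected-misread denoiser. Distinct observed
sequences are scanned in decreasing abundance (ties lexicographic); a
candidate with observed count `m` is admitted unless `m` is attributable to
misreads of already-accepted neighbors. The expected misread count `E` sums
the emission probability of the candidate given each accepted neighbor
within edit distance 4, evaluated at each of the neighbor's exact-match
reads' qualities. Attribution is judged by a one-sided Poisson tail:
the candidate is kept iff `P(Poisson(E) ≥ m) < α` with `α = 1e-3`
(an over-dispersion factor scaling `E` is exposed for data whose quality
scores underestimate error). A fixed count threshold would either reject
every rare sequence or accept every replicated error; the tail test adapts
to how much error mass the neighborhood actually produces.

* UMIs are denoised with the PHRED-default table and indel-free emissions
  (minimum abundance 1 — liberal acceptance is intended, since quality
  scores tend to understate error).
* The error profile is then estimated from reads clustered by accepted
  UMI (each read to its maximum-emission UMI; ties to the more abundant,
  then lexicographic). Clusters whose runner-up sample sequence exceeds
  half the modal sequence's count are split once as suspected collisions:
  both sequences become centers and members join the closer center by
  Hamming distance, the more abundant on ties. Cluster centers
  (UMI + modal sequence) must be replicated at least twice so centers are
  error-free; all member/center differences are counted as errors.
* Haplotypes are denoised over distinct *full* reads (UMI + sequence,
  minimum abundance 2) with the estimated profile and indel-capable
  emissions; accepted full reads are stripped of the UMI and deduplicated.
  The pool is deliberately liberal: replicated PCR errors that survive it
  are eliminated later by the penalty unless their amplified counts truly
  exceed ρ. Both pools can be replaced by user-supplied sized FASTA files.

Mixing proportions initialize to relative exact-match UMI counts; Γ rows
initialize to observed exact transition counts restricted to admissible
pairs, row-normalized (uniform over admissible entries if a row has no
exact counts).

## Approximations in the fit

* **Admissible pairs.** `γ_sk ≡ 0` unless some read shows `u_s` and `h_k`
  both error-free — justified because per-base error rates are well below
  0.1%, so every true molecule is observed exactly at least once at
  realistic depth.
* **Top-T posteriors.** Per read, only the `T` (default 10) largest
  posterior entries are kept and renormalized (ties at the cutoff are all
  kept). Raising T to 30 does not change estimates in simulation, which the
  test suite checks.
* **Row exclusion.** UMIs whose mixing proportion reaches exactly 0 are
  removed from the model as error UMIs.

## EM details

The E step computes `e_isk ∝ η_s Pr(b_i|u_s) γ_sk Pr(r_i|h_k)` over
admissible pairs in log space; emissions are precomputed once since the
pools are fixed. A read whose admissible mass underflows entirely is
retained through its best-available pair with a warning rather than
dropped, preserving abundance.

The M step updates η by unpenalized expected counts (only Γ is penalized)
and solves each Γ row exactly: maximizing
`Σ_k c_k log γ_k − ρ Σ_k log(1 + γ_k/ω)` on the simplex gives the
per-component stationarity quadratic
`λγ² + (λω + ρ − c)γ − cω = 0` whose positive root (computed in a
cancellation-stable form) is summed and the Lagrange multiplier λ solved by
Brent root-finding. Components whose solution lands at the ω boundary
(below 1e-10) are clamped to exact zero and the row renormalized; in the
ω→0 limit this reduces to `γ_k ∝ max(c_k − ρ, 0)`. When every count in a
row is at or below ρ, the row keeps its argmax component — a UMI that
exists must explain its reads — and this one-hot row is also the exact
constrained maximizer in that regime (verified against a simplex grid
search in the tests). Clamping can only raise the penalized *observed*
likelihood (the penalty gradient −ρ/ω dominates near zero), and the trace
is monitored: with T covering all pairs it is nondecreasing within 1e-6,
asserted in the tests.

Convergence: relative change in penalized observed log likelihood below
1e-6, at most 1000 iterations; iteration order is deterministic (reads in
input order, pairs in (s,k) lexicographic order) so runs are
bit-reproducible.

Deduplication discards UMIs with expected abundance `n·η̂_s < 1`, calls
transitions positive above `γ_tol = 1e-9` (a pure numerics guard — sub-ω
entries were already clamped to exact zero), and counts one molecule per
positive (UMI, haplotype) link. `ncollision` collapses each row to its
argmax (ties: larger expected count, then lower haplotype index).

## Automatic penalty selection

The observed exact-match count of a true UMI is modeled as a Galton–Watson
branching process with sequencing loss: per cycle each copy duplicates
with efficiency λ (offspring pgf `z(1−λ+λz)`), and the final copies are
thinned binomially by the read-sampling rate and again by the probability
that a sequenced copy escapes its UMI's exact-match tally through an error
anywhere in the read. The pmf is computed exactly by composing the
offspring pgf over cycles (polynomial coefficients; feasible to 14 cycles)
and marginalizing the binomial thinning; a seeded Monte Carlo path covers
larger cycle counts and cross-checks the exact path in tests.

The two thinning stages compose into one effective keep probability, so
only `(λ, keep)` are identifiable from abundances; the error-escape
probability is held at a user-supplied constant (default 0) and the sample
rate back-solved. Fitting minimizes the Kolmogorov–Smirnov statistic
between the model CDF and the empirical CDF after right-truncating the
`⌈(1−q)·N⌉` largest abundances (default q = 0.95) — the long right tail is
dominated by UMI collisions the branching model does not describe. Observed
abundances are necessarily ≥ 1, so the model CDF is conditioned on
detection; calibration data containing zero counts are compared
unconditionally, which substantially sharpens the identifiability of λ
(the zero class carries most of the information at low coverage). The
search is a λ grid (step 0.05) crossed with a multiplicative grid of keep
rates centered on the method-of-moments value, then a bounded local
refinement of the keep rate; the refinement can only improve the grid
optimum. The cycle count comes from experiment metadata (flag, default
10): fitting it jointly with λ is disabled because the two form a ridge.

ρ is the smallest count whose fitted CDF conditional on detection reaches
0.05 (never below 1): molecules amplified less than the fifth percentile
of real molecules are indistinguishable from error at this operating
point. Fewer than 20 candidate UMIs refuse the fit and request a manual
`--rho`. The selection is moderately consequential — too high merges
similar haplotypes under collisions, too low over-splits PCR errors — so
the CLI reports the fit (parameters, KS statistic, fitted-vs-empirical CDF
table) for inspection.

## Simulator

The generator reproduces the assumed data-generating process end to end
with a complete truth table (per-molecule UMI and haplotype, per-haplotype
sampled counts, collision pairs, per-read source molecule):

* Relative abundances of K = 25 haplotypes from the density ∝ x^(−0.5) on
  (0,1] (inverse-CDF: `X = V²`), normalized; 400 founder molecules drawn
  multinomially; 9 bp UMIs drawn distinct, and — for collision scenarios —
  resampled with replacement before attachment.
* PCR: per cycle every molecule duplicates with probability `efficiency`
  (default 0.6, 10 cycles) and each new copy mutates per base with
  substitution-specific per-cycle rates. Published per-cycle polymerase
  rates span 1e-4–1e-6 depending on the substitution; defaults are 1e-4
  for transitions and 1e-5 for transversions, tunable as a full 4×4 matrix.
* Sequencing: reads of fixed length 250 drawn uniformly with replacement
  from the pool; per-position mean quality follows a logistic decay from
  Q38 to Q30 along the read (plus integer jitter, sd 2) as a parametric
  stand-in for empirical MiSeq profiles; substitution errors are realized
  at the quality-implied rates, so reported qualities are honest; indels
  at 2e-5 per position; reads re-padded/truncated to fixed length after
  indels. A `seq_error_scale` knob decouples realized errors from reported
  qualities (0 gives error-free reads with realistic quality strings) for
  exact-recovery testing.
* Presets `sim1`–`sim4` differ in the collision flag and sequencing depth
  (10k/20k reads); exact per-scenario PCR settings of the original
  experiments are not public, so the presets are labeled approximate.

What the simulator does *not* emulate — and what passing tests therefore
do not establish about real data: chimera formation; context-dependent or
position-dependent polymerase error; real instrument quality profiles and
miscalibrated quality scores; primer artifacts; variable read lengths;
haplotypes as similar as real within-host viral variants (simulated
haplotypes are independent random sequences, far apart in edit distance —
the collision tests therefore probe the machinery, not the hardest
similar-sequence cases); and pre-tagging (cDNA) errors, which no UMI
method can see.

## Problem sizes and numerical choices

The test suite runs the full pipeline at 2,500–6,000 reads with 100–400
molecules — deep enough that every molecule is sequenced several times and
the collision structure of the 400-molecules-on-253-tags regime appears,
while keeping the whole suite under a minute of compute. Key constants:
`ω = 1e-20`; `γ_tol = 1e-9`; M-step clamp 1e-10; `d_max = 4`; EM tolerance
1e-6, max 1000 iterations; denoiser significance `α = 1e-3` and neighbor
radius 4; quality bins of width 2; gap-free treatment beyond 16 mismatches;
alignment band `max(length difference, edit distance, 4) + 1`.

## Known limitations

Early-cycle PCR errors amplified above ρ are reported as haplotypes (and,
when sharing a tag with their parent, as collisions) — they are
statistically indistinguishable from real molecules without an explicit
PCR lineage model. Collisions between identical haplotypes are invisible
(the same (u, h) link). The branching-model fit assumes a single global
efficiency; per-molecule amplification bias fattens the abundance
distribution and is only absorbed, not modeled. η is unpenalized, so the
UMI pool can stay overpopulated on very clean data. Memory in the E step
is O(n × admissible pairs), comfortable at amplicon scale but not designed
for tens of millions of reads.
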