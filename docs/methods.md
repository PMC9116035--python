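# Methods

## The channel model

A DNA data storage experiment stores a file as M short designed sequences
(references). Physically each reference exists as many molecules, and every
processing step both mutates molecules and reshuffles how many copies of each
molecular species survive. `dnachannel` therefore represents the pool per
reference as a *variant table*: a set of distinct edited versions of the
reference (canonical edit lists) with copy numbers, and builds every stage
from two primitives:

* **Error generation (E)** — each molecule independently acquires new
  substitutions, deletions and insertions at flat per-base rates
  (`ErrorRates`: a 4x4 substitution matrix plus deletion/insertion
  probabilities). The per-reference total copy number is conserved exactly,
  which is asserted on every call.
* **Distribution change (D)** — every variant's copy number is replaced by an
  independent draw from a stage-specific law (binomial thinning, branching
  amplification, ...). A reference whose total reaches zero is lost.

The full channel is the composition

```
synthesis -> decay -> PCR -> sampling -> sequencing
```

with per-stage laws:

| stage      | copy-number law                              | new errors            |
|------------|----------------------------------------------|-----------------------|
| synthesis  | Binomial(mean_depth * M, 1/M) per reference (or negative binomial / constant) | synthesis rates |
| decay      | Binomial(n, survival)                        | damage substitutions  |
| PCR        | per cycle n <- n + Binomial(n, e_i); e_i ~ N(eff, bias_sigma) clipped to [0,1], drawn once per reference | none |
| sampling   | Binomial(n, ratio)                           | none                  |
| sequencing | multinomial read allocation over molecules, budget depth x (surviving refs) | platform rates |

Design notes on the non-obvious choices:

* **PCR normalization.** Amplification multiplies the pool by roughly
  (1+eff)^cycles, but downstream steps (an aliquot taken into sequencing
  prep) are defined against the physical scale of the tube, not the raw
  product. With `normalize=True` (default) the amplified pool is binomially
  diluted back to its input total, so PCR contributes *relative* skew between
  sequences — the per-reference efficiency e_i — without inflating the scale.
  With `normalize=False` the stage is pure branching growth (efficiency 1
  doubles counts exactly each cycle).
* **Sampling as thinning.** Independent binomial thinning approximates the
  exact hypergeometric aliquot; at pool sizes orders of magnitude above the
  sample the two are indistinguishable, and thinning is linear in the number
  of variants.
* **Sequencing coverage skew.** The read budget is shared globally in
  proportion to copy numbers, so poorly amplified/sampled references receive
  proportionally fewer reads — the mechanism behind the lost-count versus
  depth curves.
* **Error-generation algorithm.** For each variant the no-new-error fraction
  is drawn in a single binomial; only mutated molecules are materialized.
  The number of new edits per mutated molecule is Binomial(L, q̄) conditioned
  on >= 1 (q̄ = mean per-base event probability), positions are drawn without
  replacement (uniformly for flat rates, proportionally to per-base rates
  otherwise), and the event type uses the local base's normalized masses.
  For the uniform-rate presets this is distributionally identical to a
  per-base, per-molecule simulation; for base-dependent substitution rows the
  per-molecule edit count uses the mean rate (a stated approximation).
  Events colliding with existing edits follow deterministic merge rules
  (deletion supersedes substitution; events on deleted positions are
  discarded; duplicate insertions at a slot are discarded).
* **Edit coordinates.** All edits are 0-based in original-reference
  coordinates and applied substitutions -> deletions -> insertions, so edit
  lists have a unique canonical form (stable-sorted by position then op;
  same-position insertions keep their left-to-right order).

## Consensus and the two error classes

Reads are voted position-wise per reference. Only reads whose length equals
the reference length enter the vote (positional voting is ill-defined across
lengths; an alignment-projection mode exists but is off by default). Position
ties break deterministically in A<C<G<T order — arbitrary but replayable.
Two final error classes result: a reference with no qualifying reads is
**lost** (N_l); a position where a wrong base outvotes the true one is a
**voting error**, summarized as histograms N_e(i) both per base and per byte
(4 nt = 1 byte at 2 bits/base, the unit Reed–Solomon capacity is counted in).
`sum_i N_e(i) + N_l = M` is exact on every run.

## Redundancy planning

For a fountain + RS encoding (M chunks -> (1+alpha)M droplets, L_RS parity
bytes per strand correcting floor(L_RS/2) byte errors):

* Information density at byte-correction capacity k (L_RS = 2k):
  `D(k) = (L_d / (L_d + 2k)) * (N / ((1+beta)N + N_l + tail_k))`, with
  `tail_k` the discarded sequences. The capacity rule discards byte-error
  counts *strictly above* k (`tail_mode="capacity"`, default); the variant
  that also discards exactly-k-error sequences is available as
  `tail_mode="printed"`. L_RS = 2 argmax_k D(k), ties to the smaller k.
* Total lost N_tl = N_l + #(sequences with byte errors > floor(L_RS/2)),
  fitted across replicates as Poisson (MLE lambda = mean, with a Pearson
  diagnostic), rescaled per overhead as lambda = p_tl (1+alpha) N.
* Droplets-needed samples (1+beta)M are fitted with a right-skewed Gumbel
  (maximum likelihood; Anderson–Darling statistic attached). Permitted lost
  (alpha-beta)M = (1+alpha)M - (1+beta)M is the reflection of that fit,
  discretized as pmf(j) = CDF(j+1/2) - CDF(j-1/2) on [0, T_max]; T_max
  defaults to the 1-1e-6 quantile of permitted lost. Truncated upper-tail
  mass counts as success (losses there are astronomically unlikely to exceed
  it); permitted-lost mass below zero — a decode infeasible even with no
  losses — counts as certain failure.
* Failure probability: decoding fails when the lost number exceeds the
  permitted number, `p_f(alpha) = sum_j f_perm(j) P[N_tl > j]`. p_f is
  non-increasing in alpha for fixed fits, so the acceptable region is the
  contiguous grid range with p_f <= 1 - target.
* **Decoding-overhead floor.** The bundled inactivation decoder needs only
  ~0.1% droplet overhead, so planning on the fitted beta alone would assume a
  maximally thrifty decoder. The planner uses beta = max(min_beta, fitted)
  with `min_beta = 0.05` by default — a 5% decoding margin; `min_beta=0`
  plans on the fit alone.

## The fountain fixture

The synthetic-data machinery is self-contained: a deterministic
pseudo-random file generator; an LT encoder with a robust-soliton degree
distribution (c = 0.05, delta = 0.05 defaults) whose droplets derive their
degree and member set from a 32-bit seed through a documented PRNG (numpy
PCG64); and two decoders — pure peeling, and the default *inactivation*
decoder that augments peeling with GF(2) elimination of the stalled residual
system (the strategy of production fountain decoders). Pure peeling at
M ≈ 2000 needs 9–13% droplet overhead regardless of soliton parameters,
which says more about belief propagation at this scale than about the
channel; the inactivation decoder's overhead is ~0.1% and both yield
right-skewed droplets-needed samples. Droplets map to DNA at 2 bits/base
(A=00, C=01, G=10, T=11, MSB first) as 4-byte seed + payload + L_RS parity
bytes. The parity bytes are deterministic placeholders, not true RS
codewords: error handling is modelled by capacity counting
(`rs_recoverable`), exactly the granularity the planner needs.

## The default study

`dnachannel.study` wires the reference experiment used by the tests and the
acceptance script: a 40960-byte pseudo-random file in M = 2048 chunks of 20
bytes, encoded into 2048 strands of 104 nt (4-byte seed + 20-byte payload +
2 parity bytes). Channel defaults: synthesis mean depth 5000 (binomial) with
sub/del/ins rates 4e-3 / 3.5e-3 / 5e-4 (array synthesis, deletions
dominant); decay survival 0.99 with 2e-3 damage substitutions; PCR 12
normalized cycles at efficiency 0.8 with per-sequence bias s.d. 0.015;
sampling ratio 0.001 (≈5 sampled copies per sequence); short-read sequencing
at mean depth 10 with sub 2e-3 and indels 2e-4 (a Nanopore-like high-error
preset also ships). Per-stage rates are editable placeholders chosen inside
published ranges so that the channel operates in the regime the model is
meant to probe: ~0.8% of sequences lost after the sampling bottleneck, an
error profile dominated by single-byte voting errors (so the density scan
prefers L_RS = 2 at a peak near 76%), and a 99%-success overhead near
alpha ≈ 0.25. They are not measurements of any specific platform.

Problem sizes in the test suite and acceptance script (10 replicates at
M = 2048 for the channel studies, 10 at M = 1024 for the alpha-selection
check, depths 40–60 for the convergence study) were chosen as the smallest
runs at which the replicate means stabilize.

## What the synthetic data does and does not capture

The generator reproduces the *structure* of storage-channel noise — copy
number skew and loss through bottlenecks, error accumulation across stages,
voting-error formation at low effective depth — under flat per-base rates
and independent molecules. It does not model sequence-context effects
(homopolymers, GC bias in synthesis or PCR), per-position rate profiles,
PCR chimeras, primer regions, strand orientation, or clustering/index
decoding (read-to-reference linkage is ground truth). Passing tests
therefore validate the machinery and its statistics, not the fidelity of
any particular laboratory protocol; fitting stage parameters to real
sequencing data is out of scope.

## Numerical and degenerate-input conventions

All randomness flows from explicit `numpy.random.Generator`s; composed runs
spawn one child per stage from a `SeedSequence`, so any stage or replicate
replays independently. Degenerate droplets-needed samples fall back to a
point mass (with a warning). Counts are exact integers throughout; PCR
counts are capped at a configured ceiling (1e15) with a warning. Voting and
tie-breaking, diff tie-breaking (match > substitution > deletion >
insertion, leftmost), and edit-set merge rules are all deterministic, so a
(config, seed) pair reproduces outputs byte-for-byte.
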