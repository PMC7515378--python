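# Methods

## Ordinal symbolization

A series x(1..N) is embedded with unit delay into the N−d+1
overlapping vectors X(i) = (x(i), …, x(i+d−1)). The ordinal pattern of
a vector is the permutation of positions 1..d that sorts it into
non-decreasing order; ties are broken by original position (stable
sort), so (4, 5, 4) → (1, 3, 2) and a constant vector maps to the
identity. Patterns are stored as rank tuples and rendered as base-10
codes (132 for (1,3,2)), which is collision-free for d ≤ 9 — the
package therefore restricts d to 2..9 (3..9 where the sign flag below
is needed). The usual practical range is d = 3..7.

Each vector also carries a signed weight: its population variance
(divisor d), with the sign of flag(i) = mean(X(i)[2..d−1]) − mean(X(i))
— positive when the window's interior sits at or above the window
mean. For d = 3 the interior is the single middle element. The weight
separates same-pattern windows of different spread, and the sign
separates windows of equal spread but opposite local shape.

## The entropies

* **PE** — normalized Shannon entropy (natural log) of the pattern
  frequencies, divided by ln d!.
* **WPE** — patterns tallied with the *unsigned* variance as weight;
  the sign flag plays no role here. A constant signal has zero total
  weight and is rejected rather than silently reported as 0.
* **IPE** — amplitudes are quantized into L bins of width
  Δ = (xmax−xmin)/L (top bin closed at xmax); the first element of
  each vector is quantized directly, the rest are offset from it by
  floor((x_k − x_1)/Δ), all clamped to [0, L−1]; the entropy of the
  word distribution is normalized by ln L^d. A constant signal has no
  range to quantize and is rejected.
* **NPE** — see below.

All normalized entropies use the natural log in numerator and
denominator (the ratio is base-invariant) and the 0·ln 0 := 0
convention; a final clamp to [0, 1] guards one-ulp excursions at exact
uniformity.

## The NPE network

Scanning i = 2..n (n = N−d+1 nodes), node i searches j = 1, …, i−1 in
ascending order and connects to the first j with the identical pattern
and |w(i) − w(j)| ≤ error; then P(j) += 1 and the scan for i stops.
Nodes start at the score floor 1e−5 (configurable). The NPE is the
entropy of the normalized score vector over ln n.

Three readings fixed here, each forced by consistency of the procedure
with its own worked arithmetic:

* the weight test is the **absolute** difference — a signed reading
  would trivially connect every pair with w(i) < w(j);
* the backward scan continues past same-pattern predecessors that fail
  the weight test (the stop sits inside the combined condition);
* only the earlier endpoint's score is incremented. Note the earlier
  endpoint of one edge can still be the *later* endpoint of another:
  the tolerance is not transitive (weights 0.667/1.201/1.728 at
  error 0.55 chain 5→1 and 9→5). Each node is a later endpoint at most
  once, and that invariant is tested.

The implementation indexes scan candidates by pattern code, so each
node only touches same-pattern predecessors (order preserved); output
is identical to the naive all-pairs scan, which the test suite asserts
against a brute-force reference on a randomized corpus of short
signals. Worst-case work is still quadratic within a pattern class;
the 20,480-sample reference series completes in well under a second.

The tolerance *error* is the one free parameter that matters: smaller
values make connections rarer and push NPE up. Package defaults are
0.005 (short series, ~10³ samples) and 0.0005 for the long reference
series — both echoed in every result, since NPE values are only
comparable at a fixed tolerance. The edge count is non-decreasing in
the tolerance (tested). NPE is invariant under adding a constant to
the signal and covariant under scaling: NPE(a·x, d, a²·error) =
NPE(x, d, error).

## Signal generators

* **periodic / uniform random** — fixtures; only the random generator
  consumes a seed.
* **logistic map** x → μx(1−x), μ ∈ (0, 4]; defaults x0 = 0.3 and a
  10³-step transient avoid the measure-zero degenerate orbits (x0 = 0.5
  at μ = 4 maps to 1, 0, 0, … and triggers a warning). The Lyapunov
  exponent is computed as the orbit average of ln|μ(1−2x)|; at μ = 4
  it equals ln 2, a closed-form anchor used in the tests.
* **simplified Lorenz flow** (ẋ1 = 10(x2−x1),
  ẋ2 = (24−4c)x1 − x1x3 + c·x2, ẋ3 = x1x2 − 8x3/3) — fixed-step RK4,
  defaults h = 0.01, transient 10⁴ steps, initial state (0.3, 0.2,
  0.1): typical choices for this system family, all configurable. The
  integrator's fourth-order self-convergence is tested. Divergence
  beyond |state| > 10⁶ raises.
* **fractional Hénon map** — the Caputo fractional-difference solution
  x_i = x0 + Σ_j φ(i−j)·(1 − a·x²_{j−1} + y_{j−1} − x_{j−1}) (and the
  analogous y update) with memory kernel
  φ(k) = Γ(k+ν)/(Γ(ν)·Γ(k+1)), evaluated by the overflow-free
  recurrence φ(0) = 1, φ(k) = φ(k−1)(k−1+ν)/k. At ν = 1 the kernel is
  identically 1 and the sum telescopes to the classic Hénon map — the
  reduction is verified to machine precision on contracting orbits
  (on chaotic orbits any 1e−16 rounding difference is amplified
  exponentially, so digit-level agreement there is meaningless). The
  full memory makes generation O(n²); lengths beyond 5·10³ samples
  require an explicit override.

## Drivers

Sliding-window profiles compute the chosen entropy independently per
window (floor((N − window)/step) + 1 windows; no cross-window
connections), so a strictly stationary deterministic signal yields
identical values in every window — tested, and the package's stand-in
for the contracts exercised by EEG-style analyses, whose recordings
are not bundled. Parameter sweeps regenerate a fresh series per grid
cell (inclusive endpoints; a cell count can be given instead of a step
since printed ranges leave the endpoint convention ambiguous); cells
whose trajectory diverges are flagged NaN rather than aborting the
sweep. Sweep tests run scaled-down grids (coarse μ-grid for the
logistic map at series length 10³; an 11×11 (a, ν)-plane for the
fractional Hénon map at length 500) — large enough to resolve the
qualitative structure (periodic windows below the chaotic band,
elevated complexity toward ν = 1 at chaotic a) while keeping the suite
fast.

## What the synthetic fixtures do and do not show

The generators produce clean, noise-free orbits and exactly periodic
ramps. They exercise the symbolization, the network construction and
the discriminative ordering (noise > chaos > periodic) under ideal
conditions; they do not emulate measurement noise, non-stationarity,
amplitude drift or artifacts of real EEG recordings, so passing tests
demonstrate correctness of the statistic, not field performance on
clinical data. Group-level statistics on real recordings (ANOVA and
post-hoc comparisons) are out of scope: the sliding-window TSV output
is designed to feed such tests in any standard package.

## Numerical choices and limitations

* Weight ties at flag = 0 take the positive sign; shift invariance of
  the signed weight can flip at that boundary under floating-point
  rounding (property tests stay off the boundary).
* The IPE quantization follows the floor-and-clamp reading of the
  binning equations; it is the only reading under which the first
  column is integer-valued.
* The base-10 pattern code is a display convenience; pattern identity
  is the rank tuple, so nothing collides for the supported d range.
* NPE values depend on (d, error, floor) jointly; comparisons across
  series are only meaningful at matched settings, which is why every
  result object and file header echoes them.
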