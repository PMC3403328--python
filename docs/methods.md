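# Methods

## Model and conventions

A PBN over `n` internal genes and `m` control nodes is stored in one of two
equivalent representations: *per-gene* (each gene carries a list of candidate
functions with selection probabilities `c_j^(i)` summing to 1) or
*constituents* (an explicit list of `N` whole Boolean networks with
probabilities `q_j` summing to 1).  A compiler expands the per-gene form into
constituents via `q_j = Π_i c_{j_i}^(i)`; conversely the transition matrix of
a per-gene PBN is assembled directly from per-gene bit probabilities (genes
select functions independently), and a test confirms both assembly routes
give identical matrices.

Conventions, fixed once and used everywhere:

* States and controls are 1-based decimal encodings, `z = 1 + Σ 2^(n-i) v_i`
  and `u = 1 + Σ 2^(m-i) v_{n+i}`; gene 1 is the most significant bit.
* Truth-table rows use the same order: the first listed parent is the most
  significant bit of the row index.  (No update order ever needs stating —
  updates are synchronous.)
* Control bits may appear at any position of a parent list; nothing
  restricts them to particular argument slots.
* Transition matrices are column stochastic (`A[i-1, j-1] = Pr(i | j, u)`),
  stored sparse (CSC); perturbed matrices are dense, which is cheap for the
  `n ≤ 12` range this package targets.
* Support tolerance: matrix entries above `1e-12` count as possible
  transitions.  Selection/constituent probabilities must sum to 1 within
  `1e-9`.

## Perturbation model

With single-gene flip probability `p`, the chain is
`Ã(u) = (1-p)^n A(u) + P` where `P = Q^{⊗n} − (1-p)^n I` and
`Q = [[1-p, p], [p, 1-p]]`.  `P` is symmetric, zero on the diagonal, has
entry `p^h (1-p)^(n-h)` between states at Hamming distance `h`, and every
row/column sums to `ξ = 1 − (1-p)^n`.  The diagonal of `Q^{⊗n}` is exactly
`(1-p)^n`, so the implementation zeroes it directly rather than subtracting
(avoiding one-ulp negative residues).  The same `P` is applied to every
`A(u)`: perturbation is a property of the genes, not of the control value.

## State reduction

The deletion criterion for state `i` given the currently kept set is

    for every control u:   Σ_{j ∈ kept} M(u)[i, j]  ≤  ξ

with `M = Ã` when `p > 0` and `M = A` (and `ξ = 0`) otherwise.  Deletion is
batched: all simultaneously deletable states are removed, the truncated sums
recomputed, and the loop repeats until no state qualifies, with `ξ` held
fixed at `1 − (1-p)^n` throughout.  Design choices worth recording:

* *Threshold comparison is `≤ ξ`.*  The unperturbed zero-inflow test is the
  `p = 0` special case.  A strict `<` would delete nothing at `p > 0`: on
  the first pass the inflow of a state with zero unperturbed inflow is
  exactly the row sum of `P`, i.e. exactly `ξ`.
* *Every-control quantifier.*  A state deletable under one control but fed
  under another could still be steered into; requiring the criterion under
  all controls is what makes the original/reduced DP agreement sound.
* *Batch deletion* makes the result order-independent; a one-at-a-time mode
  exists behind `ReductionConfig(batch=False)` for comparison.
* *Critical states* are the initial state plus all recurrent states — the
  bottom strongly connected components of the support digraph of the
  unperturbed `A(u)`, united over controls.  For a single deterministic BN
  this is the classical attractor set.  They are passed as a preserve set
  and never deleted.  (For the threshold regimes studied here this is belt
  and braces: a recurrent state's inflow includes an edge from its own
  cycle, which the slack can never cover when constituent probabilities are
  equiprobable.)
* The comparison uses an absolute slack of `1e-9` so that the exact-equality
  first pass is robust to floating-point accumulation.

### Soundness and the original/reduced agreement

At `p = 0` a deleted state has, at its deletion time, zero inflow from the
then-kept set under every control; since the final kept set is contained in
every intermediate kept set, no kept state can transition into any deleted
state.  Trajectories from the (preserved) initial state therefore remain in
the reduced state set, the deleted states can never host the terminal state,
and backward DP over the reduced set computes the same values — the solver
still verifies this structurally and raises if any successor set escapes the
reduced states.  With `p > 0` the same holds for equiprobable constituents
because every positive entry of `A` is at least `1/N`, while the total
available slack is at most `ξ < (1-p)^n / N` in the studied regimes; the
package checks the agreement on every `compare_original_reduced` call rather
than assuming it.

### What the threshold can and cannot delete (equiprobable constituents)

With `q_j = 1/N`, positive entries of `A` are multiples of `1/N`.  The first
pass deletes `i` iff `(1-p)^n Σ_j A_ij + ξ ≤ ξ`, i.e. iff the unperturbed
inflow is exactly zero; later passes have slack `Σ_{j deleted} P_ij ≤ ξ`,
which is below `(1-p)^n / N` whenever `1 − (1-p)^n < (1-p)^n / N` — true for
all `(n, N, p)` combinations exercised here.  Consequently the deleted set
is exactly the iterated zero-unperturbed-inflow cascade and is *independent
of p*.  The measured mean deletion rate for `n=6, N=4, K=2` random PBNs is
therefore the same (≈57% over the replicates used in acceptance) at
`p = 0.001` and `p = 0.01`.  Published rates for this design instead climb
steeply with `p`; no reading of the threshold rule we could construct
(perturbed truncated sums, systematic-inflow-only comparison, random
selection probabilities, per-gene form) reproduces that climb under
uniformly random function sets, so the package reports the rate the
documented procedure actually produces rather than calibrating the generator
toward the published figures.  The monotone nondecreasing-in-p property does
hold (weakly) on matched seeds.

## Minimax dynamic programming

`minimax_dp` computes `J_M(z) = C(z)` and
`J_t(z) = min_u max_{z' ∈ F(z,u)} J_{t+1}(z')` with deterministic
tie-breaks: smallest control index wins the argmin, successors are scanned
in ascending state order.  `F(z,u)` is always the support of the
*unperturbed* `A(u)`, including when `p > 0`: under `Ã` every state reaches
every state, which would collapse the minimax value to `max C` and make the
worst case meaningless; the perturbation model belongs to the reduction
threshold, not to the adversary.

Two independent oracles guard the solver: a memoization-free game-tree
recursion (exact equality required) and an open-loop enumeration over fixed
control sequences (a feedback policy can only do as well or better, with
equality for deterministic single-BN models).

An optional *switch-budget* mode (`ControlProblem.switch_budget = H`)
implements a value table `J(z, h, t)` where continuing with the control the
downstream policy commits to is free and changing controls spends one unit
of `h`; `h = 0` forbids further changes (infeasible branches cost +inf), and
the terminal layer matches any control.  The default mode (no `h`) is the
standard minimax DP and equals the budget mode with `H = M`.  This mode is
one consistent completion of an underdetermined bookkeeping scheme and is
off by default.

## Synthetic networks and experiment design

`generate_random_pbn` draws, for every required function: an in-degree
uniform on `1..K` (so `K` is a maximum), that many distinct parents uniform
over the `n+m` nodes, and a truth table uniform over all `2^(2^k)` tables
(constants allowed — only the K=1 enumeration module excludes them, where
the `(2n)^n` census counts parent×polarity choices).  Constituent PBNs use
`q_j = 1/N`; per-gene PBNs give every gene `N` candidates with `c = 1/N`.
Uniformity is the maximum-entropy default for an otherwise unspecified
"randomly generated" design.  Replicate `r` of an experiment is seeded with
`(seed, r)`, so any reported row can be regenerated in isolation.

The *reduction experiment* uses `m = 0`, builds `Ã`, preserves critical
states plus the initial state and reports the mean deleted percentage.  The
*control experiment* follows the published design: of `n` total nodes, `m`
are controls (`n − m` internal genes, network size `2^(n-m)`), terminal cost
`C(z) = z`, horizon `M = 20` at the 6-node scale, and checks
original-vs-reduced value equality per replicate.  The initial state is
fixed at `z₀ = 1` (no published value exists); wall-clock times are reported
but never asserted.  Problem sizes in the test suite (6-node grid, 10
replicates, 200 oracle instances at `n ≤ 4, M ≤ 4`) keep the whole suite in
well under a minute while exercising every code path; they are the sizes at
which the brute-force oracles remain exact.

## K=1 combinatorics

`image_distribution(n)` enumerates all `(2n)^n` in-degree-1 networks
(guarded to `n ≤ 6`), builds each deterministic state map and counts states
with at least one preimage.  The image size always equals
`2^(#distinct parents used)`, asserted during enumeration; the closed form
`n!2^n` for full-image networks and the ratio `n!/n^n` are verified against
the enumeration for small `n`.  The general nested-sum closed form for
`2^(n-k)` nonzero rows is *not* implemented: its printed index constraints
are ambiguous, and the enumeration is the normative distribution here.

## Known limitations

* Dense `P` limits perturbed models to `n ≤ 12`; entrywise Hamming-distance
  access (`perturbation_entry`) is provided but no dense-free reduction
  path is wired up.
* Synchronous updates only; no inference from expression data; a single
  perturbation probability shared by all genes.
* Synthetic PBNs are uniformly random; real regulatory networks have biased
  (often canalyzing) functions and correlated topology, so passing tests
  here demonstrate correctness of the algorithms, not biological
  performance of the reduction rates.
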