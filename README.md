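# pbnctrl

Minimax optimal control of probabilistic Boolean networks (PBNs), accelerated
by transition-probability-based state reduction.

## The problem

A PBN models a gene regulatory network as a collection of Boolean networks
over `n` binary genes: at every step each gene `v_i` picks one of its
candidate Boolean functions `f_j^(i)` with selection probability `c_j^(i)`,
so the joint dynamics is a Markov chain on the `2^n` states
`z = 1 + Σ_i 2^(n-i) v_i`.  Some nodes can be designated *control* nodes:
their `m` bits are set externally, giving a control input `u ∈ [1, 2^m]`
per step — the handle a therapy would pull to steer the network away from
disease states.

Given terminal costs `C(z)` on the states, a horizon `M` and an initial
state `z₀`, the *minimax* control problem asks for the control strategy that
minimizes the worst-case terminal cost over every trajectory the network may
take.  Backward dynamic programming solves it:

    J_M(z) = C(z),     J_t(z) = min_u  max_{z' ∈ F(z,u)}  J_{t+1}(z'),

where `F(z,u)` is the support of the transition-matrix column of `z` under
control `u`.  The DP cost grows with the `2^n` state count, so this package
also implements a state-reduction strategy: states whose total inflow
`Σ_{j ∈ kept} A_ij` is at or below a threshold `ξ` under every control are
deleted iteratively (rows and columns removed, `ξ` fixed) until none
qualifies, while recurrent ("attractor") states and the initial state are
preserved.  For networks with random single-gene perturbation probability
`p` the chain becomes `Ã = (1-p)^n A + P`, with `P = Q^{⊗n} − (1-p)^n I`
built from the single-gene kernel `Q = [[1-p, p], [p, 1-p]]`, and the
threshold is `ξ = 1 − (1-p)^n`, the row sum of `P`.  Deleted states can
never be entered from the surviving set, so the DP value on the reduced
network equals the value on the original network — which the package checks
explicitly on every run.

A combinatorial module quantifies *why* reduction works for sparse networks:
for in-degree-1 networks, exhaustive enumeration of all `(2n)^n` BNs gives
the distribution of nonzero transition-matrix rows, the `n!2^n` count of
full-image networks, and the vanishing ratio `n!/n^n`.

## Worked example

```
$ pbnctrl generate --n 5 --m 1 --bns 2 --k 2 --seed 2 --out model.json
wrote model.json (n=5, m=1, N=2, K=2, p=0.0)

$ pbnctrl reduce --pbn model.json --out-dir reduced
kept 13/32 states (59.4% deleted, xi=0)

$ pbnctrl control --pbn model.json --horizon 20 --init 1
value original=25 reduced=25 equal=True sizes 32->13
```

The generated PBN has 5 internal genes (32 states), one control node and two
constituent BNs.  The reduction deletes 19 transient states that can never
be entered from the surviving 13, so the minimax DP — terminal cost
`C(z) = z`, horizon 20, start in state 1 — gives the same worst-case cost 25
on both the 32-state and the 13-state model, while solving a problem less
than half the size.  `reduced/deleted.tsv` records which state fell in which
deletion iteration, and `reduced/B_u*.mtx` hold the reduced transition
matrices in MatrixMarket form.

The in-degree-1 census for two genes:

```
$ pbnctrl enumerate --n 2
nonzero_rows    count
4       8
2       8
total   16
full_image_ratio        0.5
```

Of the 16 possible two-gene networks, 8 reach every state and 8 reach only
two — half of all networks already have deletable states, and that
full-image share `n!/n^n` vanishes rapidly as `n` grows.

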