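# Methods

## Model class and assumptions

`crnsteady` operates on chemical reaction networks (CRNs) with
deterministic mass-action kinetics: the rate of a reaction is its rate
constant times the product of the source-species concentrations raised to
their stoichiometric coefficients. Only *positive* steady states are
parametrized; boundary states (some concentration zero) are outside the
model class. Rate constants are treated as positive symbols throughout,
so every derived statement holds for all positive parameter values unless
rates are explicitly substituted.

Structural notions follow standard CRN theory. Complexes are compared as
coefficient multisets (`A + B` ≡ `B + A`). Linkage classes are connected
components of the *undirected* complex graph; weak reversibility (WR)
means every component of the directed graph is strongly connected. The
deficiency is `δ = n − ℓ − s` with `s` the rank of the stoichiometric
matrix computed over exact rationals — floating-point ranks are never
used, because every downstream symbolic statement depends on exact rank
decisions.

## Independent decomposition

A partition of the reaction set is independent when the subnetwork ranks
sum to the whole network's rank; the positive steady-state set of the
whole system then equals the intersection of the subsystems' sets. The
finest such partition is computed by a single scan of the reaction
vectors: vectors that enlarge the current span seed singleton classes;
a dependent vector has a unique representation in the collected basis,
and all classes holding basis vectors in its support are merged (union–
find). The result is independent by construction and is verified against
brute-force enumeration of all set partitions on small random networks in
the test suite. Reaction input order can relabel classes but never
changes the partition.

## Network translation

Subnetworks that are not WR with δ = 0 are translated: each reaction may
be shifted by an integer species vector `h_r`, replacing source and
product by `source + h_r`, `product + h_r` (rejected if any coefficient
would go negative) while the rate monomial stays that of the original
source. The shifted network is a generalized CRN (GCRN) carrying a
stoichiometric complex per vertex and a kinetic complex (the original
source) per source vertex; a vertex that is never a source keeps its
stoichiometric complex as its kinetic complex, a convention that only
matters in degenerate cases since weak reversibility makes every vertex a
source.

When reactions with distinct kinetic complexes land on one translated
source vertex, the vertex is split into one copy per kinetic complex.
Incoming effective edges attach to the *natural* copy (the one whose
kinetic complex equals the stoichiometric complex, if present, else the
canonically first). The copies are joined by phantom edges — zero
stoichiometric difference, fresh positive parameter σ numbered in
insertion order. A directed cycle through the copies always restores
weak reversibility; phantom edges not needed for it are then dropped
greedily in insertion order, so a two-way split keeps a single σ edge
whenever an effective path closes the cycle. Phantom edges contribute
nothing to the ODEs, and the suite asserts symbolically for every
translation produced that the GCRN's mass-action right-hand side is
identical to the original network's.

The *effective deficiency* is the deficiency of the stoichiometric CRN
(nodes: distinct stoichiometric complexes, phantom edges drop out); the
*kinetic deficiency* is that of the kinetic-order CRN (nodes: distinct
kinetic complexes, all edges including phantoms, rank over the kinetic
differences).

### Translation search

No complete algorithm is attempted. Candidate shifts per reaction are
(a) zero, (b) negatives of sub-complexes common to source and product
(catalyst removal, e.g. `−B` for `A + B → B`), and (c) vectors carrying
the source onto another source complex of the subnetwork; candidates are
bounded by `max_support` non-zero species (default 2) and coefficient
magnitude `max_coeff` (default 2) and ordered by total size then
lexicographically. Subsets of reactions to shift are enumerated by
increasing size, depth-first, and the first assignment whose GCRN passes
all four checks (WR twice, effective and kinetic deficiency zero) wins —
the search is deterministic and its success is *checked, not trusted*.
Exhausting the evaluation budget (default 5000 GCRN evaluations) is
reported distinctly from a completed-but-failed search; neither proves
impossibility. Positive kinetic deficiency is a hard unsupported error:
extra conditions would need checking before any parametrization, and a
silent wrong answer is worse than none.

## Steady-state parametrization

For a WR translated network with zero kinetic deficiency the positive
complex-balanced equilibria are monomial in structure. Tree constants
`K_i` (sum over spanning trees of the kinetic-order graph directed toward
`i` of the edge-label products) are computed as signed minors of the
symbolic out-degree Laplacian (directed matrix-tree theorem) and, on
graphs with at most 8 vertices per component, cross-checked against
explicit in-tree enumeration. A spanning forest over the kinetic
vertices is chosen deterministically: per component, a breadth-first tree
of the undirected graph rooted at the canonically smallest vertex,
oriented away from the root. Any forest — subgraph or not — yields the
same steady-state manifold; forest-independence is verified numerically
in the suite rather than assumed.

Each forest edge contributes a ratio `κ = K_head/K_tail` and a kinetic
difference row of `M`. The generalized inverse `H` is built from an
integer Smith-style diagonalization `U M V = S` as `H = V S⁺ U`:
deterministic, exact, and integer whenever the invariant factors are 1,
which keeps the monomial exponents integral (a rank-factorization
pseudoinverse would generically produce fractional exponents and hence
radicals in otherwise rational solutions). The kernel basis `B` is read
off the columns of `V`, sign-normalized and sorted so τ labels are stable
across runs. Species `j` then gets
`x_j = Π_e κ_e^{H[j,e]} · Π_t τ_t^{B[j,t]}`, strictly positive for
positive parameters. Only species appearing in kinetic complexes receive
expressions; σ and τ numbering is global across the pipeline so merged
solutions never collide.

## Merging and conservation-law resolution

Subnetwork solutions are merged in decomposition order; for each species
already assigned an expression, the two expressions are equated and the
numerator of the difference solved for the newest free parameter present
(τ preferred over σ — matching the convention that σ's survive to the
end). Among several roots the branch positive at the all-ones sample
point is selected; additional positive roots are recorded as potential
multistationarity rather than silently discarded. A parameter-free merge
equation that does not vanish marks the decomposition's subsystems as
having no common positive steady state. Equations the solver cannot
close are kept as residuals instead of failing the pipeline.

Conservation laws are an integer basis of the left kernel of `S`,
primitive, first-nonzero-positive; mixed-sign basis vectors are replaced
by small signed integer combinations of the others when that yields a
non-negative ("pool") basis, which reproduces the natural totals (e.g.
gene + bound gene) on all bundled models. Each conserved quantity enters
the resolution as an atomic positive symbol `Q_i` recorded alongside its
meaning in initial concentrations (`b0 + d0` style); substituting the
steady-state expressions into the laws gives one equation per law in the
remaining free parameters, solved single-unknown-first; coupled blocks go
through Groebner-basis polynomial system solving (robust for both
symbolic and numeric rational coefficients), with the generic symbolic
solver as fallback.
Degree-2 cases yield explicit radicals (the toggle-switch model is the
canonical example); higher-degree residuals are returned symbolically
rather than mis-solved.

ACR (absolute concentration robustness) is decided per species and per
conserved quantity by a symbolic partial derivative of the fully resolved
expression with respect to `Q_i`, with a finite-perturbation numeric
cross-check; a species robust to every conserved quantity has ACR. The
report is evaluated at user-supplied rate constants (all-ones in the
bundled insulin analysis); fully symbolic rates are possible for small
networks but grow quickly.

## Numeric oracles

`numeric_steady_state` integrates the mass-action ODEs with LSODA in
geometrically growing time chunks until `max |dx/dt| < tol` (default
1e-10); convergence is residual-based, not state-difference-based, to
avoid declaring convergence on slow manifolds. `check_solution`
evaluates a merged solution at log-uniform random parameter points
(deterministic per seed) and asserts residuals below 1e-9.
`random_wr_dz_network` builds unions of random directed cycles over
small random complexes and retries until deficiency zero, giving seeded
WR-DZ instances for property tests.

## Bundled networks and what the tests show

Four reaction lists ship with the package: a 4-reaction birth/death
example, a 6-reaction network whose one non-reversible reaction forces a
translation with a phantom edge, a 14-reaction CRISPRi toggle-switch
model (two sgRNA/dCas9 complexes repressing each other's target genes,
conserved gene totals), and a 35-reaction mass-action recast of the
Sedaghat insulin signaling model (receptor cycling with synthesis and
degradation, IRS-1/PI3K complex formation, lipid interconversion, Akt and
PKC activation, GLUT4 translocation). These are small, fully specified
models: passing tests demonstrate the correctness of the symbolic
machinery on them, not the biological accuracy of the models themselves,
and say nothing about networks whose subnetworks admit no WR-DZ
translation — such subnetworks are reported unsolved by design.

Problem sizes used in the test suite were chosen to keep the full run in
the minutes range: brute-force decomposition oracles up to 6 reactions,
matrix-tree cross-checks up to 8 vertices, 100 random WR-DZ seeds, 20
sample points per numeric oracle, and ODE manifold checks on the three
smaller bundled models plus unit-rate spot checks on the insulin model.

## Known limitations

* The translation search is incomplete (bounded shifts, greedy phantom
  topology); models needing larger shift supports require raising the
  bounds or supplying `--user-shifts`.
* Positive kinetic deficiency is not parametrized.
* Merge/resolution solving is heuristic where polynomial degrees exceed
  two; residual equations are returned unsolved in such cases.
* Multiple positive roots are reported, but no attempt is made to
  enumerate the full solution variety in degenerate (non-finite) cases.
* ACR verdicts at fixed rate constants do not preclude rate-dependent
  robustness changes elsewhere in parameter space.
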