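# crnsteady

Analytic positive steady states of mass-action biochemical reaction
networks, derived symbolically rather than simulated.

Deterministic mass-action models of biochemical systems — signaling
cascades, gene circuits, metabolic pathways — are usually interrogated by
numerical integration, one parameter set at a time. For a large class of
networks a *closed form* of the positive steady state exists and can be
read off the network structure, which makes questions like bistability,
parameter monotonicity and concentration robustness answerable for **all**
parameter values at once. `crnsteady` computes such closed forms for
networks whose independent subnetworks are, or can be translated into,
weakly reversible deficiency-zero generalized networks. It is aimed at
systems biologists and reaction-network theorists who want analytic steady
states of medium-sized models (tens of reactions) without hand algebra.

## Method

For a CRN with stoichiometric matrix `S` (columns = product − source of
each reaction), deficiency `δ = n − ℓ − s` (complexes − linkage classes −
rank S), the pipeline is:

1. **Finest independent decomposition** — partition the reactions so that
   the subnetwork ranks sum to `s` with the maximum number of classes;
   the positive steady-state set of the whole system is then exactly the
   intersection of the subnetworks' sets. Computed by exact linear
   algebra over the reaction vectors (basis collection plus union–find
   merging of dependence supports).
2. **Network translation** — each subnetwork that is not already weakly
   reversible (WR) with δ = 0 is shifted: a reaction `A + B → B` may
   become `A → 0` while keeping its original rate monomial `k·a·b`. The
   result is a generalized CRN with a stoichiometric complex `y(v)` and a
   kinetic complex `ỹ(v)` per vertex. Source vertices that collide are
   split and reconnected by *phantom edges* (zero stoichiometric vector,
   free rate parameter σ). A small deterministic search looks for shifts
   making both the stoichiometric and kinetic-order graphs WR with zero
   effective and kinetic deficiency.
3. **Tree-constant parametrization** — with `K_i` the sum over spanning
   trees of the kinetic-order graph directed toward vertex `i` of the
   products of edge labels (matrix-tree theorem), pick a spanning forest;
   each forest edge `i → i′` contributes `κ = K_{i′}/K_i` and a kinetic
   difference row of a matrix `M`. With `H` a generalized inverse
   (`MHM = M`, built from the Smith normal form so exponents stay
   integral) and `B` an integer basis of `ker M`, species `j` has steady
   state `x_j = Π_e κ_e^{H[j,e]} · Π_t τ_t^{B[j,t]}` with free positive
   parameters τ.
4. **Merging and resolution** — expressions for species shared between
   subnetworks are equated and solved for free parameters; the survivors
   are resolved against the conservation laws (integer basis of the left
   kernel of `S`) given initial concentrations. The resolved solution
   supports an **absolute concentration robustness** (ACR) report: which
   species' steady states are independent of which conserved quantities.

## Worked example

Reaction lists are plain text, one reaction per line
(`ID: complex -> complex [rate]`, `0` is the empty complex, `<->` expands
a reversible pair). The bundled four-reaction example:

```
R1: 0 -> A [k1]
R2: 0 -> B [k2]
R3: A + B -> B [k3]
R4: B -> 0 [k4]
```

```sh
$ crnsteady decompose methods.crn
2 independent subnetworks (total rank 2):
  N1: {R1, R3}  n=4 l=2 s=1 delta=1 WR=no
  N2: {R2, R4}  n=2 l=1 s=1 delta=0 WR=yes

$ crnsteady solve methods.crn
steady state:
  a = k1*k4/(k2*k3)
  b = k2/k4
free parameters: none
```

`{R1, R3}` is translated (`A + B → B` shifted to `A → 0`), parametrized
as `a = (k1/k3)·τ1`, `b = 1/τ1`, and merging with `b = k2/k4` from
`{R2, R4}` eliminates τ1 — reproducing the steady state one would get by
solving `k1 − k3·a·b = 0`, `k2 − k4·b = 0` directly.

The same pipeline run on the bundled 14-reaction CRISPRi toggle-switch
model (`crnsteady solve crispri.crn`) leaves two free parameters that
resolve against the two conserved gene totals into an explicit quadratic
root for the sgRNA concentration — from which monotonicity in every rate
constant (hence absence of bistability) can be read off. On the bundled
35-reaction insulin signaling cascade, `crnsteady acr insulin.crn
--rates k=1` reports which of the 20 species are robust to all five
conserved pools (the receptor states and intracellular GLUT4 are; cell
surface GLUT4 is not).

Python API: `parse_network`, `solve_crn`, `resolve_with_conservation`,
`acr_report`, `numeric_steady_state` (ODE cross-check); see the module
docstrings.

## Scope and limits

Mass-action kinetics only. Subnetworks with positive kinetic deficiency
after translation are reported as unsupported rather than parametrized
(additional conditions would have to be checked); the translation search
is deterministic but incomplete, so a failure is not a proof that no
WR-DZ translation exists. Stability, boundary steady states and
stochastic stationary distributions are out of scope. See
`docs/methods.md` for the full model description, numerical choices and
limitations.
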