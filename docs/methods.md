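# Methods

## The model

`moranfix` studies the constant-fitness Moran process on a graph of N
nodes. Every node carries exactly one individual: a wild-type with
fitness 1 or a mutant with fitness r > 0 (r < 1 disadvantageous, r > 1
advantageous). Links are unweighted and self-loops are excluded; an
edge i → j means the offspring of i may displace the occupant of j.
Each time step holds one birth and one death:

* **Birth-death (Bd).** A reproducer is drawn from the whole population
  with probability proportional to fitness; its offspring replaces a
  uniformly random out-neighbor. Selection acts globally.
* **death-Birth (dB).** A uniformly random individual dies; its
  in-neighbors compete in proportion to fitness to fill the vacancy.
  Selection acts locally.

Self-replacement is excluded under both rules (no imitation-style
self-loops). Rules with selection at the death step (bD, Db, BD, DB)
are out of scope.

The quantity of interest is the fixation probability φ^G(r): the chance
that a single mutant, placed on a node chosen uniformly at random,
eventually occupies every node. A graph is an **amplifier of
selection** if φ^G exceeds the well-mixed value for advantageous
mutants and falls below it for disadvantageous ones, a **suppressor**
under the reversed pattern.

## Exact computation

The mutant configuration is a subset of nodes, encoded as a bitmask in
[0, 2^N). The empty and full sets are absorbing. Ordering the t =
2^N − 2 transient configurations by bitmask value and appending the two
absorbing states puts the transition matrix in canonical form
T = [[Q, R], [0, I]]. The fixation probabilities from every transient
start are the second column of Φ = (I − Q)⁻¹ R. We assemble Q sparsely
(each row holds at most N · max-degree nonzeros), factor (I − Q) once
with a sparse LU, and solve for both absorption columns; the residual
is checked against 10⁻⁹ and a violation is reported as an unhandled
recurrent class rather than returned. Avoiding the explicit inverse is
what keeps N = 12–14 within reach; the full matrix at N = 14 already
holds (2^14)² ≈ 2.7·10⁸ entries.

Two routes produce the same transition probabilities: a scalar
per-configuration `step_distribution` and the vectorized assembly used
by the solver. The tests hold them against each other state by state.

### Structural short-circuits

Solving is skipped where structure decides the outcome:

* **Disconnected graphs** (judged on the undirected skeleton, also for
  directed graphs): a single mutant can never reach every node, φ = 0.
* **Directed graphs with more than one source strongly-connected
  component**: no single lineage can reach all source components, so
  φ = 0 from every start. This strictly generalizes the multi-rooted
  rule (a root — in-degree zero, positive out-degree — is a singleton
  source component) and also covers root-free multi-source graphs,
  where (I − Q) would be singular because mutually unreachable mutant
  configurations form a recurrent class among the transients.
* **One-rooted directed graphs** (unique source component, a single
  root node): the root is never replaced, so the mutant fixes iff it
  lands there; per-node φ is 1 on the root and 0 elsewhere, average
  1/N.

Two conventions the update rules leave open on directed graphs:
a node with out-degree zero is excluded from the Bd birth lottery,
which leaves absorption probabilities unchanged relative to treating
its births as null self-transitions (the embedded jump chains coincide;
asserted in a test against a dense lazy-chain oracle). A node with
in-degree zero makes dB ill-defined, but any such node makes the graph
rooted, so the case is unreachable after the short-circuits; the full
solver refuses it rather than invent semantics.

### Monte-Carlo oracle

`simulate_fixation` runs the chain to absorption from uniformly random
single-mutant starts and returns the fixation frequency with its
binomial standard error. All replicates advance in lockstep through
vectorized categorical sampling, making 10⁵ replicates on desk-size
graphs a sub-second operation. It serves as an independent oracle for
the exact solver (agreement within 3 standard errors), never as the
primary computation — fixation probabilities sit close to 1/N, so the
noise floor of simulation is exactly why the exact solve exists.

## Closed forms

When the mutant count performs a birth-death chain on 0..N with gain
and loss probabilities T_j±, the single-mutant fixation probability is

    φ = 1 / (1 + Σ_{k=1}^{N−1} Π_{j=1}^{k} T_j⁻/T_j⁺).

* **Well-mixed Bd**: T_j⁻/T_j⁺ = 1/r for every j, giving
  φ^M_Bd = (1 − 1/r)/(1 − r^{−N}).
* **Well-mixed dB**: φ^M_dB = ((N−1)/N)(1 − 1/r)/(1 − r^{−(N−1)}).
  The (N−1)/N prefactor is the cost of local selection.
* **Cycle under dB**: starting from one mutant the mutant set stays a
  contiguous arc, so the 2^N chain reduces exactly to a chain on the
  arc length with generic rates T_j⁺ = (2/N)·r/(r+1),
  T_j⁻ = (2/N)/(r+1) and boundary cases T_1⁻ = 1/N, T_{N−1}⁺ = 1/N.
  At N = 4 this evaluates to φ°_dB = 2r²/(3r² + 2r + 3). The general-N
  rates are our own arc-reduction; they are gated by the N = 4 closed
  form and by equality with the full 2^N solve for N = 4..10.

Both well-mixed forms are singular at r = 1 as written; the neutral
value 1/N is special-cased rather than left to floating-point
cancellation, and continuity at r = 1 is tested. The cycle-vs-well-mixed
deficit φ°_dB − φ^M_dB is nonpositive for all r > 0 with equality only
at r = 1 (at N = 4 it equals −r²(r−1)²/(4(r²+r+1)(3r²+2r+3))); the
general-N inequality is verified numerically on an r-grid for
N = 4..12 rather than re-deriving the algebraic proof.

## Classification

Each rule is compared against its own well-mixed reference — Bd against
φ^M_Bd, dB against φ^M_dB, never crossed — because the two references
differ noticeably at the small N considered here. The decision grid is
r = 0.75 (disadvantageous) and r = 1.25, 1.5, 1.75 (advantageous);
r = 1 is evaluated as a sanity check (φ must equal 1/N) but carries no
decision weight. Checks run in order: disconnected; directed source
census (multi_rooted / one_rooted); isothermality under Bd only, where
the isothermal theorem equates φ^G with the well-mixed value without
solving (temperature = summed incoming replacement weight; for
undirected graphs under Bd this is degree-regularity); otherwise the
exact φ^G at every grid r.

Strict inequalities are taken with an explicit absolute equality
tolerance, default 10⁻⁹: differences inside the band count as neither
direction. The direct LU solve on these small well-conditioned systems
is accurate to ~10⁻¹³, so the band is wide enough to absorb numerical
noise and narrow enough never to blur a real margin (the smallest true
classification margins observed at these sizes are ≳10⁻⁵). Graphs
matching the reference inside the band at every grid point are labeled
`wellmixed_equivalent`; remaining graphs that fit neither inequality
pattern are `unclassified`, subdivided into `margin` (some comparison
fell inside the band) and `mixed` (all comparisons strict but the
pattern fits neither class — the dB cycle, below its reference on both
sides of neutrality, is the canonical case). One-rooted graphs are
reported as their own category with the metadata note
`technically_suppressor`, since φ = 1/N sits below the advantageous and
above the disadvantageous reference.

## Synthetic ensembles

The G(N, p) generator is the pipeline's data source: each of the
N(N−1)/2 undirected (or N(N−1) directed ordered) node pairs receives a
link independently with probability p, never a self-loop, and the
initial mutant is placed uniformly at random. This emulates the
Erdős-Rényi ensembles whose classification the package reproduces; it
deliberately has no degree heterogeneity beyond binomial, no clustering
and no community structure, so passing ensemble tests says nothing
about scale-free or small-world populations (generators for those are a
non-goal).

Sweeps draw `graphs_per_p` graphs at each grid value of p, classify
each, and tally category proportions next to the analytic overlays: the
connectivity probability P_N from the recursion
P_N = 1 − Σ_{K=1}^{N−1} C(N−1, K−1) P_K (1−p)^{K(N−K)} (P_1 = 1; at
N = 4 this is the polynomial −6p⁶ + 24p⁵ − 33p⁴ + 16p³), the N = 4
isothermality probability p⁶ + 3p⁴(1−p)², and for directed ensembles
the probability 1 − (1 − (1−p)^{N−1})^N of at least one in-degree-zero
node. Directed sweeps report all sampled graphs classified; the
rooted/disconnected categories make the connectivity-conditioned view
recoverable from the same tallies, so both readings of the ensemble are
available.

Determinism: every graph's RNG derives from the key (sweep seed,
p-index, graph index), so a single graph can be replayed without
re-running the sweep, and an identical config byte-reproduces the CSV
output. Default sweep scale is N ∈ {4, 8, 10}, a 21-point p-grid and
200 graphs per point — chosen as a desk-scale working default; all
three are ordinary config knobs.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the exhaustive N = 4
census exactly, cross-check the cycle reduction against full solves up
to N = 10, verify the cycle inequality up to N = 12, and classify a few
hundred connected random graphs up to N = 10 per rule. These sizes keep
a full run in the low minutes on one core while exercising every code
path; the solver itself accepts any N ≤ 14.

## Known limitations

* The full solve is capped at N = 14 (2^N states); no symmetry
  reduction is attempted, by design, since it cannot be automated
  across arbitrary random graphs.
* Classification at finitely many r values can in principle mislabel a
  graph whose φ^G crosses the reference outside the grid; the grid is
  a config knob, and margins are reported so borderline graphs are
  auditable.
* Undirected dB ensembles are observed to contain no amplifiers up to
  the sizes tested; that is an empirical statement of the pipeline, not
  a theorem the package proves.
* Fixation times are not exposed; the fundamental matrix is only used
  en route to absorption probabilities.
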