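# moranfix

Exact fixation probabilities for the Moran process on graphs, and
classification of random-graph ensembles into amplifiers and
suppressors of selection.

## The problem

In evolutionary graph theory a population lives on a graph: each node
holds one individual (wild-type, fitness 1, or mutant, fitness r), and
links say whose offspring can displace whom. The central quantity is
the **fixation probability** φ^G(r): the chance that a single mutant,
placed on a uniformly random node, eventually takes over. Structure can
reshape selection — a graph is an **amplifier** if it raises φ above
the well-mixed (complete-graph) value for advantageous mutants
(r > 1) and lowers it for disadvantageous ones (r < 1), and a
**suppressor** under the reversed pattern. Whether a given structure
amplifies or suppresses turns out to hinge on the microscopic update
rule:

* **Bd (Birth-death)**: a reproducer is chosen from the whole
  population proportional to fitness; its offspring replaces a random
  neighbor. Almost every connected, non-regular undirected random
  graph is an amplifier.
* **dB (death-Birth)**: a random individual dies; its neighbors compete
  proportional to fitness for the slot. The same ensembles contain
  essentially only suppressors.

Because even the well-mixed references differ between the rules —
φ^M_Bd = (1 − 1/r)/(1 − r^−N) versus
φ^M_dB = ((N−1)/N)(1 − 1/r)/(1 − r^−(N−1)) — each rule is always
compared against its own reference.

`moranfix` is aimed at researchers and students of evolutionary
dynamics who need exact (not simulated) fixation probabilities on
arbitrary small graphs (N ≤ 14), the closed forms for well-mixed
populations and cycles, and a reproducible pipeline for classifying
Erdős-Rényi G(N, p) ensembles, undirected or directed.

## What it computes

The mutant configuration performs an absorbing Markov chain on 2^N
states. In canonical form T = [[Q, R], [0, I]], and the fixation
probabilities from all starts are the second column of
Φ = (I − Q)⁻¹ R, obtained here from a sparse LU solve. Structural
short-circuits (disconnected → φ = 0; directed multi-source → φ = 0;
one-rooted → φ = 1/N; isothermal under Bd → well-mixed value) avoid
solving where structure already decides. A vectorized Monte-Carlo
simulator provides an independent cross-check, and closed forms for the
well-mixed population and the dB cycle
(φ°_dB = 2r²/(3r² + 2r + 3) at N = 4) serve as analytic oracles.
See `docs/methods.md` for the full account.

## Worked example

The star on five nodes under Bd updating — hub linked to four leaves —
is the textbook amplifier:

```python
from moranfix import star_graph, fixation_with_shortcuts, phi_wellmixed_bd, classify

g = star_graph(5)
for r in (0.75, 1.25, 1.5, 1.75):
    res = fixation_with_shortcuts(g, r, "Bd")
    print(f"r={r}: phi_star={res.uniform_avg:.6f}  phi_wellmixed={phi_wellmixed_bd(r, 5):.6f}")
print(classify(g, "Bd").label)
```

prints

```
r=0.75: phi_star=0.081106  phi_wellmixed=0.103713
r=1.25: phi_star=0.329468  phi_wellmixed=0.297477
r=1.5: phi_star=0.439317  phi_wellmixed=0.383886
r=1.75: phi_star=0.524283  phi_wellmixed=0.456377
amplifier
```

The star sits below the well-mixed reference at r = 0.75 and above it
at every advantageous r: selection is amplified. Under dB the same
graph classifies as a suppressor.

The exhaustive four-node census from the command line:

```
$ moranfix census-n4 --rule dB
   graph      degrees  n_edges  ...                label detail  phi_0.75 ...
    path (1, 1, 2, 2)        3  ...           suppressor   None  0.197027
    star (1, 1, 1, 3)        3  ...           suppressor   None  0.215561
   cycle (2, 2, 2, 2)        4  ...         unclassified  mixed  0.181818
     paw (1, 2, 2, 3)        4  ...           suppressor   None  0.197137
 diamond (2, 2, 3, 3)        5  ...           suppressor   None  0.187206
complete (3, 3, 3, 3)        6  ... wellmixed_equivalent   None  0.182432
```

Under dB the cycle is the unique four-node graph that is neither an
amplifier nor a suppressor: its φ sits below the well-mixed reference
on *both* sides of neutrality (the `mixed` detail). Other subcommands:
`sweep` (classify a G(N, p) ensemble over a p-grid and write CSV/JSON),
`classify-graph` and `phi` (operate on a plain edge-list file).

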