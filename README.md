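# overmod

Convert a disjoint (hard) partition of an undirected, optionally weighted
network into an overlapping (soft) partition by maximising an
overlapping-modularity objective over binary connector-node/module
assignments.

Given a network and a hard partition (from any external method, or the
built-in greedy optimiser), nodes are classified as *isolated* (all
neighbours inside their own module; membership frozen) or *connectors*
(at least one foreign neighbour; free to join any neighbouring module).
The objective

    Q_ov = sum_m [ W_m / L  -  (S_m / 2L)^2 ]

— with `W_m` the edge weight internal to module m, `S_m` the summed node
strengths of its members and `L` the total edge weight — is maximised
over the binary memberships subject to every connector keeping at least
one module, either exactly (exhaustive enumeration on small instances)
or by seeded multi-start steepest-ascent local search. Connectors ending
up in two or more modules are *inter-connectors*; the rest are
*intra-connectors*.

The package also ships the surrounding evaluation machinery: hard
modularity, Jaccard set comparison, participation coefficients and node
profiles, Monte-Carlo node-removal robustness curves, and a synthetic
benchmark generator with planted overlapping nodes plus recovery
scoring.

## CLI

All stochastic commands require `--seed` and are byte-reproducible.
Outputs are TSV with `#` comment headers recording version, seed and
parameters.

```sh
# stage 1: hard partition (or bring your own node<TAB>module file)
overmod partition --edges net.edges --seed 7 --out hard.tsv

# classify isolated vs connector nodes
overmod roles --edges net.edges --partition hard.tsv --out roles.tsv

# stage 2: convert to an overlapping partition
overmod convert --edges net.edges --partition hard.tsv \
    --restarts 100 --seed 7 --out soft.tsv
# small instances can be solved exactly:
overmod convert --edges net.edges --partition hard.tsv \
    --seed 7 --exact --budget 4096 --out soft.tsv

# per-node profiles (degree, participation coefficient, centralities)
overmod profiles --edges net.edges --partition hard.tsv --soft soft.tsv \
    --out profiles.tsv

# node-removal robustness curves per role class
overmod robustness --edges net.edges --soft soft.tsv --runs 100 --seed 7 \
    --out curves.tsv

# synthetic benchmark with planted overlap, and recovery over a grid
overmod synth --n 500 --k 10 --modules 10 --on 75 --om 4 --mu 0.05 \
    --seed 7 --out-prefix bench
overmod bench --on 75 --om 4 --mu 0.05 --mu 0.3 --replicates 10 \
    --restarts 100 --seed 7 --out recovery.tsv

# end-to-end pipeline with a JSON run manifest
overmod run --edges net.edges --auto-partition --restarts 100 --seed 7 \
    --out-prefix out
```

Edge lists are whitespace-separated `node1 node2 [weight]` lines
(`--weighted` to parse the third column); duplicate lines sum, self-loops
are allowed, `#` comments ignored. Only the main connected component is
analysed.

## Conventions

- A self-loop `a_ii` counts once in the node strength `s_i` and once in
  `L`, so `sum_i s_i = 2L - sum_i a_ii`; loop-free networks satisfy
  `sum_i s_i = 2L` exactly.
- Jaccard of two empty sets is defined as 1.
- The multi-start solver derives restart r's random stream from
  `(seed, r)`, so raising `--restarts` extends rather than reshuffles the
  restart sequence.
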