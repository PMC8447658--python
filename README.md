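# cscnet

Ranking candidate line (re)measurements that reconnect spectroscopic
networks.

## The problem

A line-by-line spectroscopic database links molecular quantum states by
measured transitions.  By the Ritz principle, wavenumbers are additive —
E(B) = E(A) + ν̃(AB) — so any state connected to the zero-energy *root*
state by a path of transitions has a determinable absolute energy, with
an uncertainty inherited from the path.  In real databases many states
sit in *floating components*: subgraphs with no (accurate) path to the
root, whose absolute energies are therefore unavailable or poor.  Every
new measurement has a cost, and not all candidate lines are equally
useful: one well-chosen transition can anchor dozens of states at once.

`cscnet` implements the **Connecting Spectroscopic Components (CSC)**
method for experimental and database spectroscopists planning
(re)measurement campaigns.  Given an *internal* set of transitions (the
database to improve, or its subset below an uncertainty threshold) and
an *external* set of candidates (new-experiment lines, or the inaccurate
remainder of the database), it:

1. builds the internal spectroscopic network H and its connected
   components H₀ (containing the root *r*), H₁, H₂, …;
2. contracts each component to a single vertex hᵢ, pools parallel
   external candidates into single edges, and keeps "grey" states
   (touched only by external lines) as singleton vertices, giving a
   small simple graph G′;
3. runs an all-shortest-paths BFS from h₀, recording for each floating
   component the minimum number of new measurements lᵢ and *every*
   minimum-length path family Sᵢ;
4. ranks components by the **utility factor** uᵢ = |Hᵢ| / lᵢ — newly
   connectable quantum states per new measurement — and expands each
   suggested path back into the concrete candidate transitions (the
   per-edge *pools*: measuring any one line of a pool realises the edge).

A spanning tree of G′ (the *global* solution) gives the overall minimum
number of new measurements; the per-component *local* ranking is more
robust to a single failed measurement, and `compare_local_global`
quantifies the trade-off.  Survey tools compute expansion ratios
(|H₀|+|Hᵢ|)/|H₀|, detect *accurate floating components* (subnetworks
held together by highly accurate lines yet lacking an accurate path to
the root), and scan for the most productive wavenumber window of fixed
length.

## Worked example

The built-in fixture (`cscnet.make_fig2_fixture`) is a 21-state network:
six internal components of sizes 3 (with the root), 4, 3, 2, 4, 4, one
grey state, and eight candidate lines.  Rank the candidates:

```sh
python -c "from cscnet import make_fig2_fixture, write_linelist; \
  i, e, r = make_fig2_fixture(); write_linelist(i + e, 'example.txt')"
csc run --input example.txt --threshold 1e-3 --root 0,0 \
    --min-component-size 1 --output example_csc.txt
```

which prints the summary table

```
component	size	length	utility	n_paths	pool_sizes
1	4	1	4.00	1	1
3	4	1	4.00	1	2
4	3	1	3.00	1	1
2	4	2	2.00	1	1,1
5	2	2	1.00	1	1,1
```

Reading: two components of four states each tie at utility 4 — one new
measurement connects four states; one of the two has a pool of 2 (two
interchangeable candidate lines realise the same contracted edge).  A
three-state component follows at utility 3; a four-state component
reachable only through the grey state needs two measurements (u = 2);
and the two-state component, also two edges away, trails at u = 1
(its route happens to pass through another floating component, an extra
gain the utility factor deliberately does not claim).  The
`example_csc.txt` file lists one row per (path, edge, candidate line):

```
# path edge wavenumber uncertainty <upper labels> <lower labels> tag
1 1 100.00000000 0.01000000 1 0 0 1 EXT.1
2 1 900.00000000 0.01000000 5 0 0 0 EXT.7
2 1 950.00000000 0.01000000 5 1 0 1 EXT.8
...
```

The best 100 cm⁻¹ measurement window:

```sh
csc intervals --input example.txt --threshold 1e-3 --root 0,0 -L 100
# best_T = 2
A	B
100.00000000	150.00000000
```

— any window containing both 100 and 150 cm⁻¹ reaches two components.

Other subcommands: `csc global` (spanning-tree solution), `csc floating`
(accurate floating components), `csc energies` (Ritz-chained absolute
energies), `csc simulate` (seeded synthetic networks).  See
`csc <cmd> --help`.

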