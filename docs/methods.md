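# Methods

## Model

A spectroscopic network (SN) is an undirected multigraph: vertices are
molecular quantum states (identified by fixed-arity label tuples —
quantum numbers, symmetry species, counting indices), edges are assigned
transitions with a wavenumber w (cm⁻¹) and an uncertainty u (cm⁻¹, the
half-width of a 95% interval).  The root r is the lowest-energy state,
fixed at energy zero.  Chaining the Ritz principle
E(upper) = E(lower) + w along a path from r assigns an absolute energy
to every state in r's component; an accurate path is treated as a
*necessary* condition for an accurate absolute energy.

The selection problem: given internal transitions (the database, or its
accurate subset) and external candidates (new-experiment lines, or the
inaccurate remainder), rank the candidates by how many states they
newly connect to r per measurement.

### Pipeline

1. **Components.**  H is built from internal transitions only; its
   components are H₀ (containing r, added as an isolated vertex if
   nothing touches it), H₁, H₂, ….  All connectivity is undirected: the
   upper/lower orientation matters only for energy propagation.
2. **Contraction.**  Each Hᵢ collapses to a vertex hᵢ.  External
   candidates internal to one component become self-loops and are
   dropped (this subsumes candidates duplicating an internal adjacency,
   whose endpoints necessarily share a component).  Parallel external
   edges between one vertex pair merge into a single edge carrying the
   *pool* of its transitions; measuring any one pool member realises the
   edge.  States absent from H ("grey" states) stay as singleton
   vertices.  The contracted graph G′ is simple, small, and unweighted —
   equivalent to 0/1-weighted shortest paths on the uncontracted graph
   (internal edges 0, external edges 1), but much cheaper and free of
   the zero-weight path-enumeration pitfalls; the equivalence is
   property-tested.
3. **All shortest paths.**  BFS from h₀ yields, per floating component,
   the minimum measurement count lᵢ and the complete family Sᵢ of
   minimum-length paths (not just one witness: experimenters choose
   among interchangeable routes).  Grey vertices can appear as path
   interiors, each costing one edge like any other hop; they are never
   targets.  Unreachable components get lᵢ = ∞ and are reported in a
   separate "unconnectable" section rather than dropped.
4. **Utility and ranking.**  uᵢ = |Hᵢ| / lᵢ, kept as an exact rational
   and printed with two decimals.  Ordering is uᵢ descending, |Hᵢ|
   descending, component index ascending — the tie-breaks are a design
   choice for a deterministic, byte-stable total order.  When a path
   traverses other floating components, their states are reported as a
   per-path `bonus_vertices` annotation but never folded into uᵢ: the
   factor stays a simple, comparable lower bound.
5. **Global solution.**  With unit weights, any spanning tree of the
   h₀-component of G′ is minimum; Kruskal over lexicographically sorted
   edges makes the choice deterministic.  The tree minimises total new
   measurements, but a single failed measurement can strand several
   components; `compare_local_global` reports, per selected edge, how
   many target components a single failure strands under each strategy.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` | none (required) | cm⁻¹; uncertainty ≥ threshold ⇒ external, < ⇒ internal (the boundary value is external) |
| `min_component_size` | 8 | floating components below this are not ranked; tiny components dominate real outputs for little gain. Pass 1 to rank everything |
| `min_utility` | 0 | optional lower bound on uᵢ to cap output size |
| `n_upper_cols` / `n_lower_cols` | 2 | label columns per state in segment files; molecule-dependent. Upper-state columns come first by default (`upper_first`) — the dialect itself does not fix the order, so it is configuration |
| magic-number uncertainty | caller-supplied (1e-6 cm⁻¹ typical) | pseudo-root lines anchoring detached symmetry blocks; wavenumber is a 1.0 cm⁻¹ placeholder, schema-valid but never used by the ranking |
| interval length `L` | none (required) | cm⁻¹ window for the interval scan; endpoints closed |

Sufficiently-large rule for accurate floating components: at least 5
states connected by lines with u < 5×10⁻⁶ cm⁻¹, or at least 30 with
u < 10⁻⁵ cm⁻¹.  The rule re-examines the component's own lines at both
bounds, so a component assembled at a looser bound qualifies only
through a sub-block meeting one of the two.

## Interpretations and numerical choices

- **Interval scan.**  "Reachable using transitions within the window" is
  ambiguous when lᵢ > 1; the default counts a component only if some
  *complete* shortest path is realisable from in-window pool members (a
  partial path connects nothing).  `complete_paths=False` switches to
  per-edge credit.  Windows are closed intervals anchored at each
  suggested wavenumber; all tied best windows (A, B) are returned, with
  B the largest in-window suggested wavenumber (B − A < L).
- **Energy propagation** follows a BFS spanning tree and does not
  reconcile cycle inconsistencies — a deliberate simplification relative
  to full weighted least-squares inversion of the whole network, which
  is out of scope.  Among parallel lines the most accurate (tie: lowest
  tag) is used.  Path uncertainties combine in quadrature, treating the
  lines' 95% intervals as independent — an assumption, stated here
  because the combination rule is not fixed by the data model.
- **Component ordering** is H₀ first, then size-descending with
  smallest-member-label tie-break, chosen for byte-stable output.  Note
  the worked example's figure numbering is *not* size-ordered; tests and
  the acceptance script map figure components to partition indices via
  member states rather than assuming index equality.
- **Ratios** are printed with decimal half-up rounding to 2 digits
  (`survey.round_half_up`); exact values are retained internally.
  Utility factors are `fractions.Fraction`s, so uᵢ·lᵢ = |Hᵢ| holds
  exactly.
- Duplicate tags in one file are a hard error: pools are reported by
  tag, so ambiguity would corrupt the output's meaning.

## Synthetic data

`synth.make_fig2_fixture` hand-builds a 21-state network — components of
sizes 3 (with root), 4, 3, 2, 4, 4 plus one grey state and eight
candidates — covering every path scenario the ranking distinguishes:
direct edges, a two-candidate pool on one edge, a route through another
floating component, and a route through a grey state.  The component
containing the root is set to 3 states; no reported quantity depends on
its size.  Internal lines carry u = 10⁻⁶ cm⁻¹ and candidates
10⁻² cm⁻¹, so any threshold between those regimes (10⁻³ documented)
reproduces the same split.  Candidate wavenumbers are spaced 100–950
cm⁻¹ so a 100 cm⁻¹ window isolates exactly the two direct candidates at
100 and 150 cm⁻¹.

`synth.generate` draws seeded random networks: per-component random
spanning trees plus density-controlled extra edges, cross-component
external candidates optionally routed through fresh grey states, uniform
wavenumbers, and uncertainties from a discrete mixture of accuracy
levels (default 50% at 10⁻⁶, 50% at 10⁻³ cm⁻¹ — emulating the microwave
vs FT-IR accuracy split of real line lists).  One `random.Random(seed)`
stream makes output byte-reproducible.  What the generator does *not*
emulate: selection rules and symmetry blocks (state labels are synthetic
integer tuples, any state pair may be linked), realistic wavenumber–
state relationships, intensities, and measurement feasibility.  Passing
property tests therefore demonstrate graph-algorithmic correctness on
networks with realistic *topology statistics*, not agreement with any
molecule's physics.

Property batteries run on 200 seeded networks (3–6 components of 1–5
states, 5–12 candidates, 30% grey routing) — small enough that the full
suite completes in seconds while exercising unreachable components,
grey interiors, pooled parallels and tied rankings.

## Limitations

- No least-squares energy refinement or cycle-closure diagnostics; the
  energies subcommand is a first-order Ritz chain.
- lᵢ counts measurements, not measurement difficulty; feasibility
  filtering (e.g. by rotational quantum number) is the user's job —
  supply a curated external set.
- For lᵢ > 1 no scalar "pool size" is reported (pools are per-edge,
  per-path); collapsing them to one number would misstate the choice
  structure.
- The MST tie-break ignores pool sizes; preferring large pools on ties
  could improve robustness but is not implemented.
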