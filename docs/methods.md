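# Methods

## Model and procedure

The pipeline has four stages.

1. **Base graph.** Cities become nodes at their planar coordinates; edges
   carry Euclidean lengths. The substrate the dynamics run on is
   configurable: Delaunay triangulation (default), complete graph, or
   symmetrized k-nearest-neighbour. Delaunay is the default because it is
   planar, sparse, connected, and contains every nearest-neighbour link —
   a plausible candidate set for ground transport. A collinear point set
   (where the triangulation is undefined) falls back to the complete graph
   with a warning; coincident cities are rejected outright.

2. **Demand.** The gravity model F_ij = G · M_i^a1 · M_j^a2 / D_ij^a3 with
   GDP masses and a1 = a2 = 0.5, a3 = 0. The distance exponent of zero
   encodes the assumption that modern inter-city traffic correlates with
   economic size, not separation; the classical population/distance²
   variant is kept for comparisons. The scale G only multiplies the matrix
   (scale equivariance is tested), so predictions are meaningful up to a
   proportionality constant. Rows of a city table that enumerate several
   urban areas collapse to a single node with summed populations and
   summed economic powers.

3. **Physarum design loop.** Demand is max-normalized so injections and
   conductivities share the [0, 1] scale. Each outer sweep runs, for every
   unordered pair with positive demand, one iteration of the single-O-D
   dynamics (pressure solve, flux, conductivity update) starting from the
   shared matrix D_k with injection I0 = F_ij. Per-pair results are
   combined elementwise with weights F_ij / ΣF ("flow-weighted": a pair's
   influence is its share of total demand; a plain average is available as
   an ablation), and the combination is divided by its maximum so
   max(D) = 1. The loop stops when the max elementwise change of the
   normalized matrix drops below delta.

4. **Extraction and metrics.** Thresholding at alpha keeps edges with
   D_ij >= alpha (keep-at-equality). The sweep starts at alpha = 0.01 and
   then visits the distinct edge conductivities above it — the only points
   where the network can change — recording, for each connected network:
   total length TL and all-pairs shortest-distance sum MD, both normalized
   by the base graph's minimum spanning tree; fault tolerance FT, the
   fraction of single-link removals that leave the network connected
   (equivalently 1 − bridges/|E|, and computed by exhaustive removal); and
   efficiency FT/(TL/TL_MST). The sweep stops at the first disconnecting
   threshold.

## Parameters

| parameter | default | meaning |
|---|---|---|
| gamma | 1.0 | tube decay rate; sets the conductivity scale D* = I0/gamma |
| dt | 0.5 | Euler step of the conductivity update, in (0, 1]; 0.5 damps the update enough to keep warm-start memory across sweeps while converging geometrically |
| d_init | 0.5 | initial conductivity on every edge (mid-scale, unbiased); `"random"` draws uniform(0.05, 1) per edge from the config seed |
| delta | 0.01 | outer-loop stop: max elementwise change of normalized D between sweeps |
| inner_steps | 1 | Physarum iterations per O-D pair per sweep; 1 keeps pairs tightly coupled through the aggregation |
| max_outer | 200 | outer-sweep cap; runs that hit it return `converged=False` |
| tol (single O-D) | 1e-6 | stop when the max per-edge change falls below tol · max(D) |
| alpha_start | 0.01 | first recorded extraction threshold |

Units: lengths inherit the coordinate unit; demand inherits the mass unit
and is dimensionless after max-normalization; conductivities are
dimensionless in [0, 1].

## Numerical choices

- The pressure system is the grounded weighted Laplacian (conductances
  D_ij/L_ij) with the sink row/column removed, solved by a sparse direct
  solve. Edges with D below 1e-12 are dropped from the system (never from
  the graph) to avoid singularity; nodes outside the sink's conductive
  component get pressure 0 and carry no flux. Source and sink in different
  conductive components is an error naming the pair.
- Self-pairs (i = j) carry no demand and are skipped; zero-demand pairs are
  skipped entirely.
- Pairs within a sweep all read the same frozen D_k (Jacobi-style), so the
  outcome is independent of pair ordering and bit-reproducible; with a
  fixed seed and config two runs produce byte-identical outputs.
- MST ties are broken lexicographically (stable Kruskal over canonically
  sorted edges). Edges are stored as unordered (i, j), i < j, 0-based.
- The convergence criterion is applied to conductivity differences, the
  most direct reading of "the matrix elements stabilize"; metric-stability
  stopping was the alternative and is recoverable by monitoring the sweep
  output.
- CSV readers parse floats in round-trip mode so matrices and fixtures
  survive write/read cycles bit-exactly.

## Synthetic data

`SyntheticSpec`/`generate_city_map` emulate the statistical structure the
demand model assumes: cities scattered uniformly in a box with a minimum
pairwise separation (default 0.3/√n of the box scale, by rejection),
heavy-tailed populations (lognormal, median 5·10⁵, σ = 0.75; a Pareto
option exists), and GDP coupled to population by GDP = c·pop^β·ε with
β = 1, c = 10⁻⁴ and lognormal noise σ = 0.3 — mirroring the strong
empirical GDP–population correlation in real city systems. The region is
an axis-aligned box rather than an arbitrary polygon; nothing downstream
depends on the region's shape.

What the generator does **not** emulate: real road geometry and
geographic obstacles (mountains, coastlines), correlated spatial
clustering of cities, asymmetric demand, and congestion feedback. Passing
tests on synthetic maps therefore demonstrate the correctness and
convergence of the algorithm, not the realism of any particular designed
network.

The packaged Mexico (19 nodes) and China (31 nodes) tables reproduce
published population/economic-power data. Their printed sources carry no
coordinates, so the bundled x/y values are approximate city
longitudes/latitudes added here for geometry-dependent code paths; every
map built from them is flagged `crs_note="synthetic …"`, and no reference
quantity computed by the acceptance script depends on them. The China
table's observed traffic column is exposed for ranking comparisons only
and is never a model input. The Mexico table's economic powers are
rank-style scores used directly as masses, exactly as the combination rule
(row 14: 2 + 1 + 7 = 10; row 19: 21 + 19 = 40, by the same rule) implies.

## Design choices that were genuinely open

- **Aggregation form.** How per-pair conductivities combine into one
  matrix is underdetermined; the demand-weighted convex combination is the
  default because the role a pair plays in the network should scale with
  the traffic it carries. The uniform average is retained as an ablation.
- **Injection scale.** Per-pair injections use max-normalized demand so
  flux and conductivity magnitudes stay commensurate; raw demand is a
  config switch (`normalize_demand=False`).
- **Fault-tolerance sign.** FT is reported as the probability of
  *surviving* a single-link removal (spanning tree 0, cycle 1), the
  convention under which higher is better and an MST scores 0.
- **Base-graph edge set.** Nothing fixes the substrate the dynamics run
  on; Delaunay and complete modes are both first-class rather than
  guessing a single intent.

## Problem sizes

Default verification runs use 10-city synthetic instances for the design
loop (45 O-D pairs, convergence in a few dozen sweeps, seconds per
instance), 8–30-node random graphs for conservation/shortest-path/FT
properties, and the two packaged tables (19 and 31 nodes) end-to-end;
these sizes exercise every code path while keeping the full suite fast.

## Known limitations

- The design loop is a heuristic: it has no optimality guarantee for the
  NDP decision problem, and no congestion or user-equilibrium constraints
  (links have unlimited capacity).
- Flow-weighted aggregation can let very low-demand pairs lose their last
  dedicated links for large demand disparities; demand coverage is a
  tested property at the shipped defaults, not a theorem.
- Distances are planar Euclidean; lon/lat coordinates are treated as plane
  coordinates, which distorts long east–west links at high latitudes.
- `max_outer` truncation returns a usable but unconverged matrix; callers
  must check the `converged` flag.
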