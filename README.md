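# treetop

Branch-point detection and scoring in high-dimensional single-cell data.

Single-cell snapshots of a differentiating system (mass/flow cytometry,
dimensionality-reduced scRNA-seq) sample cells along continuous
trajectories through marker space. `treetop` asks whether those
trajectories **branch** — whether some cell state feeds three or more
distinct downstream paths — and answers with a calibrated score, the
identified branch point, and the branch membership of every cell. It is
aimed at researchers analysing differentiation processes (e.g.
hematopoiesis, thymic T-cell maturation) who want a statistical statement
about branching, not only a fitted tree.

## Method in brief

Given a cells × species matrix `X` (arcsinh-transformed for cytometry),
`treetop`:

1. removes outliers and density-downsamples (SPADE-style), then picks
   `k` reference nodes by k-means++ seeding and assigns every cell to
   its nearest node (Voronoi tessellation, L1 distance by default);
2. samples an ensemble of `n` minimum spanning trees, each over one cell
   drawn uniformly at random from every Voronoi cell;
3. for each candidate node `x`, cuts every tree at `x` and records
   `B_x[i,j]` = fraction of trees in which nodes `i, j` land in the same
   branch; single-linkage clustering of `B_x` is cut at thresholds
   `p_cut = 0.01 … 0.99`, and with cluster sizes `N₁ ≥ N₂ ≥ N₃ ≥ …`
   (clusters of ≥ 2 nodes) the raw branching score of `x` is

       b(x) = (1/99) · Σ_pcut Σ_{s≥3} N_s(p_cut) ;

4. reports the **relative branching score** `b_max / b_ref`, where
   `b_max = max_x b(x)` and `b_ref` is the 95th percentile of `b_max`
   values from synthetic *non-branching* null data (noise-free filled
   triangles) matched in cell count, dimensionality and `k`. Values
   above 1 indicate branching evidence beyond any comparable
   non-branching topology; the branches at the best threshold are mapped
   back to cells through their Voronoi nodes.

Applied recursively to each branch, the same test reconstructs
multi-level hierarchies; a branch stops recursing when its score drops
to ≤ 1 or it falls below 1000 cells. See `docs/methods.md` for the full
model, parameter table and design rationale.

## Worked example

```python
from treetop import TreeTopConfig, generate_geometry, run_treetop

# 10,000 cells on three arms radiating from a common progenitor state
cells = generate_geometry("star", n_obs=10_000, d=5, rho=0.0, seed=42)

config = TreeTopConfig(k=50, n_trees=200, seed=7)
result = run_treetop(cells, config)

print(f"branch node:            {result.branch_node}")
print(f"max raw score (b_max):  {result.b_max:.2f}")
print(f"reference b_ref:        {result.b_ref:.2f}")
print(f"relative score:         {result.relative_score:.2f}")
print(f"branches found:         {result.n_branches}")
```

prints

```
branch node:            22
max raw score (b_max):  10.61
reference b_ref:        2.00
relative score:         5.30
branches found:         3
```

Cutting the trees at node 22 (the arm junction) splits the other 49
nodes into three groups of co-branching nodes in almost every tree, so
the raw score ≈ the third arm's node count (10.61). The matched
non-branching null tops out at 2.00, giving a relative score of 5.30 —
strong branching evidence — and the three reported branches are the
three arms. Running the same analysis on a filled triangle, a path, a
circle or a Gaussian cloud gives relative scores ≤ 1.

The same pipeline from the shell:

```bash
treetop simulate --kind toggle --depth 2 --n-cells 15000 --seed 7 --output cells.csv
treetop recurse --input cells.csv --id-column cell_id --label-column label \
    --cofactor 5 -k 50 --n-trees 200 --seed 7 --outdir results/
```

`results/` then contains per-node scores (`scores.csv`), per-cell branch
assignments (`branches.csv`), the nested hierarchy (`hierarchy.json`),
and a manifest with the config snapshot and output checksums. Further
subcommands: `treetop preprocess`, `treetop run`, `treetop layout`,
`treetop reference-build` (extend the reference table at any grid cell).

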