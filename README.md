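# knotph

Persistent-homology analysis of open knotted backbone curves.

Given a protein backbone (Cα trace from a PDB file) or a synthetic open
curve, the package computes degree-1 Vietoris–Rips persistence diagrams
over Z/2 with representative cycles, exact piecewise-linear persistence
landscapes, two inter-curve distances (exact W1[L∞] Wasserstein on
diagrams, L1 on landscapes), group-level randomization tests on average
landscapes, 2-D Isomap embeddings of the resulting dissimilarity matrices,
and a geometric localization of the entanglement: the landscape peak unique
to a knotted family is mapped back to a diagram point, its representative
cycle is extracted, and its overlap with the annotated knot core is scored.
A noise/sparsity sweep quantifies robustness of the class separation.

Knot-theoretic annotations (knot core span, depth category, homology class)
are *inputs* — supplied via a metadata CSV for real structures, or ground
truth by construction for synthetic curves. The package never computes knot
invariants.

## Library overview

| module | contents |
|---|---|
| `knotph.curve_io` | PDB Cα extraction (`read_backbone`), interpolated point clouds (`interpolate_cloud`), metadata CSV |
| `knotph.synthetic_curves` | seeded open-trefoil generator with depth-controlling coiled tails, unknotted partner via localized strand passage, Gaussian noise |
| `knotph.rips_persistence` | degree-1 Rips diagrams (`rips_diagram_h1`), enclosing radius, representative cycles |
| `knotph.landscapes` | exact PL landscapes, averaging, L1/sup distances, peak ↔ diagram-point correspondence |
| `knotph.diagram_distances` | exact W1[L∞] Wasserstein, pairwise distance matrices |
| `knotph.topo_stats` | label-randomization test on average landscapes |
| `knotph.embedding` | Isomap (k-NN geodesics + classical MDS) from a precomputed dissimilarity matrix |
| `knotph.pipeline` | end-to-end orchestration: global analysis, feature localization, noise sweep |

```python
import knotph as kp

curve = kp.make_open_trefoil(n_core=60, tail_lengths=(10, 10), seed=1)
diagram = kp.rips_diagram_h1(curve.points)
landscape = kp.diagram_to_landscape(diagram, max_layers=10)
cycle = kp.representative_cycle(curve.points, tuple(diagram.pairs[0]))
```

## Command line

The `knotph` entry point exposes the stages as subcommands:

```bash
knotph synth --n-core 60 --tails 10,10 --seed 1 --unknot --out-prefix curve
knotph cloud structure.pdb --chain A --points-per-gap 5 --out cloud.csv
knotph ph cloud.csv --out diagram.csv
knotph landscape diagram.csv --out landscape.json
knotph dist d1.csv d2.csv d3.csv --metric wasserstein_w1_linf --out dm.csv
knotph embed dm.csv --n-neighbors 5 --out embedding.csv
knotph rtest landscapes_a/ landscapes_b/ --n-permutations 1000 --out test.json
knotph run-all --config config.yaml
knotph sweep --config config.yaml
```

`config.yaml` is a flat key-value file; `source:` selects the input
(`kind: synthetic` with generator parameters, or `kind: pdb` with
`pdb_dir` and `metadata_csv`). The metadata CSV columns are
`structure_id, chain, homology_class, depth_category, knot_core_start,
knot_core_end` (residue numbers, inclusive).

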