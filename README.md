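# flexatlas

Flexible annotation atlases for the mouse brain: hierarchy-preserving
editing of an Allen-style anatomical ontology + annotation volume, and
resting-state functional-connectivity analysis across that hierarchy.

## The problem

MRI studies of the mouse brain routinely hand-edit regions of interest
because published annotation volumes are *fixed*: structures can be
neither merged nor subdivided without breaking the anatomical hierarchy.
The Allen Institute resources make a principled alternative possible —
an anatomical ontology (AO, a JSON tree of brain structures) paired with
an annotation volume (AV, a 3D integer image whose voxels carry
structure ids; at 100 µm isotropic resolution 1 voxel = 1 nL) — but the
two are mutually inconsistent out of the box: some ontology leaves have
no voxels, and some inner nodes carry voxels of their own. Either kind
of *destructive* node breaks the leaf ↔ label bijection that any
merge/split operation depends on.

`flexatlas` implements the full construction pipeline:

1. **Preprocess** (`build_faa_base`): prune voxel-less leaves to a
   fixpoint, split each voxel-carrying inner node X into inner X + a new
   leaf `X_peri` holding X's own voxels, relabel the volume, append
   sizes. Node-count bookkeeping obeys
   `|base| = |original| − |voxelless removed| + |destructive inners|`
   (on the Allen 100 µm inputs this is the 1327 − 490 + 29 = 866
   pattern).
2. **Combine** (`combine_nodes`): collapse an inner node's whole subtree
   into a single leaf (all-or-none — partial sibling merges are not
   expressible), relabeling its descendant leaves' voxels to the node id.
3. **Double-side** (`make_double_sided`): renumber the tree 1..N in
   depth-first pre-order, add N for the right hemisphere, and attach
   `root_L`/`root_R` under a new root (id 2N + 1). Homotopic structures
   get distinct ids; e.g. with 50 nodes per hemisphere a node at left
   id 18 receives right id 68.
4. **Divide** (`divide_node`): split an oversized leaf into low/high
   children by thresholding a modality volume (gene-expression energy,
   fitted with two Gaussians, or axonal projection density, fitted with
   a continuous Poisson + Gaussian) at the valley of the fitted
   histogram curve.
5. **Analyze FC** (`flexatlas.fc`): per-run Pearson correlation between
   node BOLD series — including *inner* nodes, whose signal is the
   size-weighted average of descendant-leaf signals, s_A(t) = Σᵢ wᵢ
   sᵢ(t) / Σᵢ wᵢ — then Fisher z, one-sample t across runs,
   Benjamini–Hochberg FDR at α = 0.05, and the three-criterion search
   for FC "modulation" by a larger anatomical unit.

A seeded synthetic-fixture module (`flexatlas.synth`) generates toy
atlases with planted destructive nodes, bimodal modality volumes with a
known generative threshold, and multi-run BOLD with planted block
correlation, so the whole pipeline is testable without downloads.

## Worked example

```python
import flexatlas as fa
from flexatlas.synth import ToyAtlasSpec, make_toy_atlas

onto, vol, truth = make_toy_atlas(ToyAtlasSpec(seed=42))
print(len(onto), sorted(truth.destructive_leaves), sorted(truth.destructive_inners))
# 15 [14, 15] [7]

base = fa.build_faa_base(onto, vol)
print(len(base.ontology), truth.expected_base_nodes)
# 14 14        (15 − 2 voxelless leaves + 1 split inner)

ds, sidemap = fa.make_double_sided(base)
print(len(ds.ontology), sidemap.offset)
# 29 14        (2·14 + 1 nodes; right id = left id + 14)
```

The 15-node toy ontology contains two planted voxel-less leaves (ids 14,
15) and one voxel-carrying inner node (id 7). Preprocessing removes the
two leaves and gives the inner node a `_peri` child, landing exactly on
the predicted 14 nodes; double-siding yields 2·14 + 1 = 29 nodes with a
right-hemisphere id offset of 14.

The same stages are available as a CLI for file-based workflows:

```sh
faa preprocess --ontology AO.json --volume AV.nrrd --out-dir base
faa combine    --faa-dir base --spec combine.txt --out-dir coarse
faa sides      --faa-dir coarse --out-dir coarse2
faa divide     --faa-dir base --spec divide.json --out-dir detailed
faa fc         --faa-dir coarse2 --timeseries run*.csv --out-dir fc
faa fixtures   --out-dir fix --preset tiny
```

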