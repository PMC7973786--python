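# Methods

## Data model

An atlas is a pair (AO, AV): an **anatomical ontology** — a rooted tree
of brain structures, each with an integer id, name, acronym, parent and
ordered children — and an **annotation volume** — a 3D integer image on
an isotropic grid in which each voxel carries a structure id and 0 means
outside the brain. At 100 µm resolution one voxel is exactly 1 nL, so
voxel counts double as sizes in nL; other resolutions scale by
(voxel size / 100 µm)³. The pair is *consistent* when the nonzero labels
of the volume coincide with the voxel-backed leaves of the tree and no
inner node's id appears in the volume. All editing operations preserve
this invariant, which is revalidated after every stage
(`validate_faa`).

Hemisphere logic is driven by an explicit declaration on the volume
(`lr_axis`, `left_is_low`) rather than by header orientation strings:
Allen NRRD files are in PIR orientation while MRI pipelines typically
use RAS, and trusting headers makes the hemisphere split untestable.
When the left–right extent is odd, the midline slice is assigned to the
left side; this is an arbitrary but fixed convention, and it matters
only for midline voxels.

## Preprocessing

Destructive nodes are (a) leaves without voxels — combining them edits
the tree without changing the volume — and (b) inner nodes with voxels
of their own, whose size would change depending on whether they are
treated as leaf or inner. Preprocessing (1) prunes voxel-less leaves
**to a fixpoint**: a single pass can strand an inner node childless, and
a childless voxel-less node is itself a destructive leaf, so pruning
repeats until none remains; (2) splits each remaining voxel-carrying
inner node X into inner X plus a leaf "X, peripheral" (`X_peri`) with a
fresh id that takes over X's voxels; (3) relabels the volume; (4)
records sizes (leaf = voxel count; inner = sum over its leaves). Fresh
ids start at the next power of ten above the largest existing id — they
can never collide and are visually distinct in downstream tables.

Volume labels absent from the ontology are a hard error by default; an
opt-in quarantine mode collects them into an explicit "unassigned" leaf
under the root so the inconsistency is surfaced rather than silently
dropped.

## Combining and double-siding

Combining collapses the *entire* subtree of an inner node into a leaf
carrying the union of its descendants' voxels. The all-or-none rule is
what preserves the hierarchy: merging a strict subset of siblings would
leave the parent's size ill-defined. Nested combine targets are
redundant and resolved outermost-wins with a warning. A leaf target is
rejected by default; a lenient mode skips it with a warning, which makes
the operation idempotent.

Double-siding renumbers the single-sided tree 1..N in depth-first
pre-order (following stored children order, so the numbering is fully
reproducible), adds the constant N for the right-hemisphere copy, and
installs a new root with id 2N + 1 over `root_L`/`root_R`. Acronyms get
`_L`/`_R` suffixes. A structure lying wholly in one hemisphere keeps an
empty, size-0 twin on the other side — dropping it would break the
left/right tree isomorphism — and empty twins are listed in the
provenance log. The renumbering map is exported as a CSV
(old_id, acronym, left_id, right_id).

## Dividing by a modality volume

A leaf is divided by the scalar values of a modality volume at its
voxels. Two fitted models are supported:

- **two_gaussian** (gene-expression energy): w₁·N(μ₁,σ₁²) + w₂·N(μ₂,σ₂²),
- **gaussian_poisson** (projection density): w_p·Pois(λ) + w_g·N(μ,σ²),
  where the Poisson mass function is extended continuously via the gamma
  function so least squares is differentiable in λ; the Poisson
  component exists to absorb the near-zero mass of projection data, so
  zero-valued voxels are included by default (a flag excludes them).

The histogram uses a deterministic rule: Freedman–Diaconis width with a
minimum of 30 bins (cap 512) and the left edge anchored at 0 (or the
data minimum when negative values occur). The density is fitted by
bounded least squares (`scipy.optimize.curve_fit`) from two moment-based
starting points; the better residual wins.

The threshold θ is the **interior local minimum of the fitted curve
between the two component centers** — the valley separating the low and
high populations, which is where a two-component histogram visually
separates. When the fitted curve has no interior minimum (a monotone
shoulder, possible with heavily overlapping components), θ falls back to
the second-derivative zero crossing between the centers nearest the
flattest point of the shoulder. The rule applied is recorded on the
model (`threshold_rule`). We deliberately did **not** define θ as the
between-mode inflection of the fitted curve in the bimodal case: for two
well-separated Gaussians those inflections sit about one σ from each
mode (the valley is convex throughout), so an inflection rule cannot
recover the separating valley — e.g. for equal N(0,1) + N(6,1) it would
return ≈1 or ≈5 instead of 3.

Ties at θ go to the high side (voxels with value < θ are "low", ≥ θ
"high"). Multiple projection experiments are aggregated by voxelwise
maximum and then mirror-symmetrized (max with the left–right flip), in
that order. Modality volumes must already be resampled to the atlas
grid; resampling is out of scope. A threshold that leaves either side
empty aborts the division with an explicit error and the node untouched.

Division is exactly inverted by combining at the new inner node, which
restores the original sizes and label volume bit for bit.

## Functional connectivity

Leaf signals are unweighted voxel means of denoised BOLD; inner-node
signals are size-weighted means of descendant-leaf signals, which equals
the direct voxel mean over the inner node's voxel union exactly (not
approximately), so the module can work from either 4D volumes or per-run
node tables. Analysis is restricted to the grey-matter branch
(parenchyma), excluding fiber tracts and ventricles; branch acronyms are
configurable and matched with `_L`/`_R` suffixes on double-sided
atlases.

Per-run FC is Pearson r. Group significance uses a one-sample t of
Fisher z against 0 across runs, with Benjamini–Hochberg FDR at α = 0.05
over the upper triangle of the analyzed matrix; pairs undefined in any
run (zero-variance series) are excluded from the family rather than
imputed. Reported mean FC is tanh of the mean z with non-significant
entries set to 0. The source literature describes the significance test
once as "two-sample"; a two-sample test has no second sample in this
design, and the per-FC significance and paired follow-ups require
one-sample/paired forms, which is what is implemented.

Condition comparisons: paired t with BH-FDR (two conditions), one-way
ANOVA with Tukey HSD (independent groups), or one-way repeated-measures
ANOVA with Holm-adjusted paired-t post-hocs (computed by the standard
sums-of-squares partition; cross-checked against pingouin in the test
suite).

The modulation search screens source leaves S against inner nodes A
using the group mean FC matrix: (1) FC(S,A) > 0.8; (2) A is not an
ancestor of S; (3) FC(S,A) strictly exceeds FC(S,B) for every
voxel-backed descendant leaf B of A. Per-criterion survivor counts are
reported as a funnel. Layer-wise FC extracts the layer × layer block
(per-run layer-pair FC = mean Fisher z over cross-layer entries) and
compares stated layer pairs with the ANOVA machinery.

## Synthetic fixtures

The generators emulate the structural features the pipeline must
handle, not realistic physiology:

- **Toy atlas**: grey / fiber-tracts / ventricle branches, a requested
  number of planted voxel-less leaves and voxel-carrying inner nodes,
  1–3 voxels per live label placed randomly (mirrored placement on
  request). Ground truth includes the planted destructive sets and the
  predicted post-preprocessing node count.
- **Bimodal volume**: per-voxel component assignment by weight, values
  sampled from the chosen mixture; the true threshold is the interior
  minimum of the generative mixture on a dense grid; the component
  assignment is returned so split sizes can be checked exactly.
- **Synthetic BOLD**: leaf series drawn from a multivariate normal with
  block correlation (within ρ_w, between ρ_b); defaults of 13 runs ×
  400 time points at TR 1.5 s mirror a typical awake-mouse acquisition
  scale. Optional 4D rendering gives each voxel its leaf series plus
  independent Gaussian noise so voxel-mean extraction can be tested.

All generators take an explicit seed and are deterministic given it.
What passing these tests does *not* show: robustness to registration
error, physiological noise spectra, partial-volume effects at node
boundaries, or hemodynamic confounds — none of which the generators
model.

## Numerical choices and limitations

- Labels are kept as 64-bit integers in memory (Allen ids reach ~6.1×10⁸);
  files store the narrowest unsigned type that fits, and editing
  operations upcast before assigning fresh ids.
- NRRD support is a built-in minimal codec (NRRD0004, 3D,
  little-endian, raw/gzip) covering what Allen files use; NIfTI goes
  through nibabel.
- Fisher transforms clip |r| at 1 − 10⁻¹² to keep z finite for
  degenerate (perfectly correlated) toy inputs.
- Problem sizes in the test suite — toy grids of 8–12³ voxels, ≤ 15-node
  ontologies, 13 runs × 400 time points, 20-seed threshold sweeps — were
  chosen as the smallest scales at which every property is
  non-trivially exercised.
- Interactive visualization (icicle plots, graph layouts) is out of
  scope; the structured JSON export and CSV tables are the exchange
  formats.
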