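"""Synthetic toy atlases, modality volumes and BOLD runs with known truth.

These generators emulate, at desk scale, the structure of the real
inputs: an ontology with grey-matter / fiber-tract / ventricle branches
containing deliberately *destructive* nodes, a matching label volume, a
bimodal modality volume with known component parameters, and multi-run
node time series with a planted block correlation structure.  Every
generator is deterministic given its seed, and each returns a ground
truth record sufficient to assert downstream invariants directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .divide import _gaussian_poisson, _two_gaussian
from .errors import CapacityError, OntologyLookupError
from .fc import NodeTimeSeries
from .ontology import AnnotationOntology, OntologyNode
from .volume import LabeledVolume, ScalarVolume

__all__ = [
    "ToyAtlasSpec",
    "ToyAtlasTruth",
    "BimodalSpec",
    "BoldSpec",
    "make_toy_atlas",
    "make_bimodal_volume",
    "make_synthetic_bold",
]


@dataclass
class ToyAtlasSpec:
    """Shape of a generated toy atlas.

    ``n_grey_leaves`` counts voxel-backed leaves under the grey branch;
    each destructive inner node hosts two of them and additionally
    carries voxels of its own.  Destructive leaves are voxel-less leaves
    under grey.  ``mirror_symmetric`` places identical labels in both
    hemispheres (the grid's left–right axis is axis 0).
    """

    n_grey_leaves: int = 6
    n_destructive_leaves: int = 2
    n_destructive_inners: int = 1
    shape: tuple[int, int, int] = (8, 8, 8)
    mirror_symmetric: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_grey_leaves < 2 * self.n_destructive_inners:
            raise ValueError(
                "need at least two grey leaves per destructive inner node"
            )


@dataclass
class ToyAtlasTruth:
    """What the generator planted, for direct downstream assertions."""

    destructive_leaves: set[int]
    destructive_inners: set[int]
    sizes: dict[int, int]
    total_nodes: int
    expected_base_nodes: int


def make_toy_atlas(spec: ToyAtlasSpec) -> tuple[AnnotationOntology, LabeledVolume, ToyAtlasTruth]:
    """Build a small ontology + label volume with planted destructive nodes.

    The ontology has root → {grey, fiber tracts, VS}; fiber tracts and VS
    each carry one voxel-backed leaf.  Expected atlas-base node count =
    total − destructive leaves + destructive inners (each split adds one
    peripheral leaf).
    """
    rng = np.random.default_rng(spec.seed)
    nodes: list[OntologyNode] = []
    next_id = [1]

    def add(name, acronym, parent):
        nid = next_id[0]
        next_id[0] += 1
        nodes.append(OntologyNode(nid, name, acronym, parent, []))
        if parent is not None:
            next(n for n in nodes if n.id == parent).children_ids.append(nid)
        return nid

    root = add("root", "root", None)
    grey = add("grey matter", "grey", root)
    fiber = add("fiber tracts", "fiber tracts", root)
    vs = add("ventricular systems", "VS", root)
    fx = add("columns of the fornix", "fxs", fiber)
    vl = add("lateral ventricle", "VL", vs)

    voxel_labels: list[int] = [fx, vl]
    destructive_inners: set[int] = set()
    destructive_leaves: set[int] = set()
    remaining = spec.n_grey_leaves
    for k in range(spec.n_destructive_inners):
        d = add(f"destructive inner {k}", f"DI{k}", grey)
        destructive_inners.add(d)
        voxel_labels.append(d)  # carries its own voxels
        for j in range(2):
            c = add(f"DI{k} child {j}", f"DI{k}c{j}", d)
            voxel_labels.append(c)
            remaining -= 1
    for k in range(remaining):
        g = add(f"grey leaf {k}", f"G{k}", grey)
        voxel_labels.append(g)
    for k in range(spec.n_destructive_leaves):
        d = add(f"destructive leaf {k}", f"DL{k}", grey)
        destructive_leaves.add(d)

    onto = AnnotationOntology.from_nodes(nodes)

    data = np.zeros(spec.shape, dtype=np.int64)
    n_lr = spec.shape[0]
    if spec.mirror_symmetric and n_lr % 2:
        raise ValueError("mirror_symmetric needs an even extent along the left-right axis")
    half = n_lr // 2 if spec.mirror_symmetric else n_lr
    coords = np.argwhere(np.ones((half,) + spec.shape[1:], dtype=bool))
    rng.shuffle(coords)
    want = {lab: 1 + int(rng.integers(0, 3)) for lab in voxel_labels}
    if sum(want.values()) > len(coords):
        raise CapacityError(
            f"grid {spec.shape} too small for {sum(want.values())} requested voxels"
        )
    pos = 0
    for lab in voxel_labels:
        for _ in range(want[lab]):
            i, j, k = coords[pos]
            pos += 1
            data[i, j, k] = lab
            if spec.mirror_symmetric:
                data[n_lr - 1 - i, j, k] = lab
    vol = LabeledVolume(data, voxel_size_um=100.0, lr_axis=0, left_is_low=True)
    sizes = {lab: want[lab] * (2 if spec.mirror_symmetric else 1) for lab in voxel_labels}
    total = len(nodes)
    truth = ToyAtlasTruth(
        destructive_leaves=destructive_leaves,
        destructive_inners=destructive_inners,
        sizes=sizes,
        total_nodes=total,
        expected_base_nodes=total - len(destructive_leaves) + len(destructive_inners),
    )
    return onto, vol, truth


@dataclass
class BimodalSpec:
    """Two-component scalar values planted inside one node.

    ``params`` uses the threshold-model keys: for ``two_gaussian``
    w1/mu1/sigma1/w2/mu2/sigma2, for ``gaussian_poisson``
    w_p/lam/w_g/mu/sigma.
    """

    node_id: int
    model_kind: str = "two_gaussian"
    params: dict[str, float] = field(
        default_factory=lambda: {"w1": 0.5, "mu1": 1.0, "sigma1": 0.2,
                                 "w2": 0.5, "mu2": 9.0, "sigma2": 0.2}
    )
    seed: int = 0


def _mixture_pdf(kind: str, p: dict[str, float]):
    if kind == "two_gaussian":
        return (lambda x: _two_gaussian(x, p["w1"], p["mu1"], p["sigma1"], p["mu2"], p["sigma2"]),
                p["mu1"], p["mu2"])
    return (lambda x: _gaussian_poisson(x, p["w_p"], p["lam"], p["mu"], p["sigma"]),
            p["lam"], p["mu"])


def generative_threshold(kind: str, params: dict[str, float]) -> float:
    """Interior minimum of the generative mixture between its centers."""
    pdf, c1, c2 = _mixture_pdf(kind, params)
    lo, hi = min(c1, c2), max(c1, c2)
    grid = np.linspace(lo, hi, 8001)[1:-1]
    return float(grid[int(np.argmin(pdf(grid)))])


def make_bimodal_volume(
    av: LabeledVolume, spec: BimodalSpec
) -> tuple[ScalarVolume, float, np.ndarray]:
    """Plant two-component values in the target node's voxels.

    Returns the scalar volume (zero outside the node), the true
    threshold (interior minimum of the generative mixture), and a boolean
    volume marking voxels drawn from the *high* component.
    """
    mask = av.data == spec.node_id
    n = int(mask.sum())
    if n == 0:
        raise OntologyLookupError(f"node {spec.node_id} absent from the volume")
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    if spec.model_kind == "two_gaussian":
        w_high = p["w2"]
        high = rng.random(n) < w_high
        vals = np.where(
            high,
            rng.normal(p["mu2"], p["sigma2"], n),
            rng.normal(p["mu1"], p["sigma1"], n),
        )
    elif spec.model_kind == "gaussian_poisson":
        w_high = p["w_g"]
        high = rng.random(n) < w_high
        vals = np.where(
            high,
            rng.normal(p["mu"], p["sigma"], n),
            rng.poisson(p["lam"], n).astype(float),
        )
    else:
        raise ValueError(f"unknown model kind {spec.model_kind!r}")
    vals = np.clip(vals, 0.0, None)
    data = np.zeros(av.shape, dtype=float)
    data[mask] = vals
    high_vol = np.zeros(av.shape, dtype=bool)
    high_vol[mask] = high
    kind = "gene_energy" if spec.model_kind == "two_gaussian" else "projection_density"
    scalar = ScalarVolume(data, av.voxel_size_um, av.lr_axis, av.left_is_low, kind)
    return scalar, generative_threshold(spec.model_kind, p), high_vol


@dataclass
class BoldSpec:
    """Planted block-correlation BOLD: leaves in the same community share
    correlation ``rho_within``; across communities ``rho_between``.
    Defaults mirror a typical awake-mouse acquisition scale: 13 runs of
    400 repetitions at TR 1.5 s."""

    blocks: dict[int, int] = field(default_factory=dict)
    rho_within: float = 0.7
    rho_between: float = 0.0
    n_runs: int = 13
    n_timepoints: int = 400
    t_r_seconds: float = 1.5
    noise_sigma: float = 0.1
    seed: int = 0
    render_4d: bool = False


def make_synthetic_bold(
    onto: AnnotationOntology, av: LabeledVolume, spec: BoldSpec
) -> dict:
    """Draw per-leaf series from a block-structured multivariate normal.

    Returns ``{"runs": [NodeTimeSeries...], "leaf_ids": [...],
    "correlation": C, "volumes": [4D arrays] or None}``.  With
    ``render_4d`` each voxel gets its leaf's series plus independent
    N(0, noise_sigma²) noise, so voxel-mean extraction can be tested.
    """
    leaf_ids = sorted(spec.blocks) if spec.blocks else sorted(
        i for i in onto.leaf_ids() if (av.data == i).any()
    )
    blocks = spec.blocks or {i: 0 for i in leaf_ids}
    n = len(leaf_ids)
    C = np.full((n, n), spec.rho_between, dtype=float)
    for a in range(n):
        for b in range(n):
            if blocks[leaf_ids[a]] == blocks[leaf_ids[b]]:
                C[a, b] = spec.rho_within
    np.fill_diagonal(C, 1.0)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ValueError("implied block correlation matrix is not positive definite") from None

    rng = np.random.default_rng(spec.seed)
    runs: list[NodeTimeSeries] = []
    volumes: list[np.ndarray] | None = [] if spec.render_4d else None
    for r in range(spec.n_runs):
        sig = L @ rng.standard_normal((n, spec.n_timepoints))
        series = {leaf_ids[k]: sig[k].copy() for k in range(n)}
        runs.append(NodeTimeSeries(f"run{r:02d}", series, spec.t_r_seconds))
        if spec.render_4d:
            vol4d = np.zeros(av.shape + (spec.n_timepoints,), dtype=float)
            for k, nid in enumerate(leaf_ids):
                mask = av.data == nid
                m = int(mask.sum())
                vol4d[mask] = sig[k] + spec.noise_sigma * rng.standard_normal((m, spec.n_timepoints))
            volumes.append(vol4d)
    return {"runs": runs, "leaf_ids": leaf_ids, "correlation": C, "volumes": volumes}
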