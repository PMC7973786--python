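"""Dividing a leaf node by a modality volume thresholded objectively.

A leaf (e.g. hippocampal CA1 or caudoputamen CP) is split into low/high
sub-leaves by thresholding gene-expression energy or axonal projection
density inside the node.  The threshold is derived from a two-component
curve fitted to the value histogram: a sum of two Gaussians for gene
energy, or a (continuous) Poisson plus a Gaussian for projection density,
whose near-zero mass the Poisson component absorbs.  The cut point θ is
the interior minimum of the fitted curve between the two component
centers — the valley separating the low and high populations; when the
fitted curve has no interior minimum (a monotone shoulder), the
second-derivative zero crossing between the centers is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import gammaln

from .base import FAA, IdAllocator, append_sizes, validate_faa
from .errors import DegenerateSplitError, FitError, OntologyLookupError, SampleSizeError
from .ontology import OntologyNode
from .volume import LabeledVolume, ScalarVolume, label_sizes, mirror

__all__ = [
    "ThresholdModel",
    "DivideSpec",
    "aggregate_projection",
    "node_values",
    "fit_threshold",
    "divide_node",
]

_SUFFIXES = {"gene_energy": ("_geneL", "_geneH"), "projection_density": ("_fiberL", "_fiberH")}


@dataclass
class ThresholdModel:
    """Fitted mixture curve and the threshold derived from it.

    ``params`` holds, for ``two_gaussian``: w1, mu1, sigma1, w2, mu2,
    sigma2 (w1+w2=1, mu1<mu2); for ``gaussian_poisson``: w_p, lam, w_g,
    mu, sigma.  ``threshold_rule`` records whether θ came from the
    interior minimum or from an inflection of the fitted curve.
    """

    model_kind: str
    params: dict[str, float]
    threshold: float
    converged: bool
    residual_norm: float
    threshold_rule: str = "interior_minimum"
    fit_diagnostics: dict = field(default_factory=dict)

    def centers(self) -> tuple[float, float]:
        if self.model_kind == "two_gaussian":
            return self.params["mu1"], self.params["mu2"]
        return self.params["lam"], self.params["mu"]

    def curve(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        if self.model_kind == "two_gaussian":
            return _two_gaussian(x, p["w1"], p["mu1"], p["sigma1"], p["mu2"], p["sigma2"])
        return _gaussian_poisson(x, p["w_p"], p["lam"], p["mu"], p["sigma"])


@dataclass
class DivideSpec:
    """What to divide and with which modality volume(s).

    Default acronym suffixes follow the modality: ``_geneL``/``_geneH``
    for gene-expression energy, ``_fiberL``/``_fiberH`` for projection
    density.  ``symmetrize`` (mirror-max) defaults to true for projection
    data, whose tracer injections are unilateral.
    """

    node: int | str
    modality: str = "gene_energy"
    source_volumes: list = field(default_factory=list)
    suffix_low: str | None = None
    suffix_high: str | None = None
    symmetrize: bool | None = None

    def __post_init__(self):
        if self.modality not in _SUFFIXES:
            raise ValueError(f"unknown modality {self.modality!r}")
        lo, hi = _SUFFIXES[self.modality]
        if self.suffix_low is None:
            self.suffix_low = lo
        if self.suffix_high is None:
            self.suffix_high = hi
        if self.suffix_low == self.suffix_high:
            raise ValueError("low/high suffixes must differ")
        if self.symmetrize is None:
            self.symmetrize = self.modality == "projection_density"


def aggregate_projection(volumes: list[ScalarVolume], symmetrize: bool = True) -> ScalarVolume:
    """Voxelwise maximum over experiments, optionally mirror-symmetrized.

    Multiple tracer experiments targeting the same pathway are combined
    by max projection; with ``symmetrize`` the result is additionally
    max-combined with its left–right mirror so the output is symmetric.
    """
    if not volumes:
        raise ValueError("aggregate_projection needs at least one volume")
    shape = volumes[0].shape
    for v in volumes[1:]:
        if v.shape != shape:
            raise ValueError(f"grid mismatch: {v.shape} != {shape}")
    out = volumes[0].with_data(np.maximum.reduce([v.data for v in volumes]))
    if symmetrize:
        out = out.with_data(np.maximum(out.data, mirror(out).data))
    return out


def node_values(scalar: ScalarVolume, vol: LabeledVolume, node_id: int) -> np.ndarray:
    """Scalar values at exactly the node's voxels (length = node size)."""
    if scalar.shape != vol.shape:
        raise ValueError(f"grid mismatch: scalar {scalar.shape} vs labels {vol.shape}")
    mask = vol.data == node_id
    if not mask.any():
        raise OntologyLookupError(f"label {node_id} not present in the volume")
    return scalar.data[mask]


# -- model curves -----------------------------------------------------------

def _two_gaussian(x, w1, mu1, s1, mu2, s2):
    g1 = np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
    g2 = np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
    return w1 * g1 + (1.0 - w1) * g2


def _poisson_cont(x, lam):
    # gamma-function extension of the Poisson mass function, differentiable in lam
    return np.exp(x * np.log(lam) - lam - gammaln(x + 1.0))


def _gaussian_poisson(x, w_p, lam, mu, s):
    g = np.exp(-0.5 * ((x - mu) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    return w_p * _poisson_cont(x, lam) + (1.0 - w_p) * g


def _histogram(values: np.ndarray, min_bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic density histogram: Freedman–Diaconis width, at least
    ``min_bins`` bins, left edge anchored at 0 (or the data minimum if
    negative values are present)."""
    v = np.asarray(values, dtype=float)
    hi = float(v.max())
    lo = min(0.0, float(v.min()))
    if hi <= lo:
        raise FitError("values are constant; no histogram to fit")
    q75, q25 = np.percentile(v, [75, 25])
    width = 2.0 * (q75 - q25) / len(v) ** (1.0 / 3.0)
    n_bins = min_bins if width <= 0 else max(min_bins, int(np.ceil((hi - lo) / width)))
    n_bins = min(n_bins, 512)
    edges = np.linspace(lo, hi, n_bins + 1)
    dens, _ = np.histogram(v, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


def fit_threshold(
    values,
    model_kind: str = "two_gaussian",
    min_samples: int = 50,
    include_zeros: bool = True,
) -> ThresholdModel:
    """Fit a two-component curve to the value histogram and derive θ.

    Bin counts are fitted by least squares.  θ is the interior local
    minimum of the fitted curve strictly between the component centers;
    if the curve is shoulder-shaped (no interior minimum) the
    second-derivative zero crossing between the centers nearest the flat
    point is used.  Zero-valued voxels are included by default — in
    projection data the Poisson component exists to absorb that mass.
    """
    v = np.asarray(values, dtype=float).ravel()
    if not include_zeros:
        v = v[v > 0]
    if v.size < min_samples:
        raise SampleSizeError(f"need at least {min_samples} values, got {v.size}")
    x, dens = _histogram(v)

    lo, hi = float(v.min()), float(v.max())
    med = float(np.median(v))
    spread = max(float(v.std()), (hi - lo) / 100.0, 1e-6)
    low_half, high_half = v[v <= med], v[v > med]
    m1 = float(low_half.mean()) if low_half.size else lo
    m2 = float(high_half.mean()) if high_half.size else hi
    s1 = max(float(low_half.std()), spread / 10.0) if low_half.size else spread
    s2 = max(float(high_half.std()), spread / 10.0) if high_half.size else spread

    if model_kind == "two_gaussian":
        fn = _two_gaussian
        p0s = [
            (0.5, m1, s1, m2, s2),
            (0.5, lo + 0.25 * (hi - lo), spread / 2, lo + 0.75 * (hi - lo), spread / 2),
        ]
        bounds = ([1e-3, lo - spread, 1e-9, lo - spread, 1e-9],
                  [1 - 1e-3, hi + spread, hi - lo + spread, hi + spread, hi - lo + spread])
    elif model_kind == "gaussian_poisson":
        fn = _gaussian_poisson
        lam0 = max(m1, 0.1)
        p0s = [(0.5, lam0, m2, s2), (0.7, max(med, 0.1), hi * 0.8, spread / 2)]
        bounds = ([1e-3, 1e-6, lo - spread, 1e-9], [1 - 1e-3, hi + spread, hi + spread, hi - lo + spread])
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    popt = None
    resid = np.inf
    for p0 in p0s:
        try:
            cand, _ = curve_fit(fn, x, dens, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        r = float(np.linalg.norm(fn(x, *cand) - dens))
        if r < resid:
            popt, resid = cand, r
    if popt is None:
        raise FitError(
            f"{model_kind} fit did not converge after {len(p0s)} starts",
            diagnostics={"n": int(v.size), "n_bins": len(x)},
        )

    if model_kind == "two_gaussian":
        w1, mu1, sg1, mu2, sg2 = (float(t) for t in popt)
        if mu1 > mu2:  # canonical order: mu1 < mu2
            w1, mu1, sg1, mu2, sg2 = 1.0 - w1, mu2, sg2, mu1, sg1
        params = {"w1": w1, "mu1": mu1, "sigma1": sg1, "w2": 1.0 - w1, "mu2": mu2, "sigma2": sg2}
    else:
        w_p, lam, mu, sg = (float(t) for t in popt)
        params = {"w_p": w_p, "lam": lam, "w_g": 1.0 - w_p, "mu": mu, "sigma": sg}

    model = ThresholdModel(
        model_kind=model_kind, params=params, threshold=np.nan,
        converged=True, residual_norm=resid,
        fit_diagnostics={"n": int(v.size), "n_bins": len(x),
                         "bin_width": float(x[1] - x[0]) if len(x) > 1 else 0.0,
                         "binning": "freedman-diaconis, min 30 bins, left edge 0"},
    )
    c1, c2 = model.centers()
    if c1 > c2:
        c1, c2 = c2, c1
    theta, rule = _threshold_from_curve(model.curve, c1, c2)
    model.threshold = theta
    model.threshold_rule = rule
    return model


def _threshold_from_curve(curve, c1: float, c2: float) -> tuple[float, str]:
    """θ between the component centers: the curve's interior local
    minimum when one exists, else the between-centers inflection."""
    span = c2 - c1
    if span <= 0:
        raise FitError("component centers coincide; no interior to threshold")
    grid = np.linspace(c1, c2, 4001)[1:-1]
    f = curve(grid)
    k = int(np.argmin(f))
    if 0 < k < len(grid) - 1:
        return float(grid[k]), "interior_minimum"
    # shoulder: f monotone between centers; use inflection (f'' zero crossing)
    d2 = np.gradient(np.gradient(f, grid), grid)
    sign = np.sign(d2)
    crossings = np.where(np.diff(sign) != 0)[0]
    if crossings.size:
        # nearest to the flattest point of the shoulder
        d1 = np.gradient(f, grid)
        flat = grid[int(np.argmin(np.abs(d1)))]
        j = crossings[int(np.argmin(np.abs(grid[crossings] - flat)))]
        return float(grid[j]), "inflection"
    return float(grid[k]), "boundary_minimum"


def divide_node(
    faa: FAA,
    spec: DivideSpec,
    scalar: ScalarVolume,
    model: ThresholdModel,
    allocator: IdAllocator | None = None,
) -> FAA:
    """Split a leaf into low/high children at the model's threshold.

    Voxels with value < θ go to the low child, ≥ θ to the high child
    (ties high).  The old leaf becomes an inner node; the two children
    get fresh ids and the old acronym plus the spec's suffixes.  If all
    voxels fall on one side the node is left untouched and a
    :class:`DegenerateSplitError` is raised.
    """
    onto = faa.ontology.copy()
    nid = onto.resolve(spec.node)
    node = onto.nodes[nid]
    if not node.is_leaf:
        raise ValueError(f"divide target {spec.node!r} (id {nid}) is not a leaf")
    mask = faa.volume.data == nid
    if not mask.any():
        raise OntologyLookupError(f"leaf {nid} has no voxels in the volume")
    low_mask = mask & (scalar.data < model.threshold)
    high_mask = mask & ~low_mask
    n_low, n_high = int(low_mask.sum()), int(high_mask.sum())
    if n_low == 0 or n_high == 0:
        raise DegenerateSplitError(
            f"threshold {model.threshold:.6g} puts all {int(mask.sum())} voxels of node "
            f"{node.acronym!r} on one side (low={n_low}, high={n_high}); node left untouched"
        )
    if allocator is None:
        allocator = IdAllocator(set(onto.nodes))
    id_low, id_high = allocator.allocate(), allocator.allocate()
    for new_id, suffix, tag in ((id_low, spec.suffix_low, "low"), (id_high, spec.suffix_high, "high")):
        onto.nodes[new_id] = OntologyNode(
            id=new_id,
            name=f"{node.name}, {tag} {spec.modality.replace('_', ' ')}",
            acronym=node.acronym + suffix,
            parent_id=nid,
            children_ids=[],
            color_hex=node.color_hex,
        )
        node.children_ids.append(new_id)
    onto.validate()

    # fresh ids may exceed the stored dtype's range
    data = faa.volume.data.astype(np.int64, copy=True)
    data[low_mask] = id_low
    data[high_mask] = id_high
    vol = faa.volume.with_data(data)
    append_sizes(onto, label_sizes(vol))
    out = FAA(onto, vol, list(faa.provenance))
    out.log(
        f"divided {node.acronym!r} (id {nid}) at theta={model.threshold:.6g} "
        f"({model.threshold_rule}) into {node.acronym}{spec.suffix_low} (id {id_low}, {n_low} vox) "
        f"and {node.acronym}{spec.suffix_high} (id {id_high}, {n_high} vox)"
    )
    validate_faa(out)
    return out
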