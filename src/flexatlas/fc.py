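"""Resting-state functional connectivity across the anatomical hierarchy.

Node time series are voxel means of denoised BOLD within each leaf; an
inner node's signal is the size-weighted average of its descendant
leaves' signals, which equals the direct voxel mean over the inner
node's voxel union exactly (weights are voxel counts).  Per-run FC is
Pearson correlation; group statistics Fisher-transform r, test each pair
against zero with a one-sample t across runs, and control the false
discovery rate with Benjamini–Hochberg at α (default 0.05).  Mean FC is
reported as tanh of the mean z with non-significant entries set to 0.

``modulation_search`` screens for source leaves whose FC to an inner node
exceeds their FC to every descendant leaf of that node — the signature a
"larger functional unit" would leave — and ``layer_fc`` compares FC
within vs. between cortical layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CoverageError, InsufficientDataError, OntologyLookupError, PairingError
from .ontology import AnnotationOntology
from .volume import LabeledVolume

__all__ = [
    "NodeTimeSeries",
    "FCResult",
    "extract_node_timeseries",
    "inner_node_signal",
    "node_signal",
    "fc_matrices",
    "group_fc_stats",
    "compare_fc",
    "modulation_search",
    "layer_fc",
]

_Z_CLIP = 1.0 - 1e-12


@dataclass
class NodeTimeSeries:
    """Per-run node signals: map node id → vector of T values."""

    run_id: str
    series: dict[int, np.ndarray]
    t_r_seconds: float = 1.5

    def n_timepoints(self) -> int:
        return len(next(iter(self.series.values()))) if self.series else 0


def extract_node_timeseries(
    bold: np.ndarray,
    av: LabeledVolume,
    leaf_ids,
    run_id: str = "run",
    t_r_seconds: float = 1.5,
) -> NodeTimeSeries:
    """Unweighted voxel-mean BOLD series per leaf from a 4D volume.

    ``bold`` has shape ``av.shape + (T,)``.  Leaves without voxels are
    excluded with a warning.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4 or bold.shape[:3] != av.shape:
        raise ValueError(f"BOLD shape {bold.shape} does not extend atlas grid {av.shape}")
    series: dict[int, np.ndarray] = {}
    for nid in leaf_ids:
        mask = av.data == nid
        if not mask.any():
            warnings.warn(f"leaf {nid} has no voxels in the atlas volume; excluded")
            continue
        series[int(nid)] = bold[mask].mean(axis=0)
    return NodeTimeSeries(run_id, series, t_r_seconds)


def inner_node_signal(
    ts: NodeTimeSeries, onto: AnnotationOntology, sizes: dict[int, int], inner_id: int
) -> np.ndarray:
    """Size-weighted average of descendant-leaf signals.

    s_A(t) = Σ_i w_i s_i(t) / Σ_i w_i with w_i the leaf voxel count; when
    leaf signals are voxel means this equals the voxel mean over the
    union of the inner node's voxels exactly.
    """
    leaves = sorted(i for i in onto.leaves_under(inner_id) if sizes.get(i, 0) > 0)
    missing = [i for i in leaves if i not in ts.series]
    if missing:
        raise CoverageError(f"run {ts.run_id}: missing leaf series for {missing}")
    if not leaves:
        raise CoverageError(f"inner node {inner_id} has no voxel-backed descendant leaves")
    w = np.array([sizes[i] for i in leaves], dtype=float)
    mat = np.stack([ts.series[i] for i in leaves])
    return (w @ mat) / w.sum()


def node_signal(ts, onto, sizes, node_id: int) -> np.ndarray:
    """Signal of any node: stored series for a leaf, derived for an inner."""
    if onto.nodes[node_id].is_leaf:
        if node_id not in ts.series:
            raise CoverageError(f"run {ts.run_id}: no series for leaf {node_id}")
        return ts.series[node_id]
    return inner_node_signal(ts, onto, sizes, node_id)


def fc_matrices(
    runs: list[NodeTimeSeries],
    node_ids,
    onto: AnnotationOntology,
    sizes: dict[int, int],
) -> tuple[list[int], list[np.ndarray]]:
    """Per-run Pearson correlation matrices over the given node set.

    Inner-node series are derived on the fly.  A zero-variance series
    yields NaN entries (excluded from group statistics) with a warning.
    """
    if not runs:
        raise InsufficientDataError("need at least one run")
    ids = sorted(int(i) for i in node_ids)
    mats: list[np.ndarray] = []
    for ts in runs:
        sig = np.stack([node_signal(ts, onto, sizes, i) for i in ids])
        if sig.shape[1] < 3:
            raise ValueError("each series needs at least 3 time points")
        sd = sig.std(axis=1)
        bad = np.where(sd == 0)[0]
        if bad.size:
            warnings.warn(
                f"run {ts.run_id}: zero-variance series for nodes "
                f"{[ids[b] for b in bad]}; correlations set to NaN"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(sig)
        r[bad, :] = np.nan
        r[:, bad] = np.nan
        np.fill_diagonal(r, 1.0)
        mats.append(r)
    return ids, mats


@dataclass
class FCResult:
    """Group-level FC: per-run r, mean z, t/p/q and the significance mask."""

    node_ids: list[int]
    r_runs: list[np.ndarray]
    mean_z: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig: np.ndarray
    mean_r: np.ndarray
    alpha: float = 0.05
    r_criterion: float = 0.8
    n_runs: int = 0
    index: dict[int, int] = field(default_factory=dict)

    def fc(self, a: int, b: int) -> float:
        """Group mean FC between two nodes (0 where not significant)."""
        return float(self.mean_r[self.index[a], self.index[b]])


def group_fc_stats(
    node_ids,
    r_runs: list[np.ndarray],
    alpha: float = 0.05,
    r_criterion: float = 0.8,
) -> FCResult:
    """One-sample t on Fisher z across runs with BH-FDR over unique pairs.

    The FDR family is the upper triangle of the analyzed matrix; pairs
    undefined in any run (zero variance) are excluded from the family
    rather than imputed.  ``mean_r = tanh(mean z)`` zeroed where q ≥ α.
    """
    ids = [int(i) for i in node_ids]
    n = len(ids)
    if len(r_runs) < 2:
        raise InsufficientDataError("group statistics need at least 2 runs")
    z = np.stack([np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP)) for r in r_runs])
    mean_z = z.mean(axis=0)
    iu = np.triu_indices(n, k=1)
    zp = z[:, iu[0], iu[1]]  # runs × pairs
    valid = ~np.isnan(zp).any(axis=0)
    t_flat = np.full(zp.shape[1], np.nan)
    p_flat = np.full(zp.shape[1], np.nan)
    if valid.any():
        tt = stats.ttest_1samp(zp[:, valid], 0.0, axis=0)
        t_flat[valid] = tt.statistic
        p_flat[valid] = tt.pvalue
    q_flat = np.full(zp.shape[1], np.nan)
    sig_flat = np.zeros(zp.shape[1], dtype=bool)
    ok = valid & ~np.isnan(p_flat)
    if ok.any():
        rej, qv, _, _ = multipletests(p_flat[ok], alpha=alpha, method="fdr_bh")
        q_flat[ok] = qv
        sig_flat[ok] = rej

    def _square(flat, fill, diag):
        m = np.full((n, n), fill, dtype=flat.dtype if hasattr(flat, "dtype") else float)
        m[iu] = flat
        m[(iu[1], iu[0])] = flat
        np.fill_diagonal(m, diag)
        return m

    t_m = _square(t_flat, np.nan, np.nan)
    p_m = _square(p_flat, np.nan, np.nan)
    q_m = _square(q_flat, np.nan, np.nan)
    sig_m = _square(sig_flat, False, False)
    mean_r = np.tanh(mean_z)
    mean_r[~sig_m] = 0.0
    np.fill_diagonal(mean_r, 1.0)
    return FCResult(
        node_ids=ids, r_runs=list(r_runs), mean_z=mean_z, t=t_m, p=p_m, q=q_m,
        sig=sig_m, mean_r=mean_r, alpha=alpha, r_criterion=r_criterion,
        n_runs=len(r_runs), index={nid: k for k, nid in enumerate(ids)},
    )


# ---------------------------------------------------------------------------
# condition comparisons
# ---------------------------------------------------------------------------

def _rm_anova(data: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA on (subjects × conditions) data."""
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        return np.inf if ms_cond > 0 else 0.0, 0.0 if ms_cond > 0 else 1.0
    f = ms_cond / ms_err
    return float(f), float(stats.f.sf(f, df_cond, df_err))


def compare_fc(
    conditions: dict[str, np.ndarray], method: str = "paired_t_fdr", alpha: float = 0.05
) -> dict:
    """Compare FC values between conditions, feature by feature.

    ``conditions`` maps condition name → array of shape (n_runs,
    n_features) of correlation values (each feature is one node pair or
    layer pair); values are Fisher-transformed before testing.

    Methods: ``paired_t_fdr`` (two conditions, paired t per feature, BH
    across features); ``oneway_anova_tukey`` (independent groups, per
    feature F test plus Tukey HSD pairwise); ``rm_anova_holm`` (repeated
    measures ANOVA per feature, Holm-adjusted paired t post-hoc).
    """
    names = list(conditions)
    arrs = {k: np.arctanh(np.clip(np.atleast_2d(np.asarray(v, dtype=float)), -_Z_CLIP, _Z_CLIP))
            for k, v in conditions.items()}
    n_feat = arrs[names[0]].shape[1]
    paired = method in ("paired_t_fdr", "rm_anova_holm")
    if paired:
        n_runs = arrs[names[0]].shape[0]
        for k, a in arrs.items():
            if a.shape != (n_runs, n_feat):
                raise PairingError(
                    f"condition {k!r} has shape {a.shape}, expected {(n_runs, n_feat)} "
                    "(paired methods need matching runs)"
                )

    out: dict = {"method": method, "conditions": names, "n_features": n_feat}
    if method == "paired_t_fdr":
        if len(names) != 2:
            raise ValueError("paired_t_fdr compares exactly two conditions")
        a, b = arrs[names[0]], arrs[names[1]]
        tt = stats.ttest_rel(a, b, axis=0)
        p = np.atleast_1d(tt.pvalue).astype(float)
        p_fixed = np.where(np.isnan(p), 1.0, p)
        rej, q, _, _ = multipletests(p_fixed, alpha=alpha, method="fdr_bh")
        out.update(stat=np.atleast_1d(tt.statistic), p=p, p_adj=q, reject=rej & ~np.isnan(p))
    elif method == "oneway_anova_tukey":
        stats_f, p_f, pairwise = [], [], []
        for j in range(n_feat):
            groups = [arrs[k][:, j] for k in names]
            f, p = stats.f_oneway(*groups)
            stats_f.append(f)
            p_f.append(p)
            hsd = stats.tukey_hsd(*groups)
            pw = {}
            for ii in range(len(names)):
                for jj in range(ii + 1, len(names)):
                    pw[(names[ii], names[jj])] = float(hsd.pvalue[ii, jj])
            pairwise.append(pw)
        out.update(stat=np.array(stats_f), p=np.array(p_f), pairwise_p=pairwise)
    elif method == "rm_anova_holm":
        stats_f, p_f, pairwise = [], [], []
        for j in range(n_feat):
            data = np.column_stack([arrs[k][:, j] for k in names])
            f, p = _rm_anova(data)
            stats_f.append(f)
            p_f.append(p)
            labels, raw = [], []
            for ii in range(len(names)):
                for jj in range(ii + 1, len(names)):
                    tt = stats.ttest_rel(data[:, ii], data[:, jj])
                    labels.append((names[ii], names[jj]))
                    raw.append(tt.pvalue if not np.isnan(tt.pvalue) else 1.0)
            _, adj, _, _ = multipletests(raw, alpha=alpha, method="holm")
            pairwise.append(dict(zip(labels, adj.tolist())))
        out.update(stat=np.array(stats_f), p=np.array(p_f), pairwise_p=pairwise)
    else:
        raise ValueError(f"unknown comparison method {method!r}")
    return out


# ---------------------------------------------------------------------------
# hierarchy-aware analyses
# ---------------------------------------------------------------------------

def modulation_search(fc: FCResult, onto: AnnotationOntology) -> dict:
    """Screen for (source leaf S, inner node A) pairs suggesting that a
    larger anatomical unit modulates FC.

    All three criteria use the group mean FC matrix: (1) FC(S, A) exceeds
    ``fc.r_criterion`` for an inner node A; (2) A is not an ancestor of
    S; (3) FC(S, A) strictly exceeds FC(S, B) for *every* voxel-backed
    descendant leaf B of A present in the matrix.  Returns the surviving
    pairs and a funnel of per-criterion source-leaf counts.
    """
    in_fc = set(fc.node_ids)
    leaves = [i for i in fc.node_ids if onto.nodes[i].is_leaf]
    inners = [i for i in fc.node_ids if not onto.nodes[i].is_leaf]
    anc_cache = {s: set(onto.ancestors(s)) for s in leaves}
    desc_leaves = {
        a: sorted(onto.leaves_under(a) & in_fc) for a in inners
    }
    pass1, pass2, pass3 = set(), set(), set()
    pairs: list[tuple[int, int]] = []
    table: list[dict] = []
    for s in leaves:
        c1 = [a for a in inners if fc.fc(s, a) > fc.r_criterion]
        if c1:
            pass1.add(s)
        c2 = [a for a in c1 if a not in anc_cache[s]]
        if c2:
            pass2.add(s)
        for a in c2:
            fcs_a = fc.fc(s, a)
            descs = [b for b in desc_leaves[a] if b != s]
            if descs and all(fcs_a > fc.fc(s, b) for b in descs):
                pass3.add(s)
                pairs.append((s, a))
                table.append({
                    "source": s, "source_acronym": onto.nodes[s].acronym,
                    "inner": a, "inner_acronym": onto.nodes[a].acronym,
                    "fc_source_inner": fcs_a,
                    "fc_source_descendants": {b: fc.fc(s, b) for b in descs},
                })
    return {
        "pairs": sorted(pairs),
        "table": table,
        "funnel": {
            "leaves_tested": len(leaves),
            "pass_fc_criterion": len(pass1),
            "pass_non_ancestor": len(pass2),
            "pass_exceeds_descendants": len(pass3),
        },
    }


def layer_fc(fc: FCResult, layers: dict[str, list[int]], method: str = "oneway_anova_tukey"):
    """Layer-by-layer FC block and a comparison across layer pairs.

    ``layers`` maps a layer name (e.g. "L1", "L2/3") to its leaf ids.
    The per-run FC of a layer pair is the mean Fisher z over all
    cross-layer entries, inverse-transformed.  With ≥3 layer pairs the
    pairs are compared by ``compare_fc``; with fewer, only the block is
    returned.
    """
    import pandas as pd

    names = list(layers)
    for name, ids in layers.items():
        for i in ids:
            if i not in fc.index:
                raise OntologyLookupError(f"layer {name!r}: node {i} not in FC result")
    pair_names: list[str] = []
    per_run: dict[str, np.ndarray] = {}
    block = np.full((len(names), len(names)), np.nan)
    for ii, na in enumerate(names):
        for jj in range(ii + 1, len(names)):
            nb = names[jj]
            rows = [fc.index[i] for i in layers[na]]
            cols = [fc.index[i] for i in layers[nb]]
            zs = []
            for r in fc.r_runs:
                sub = np.arctanh(np.clip(r[np.ix_(rows, cols)], -_Z_CLIP, _Z_CLIP))
                zs.append(np.nanmean(sub))
            key = f"{na}|{nb}"
            pair_names.append(key)
            per_run[key] = np.tanh(np.asarray(zs))
            block[ii, jj] = block[jj, ii] = float(np.tanh(np.mean(zs)))
    np.fill_diagonal(block, 1.0)
    block_df = pd.DataFrame(block, index=names, columns=names)
    comparison = None
    if len(pair_names) >= 3 or (method == "paired_t_fdr" and len(pair_names) == 2):
        comparison = compare_fc({k: v[:, None] for k, v in per_run.items()}, method=method)
    return {"block": block_df, "per_run": per_run, "comparison": comparison}
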