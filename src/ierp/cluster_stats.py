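"""Cluster-based permutation inference on the mode lattice.

Two corrections for the mass-multiple-comparison problem are provided,
both operating on an arbitrary :class:`~ierp.adjacency.AdjacencyGraph`:

* the cluster-based nonparametric permutation (CBnPP) test — threshold
  the pointwise statistic map at a parametric critical value, connect
  suprathreshold nodes through the graph, score each cluster by the sum
  of its statistic values, and compare observed cluster masses against
  the permutation distribution of the *maximum* cluster mass;
* threshold-free cluster enhancement (TFCE) — replace the arbitrary
  cluster-forming threshold by integrating extent^E * height^H over all
  thresholds, with familywise control from the permutation maximum of
  the enhanced map.

Permutation schemes follow the design: condition labels are swapped
within subject for the paired t (equivalently the sign of the paired
difference is flipped), signs are flipped for the one-sample t, the
subject order of the behavioural covariate is permuted for the Pearson
correlation, and condition labels are shuffled within subject for the
repeated-measures ANOVA.  Cluster P values use the add-one convention
(1 + #{null >= observed}) / (1 + n_perm), which never reports zero.
Both signs of the statistic are clustered separately and the null takes
the maximum over signs, giving two-sided familywise control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
from scipy import stats as sps

from ._graph_kernels import edges_to_csr, label_components, tfce_enhance
from .adjacency import AdjacencyGraph
from .modes import ModeLabel

__all__ = [
    "StatMap",
    "TfceParams",
    "Cluster",
    "ClusterResult",
    "CompactModeMap",
    "pointwise_statistic",
    "form_clusters",
    "cbnpp_test",
    "tfce_transform",
    "tfce_test",
    "compact_mode_map",
    "stack_mode_tensors",
]

_DESIGNS = ("paired-t", "one-sample-t", "pearson-r", "rm-anova-F")


@dataclass
class StatMap:
    """Pointwise statistic over the lattice (t, r or F values)."""

    values: np.ndarray          # lattice-shaped
    kind: str                   # "t", "r" or "F"
    df: tuple[int, ...]         # (df,) for t; (n-2,) for r; (df1, df2) for F
    n_subjects: int
    zero_variance: np.ndarray | None = None  # mask of flagged nodes

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()

    @property
    def two_sided(self) -> bool:
        return self.kind in ("t", "r")


@dataclass(frozen=True)
class TfceParams:
    """TFCE exponents and integration step.

    E (extent) and H (height) default to the original TFCE values 0.5
    and 2; ``dh=None`` resolves to max|stat|/100 at transform time.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None

    def __post_init__(self):
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")


@dataclass
class Cluster:
    nodes: np.ndarray           # flat node indices
    mass: float                 # signed sum of statistic values
    sign: int                   # +1 or -1
    p: float = 1.0


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_max_mass: np.ndarray   # (n_perm,)
    n_perm: int
    seed: int | None
    alpha: float
    threshold: float
    stat: StatMap
    shape: tuple[int, ...]
    exhaustive: bool = False
    note: str = ""
    node_p: np.ndarray | None = None      # TFCE only: corrected P per node
    enhanced: np.ndarray | None = None    # TFCE only

    def significant(self, alpha: float | None = None) -> list[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p <= a]

    @property
    def min_p(self) -> float:
        if self.node_p is not None:
            return float(self.node_p.min())
        if not self.clusters:
            return 1.0
        return min(c.p for c in self.clusters)

    def significant_nodes(self, alpha: float | None = None) -> np.ndarray:
        if self.node_p is not None:
            a = self.alpha if alpha is None else alpha
            return np.nonzero(self.node_p.ravel() <= a)[0]
        out = [c.nodes for c in self.significant(alpha)]
        return (np.unique(np.concatenate(out)) if out
                else np.array([], dtype=np.intp))


# ---------------------------------------------------------------------------
# pointwise statistics (all vectorised over nodes)

def _t_from_diffs(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    t = np.zeros_like(m)
    np.divide(m, sd / math.sqrt(n), out=t, where=~zero)
    return t, zero


def _pearson_r(x: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    sx = x.std(axis=0, ddof=1)
    cc = cov - cov.mean()
    sc = cov.std(ddof=1)
    zero = (sx == 0) | (sc == 0)
    r = np.zeros(x.shape[1])
    denom = (n - 1) * sx * sc
    np.divide(cc @ xc, denom, out=r, where=~zero)
    return np.clip(r, -1.0, 1.0), zero


def _rm_anova_f(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-way repeated-measures F over x (n_subj, n_cond, n_nodes)."""
    n, k, _ = x.shape
    grand = x.mean(axis=(0, 1))
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum(axis=0)
    resid = x - cond_means[None, :, :] - subj_means[:, None, :] + grand
    ss_err = (resid ** 2).sum(axis=(0, 1))
    zero = ss_err == 0
    f = np.zeros_like(grand)
    np.divide(ss_cond / (k - 1), ss_err / ((k - 1) * (n - 1)), out=f,
              where=~zero)
    return f, zero


def _prepare(data, design: str, covariate=None):
    """Normalise `data` to arrays flattened over lattice nodes.

    Accepted shapes: (n_subj, n_cond, *lattice) for paired-t/rm-anova-F;
    (n_subj, *lattice) for one-sample-t and pearson-r; a (A, B) tuple of
    per-condition arrays for paired-t.
    """
    if design not in _DESIGNS:
        raise ValueError(f"design must be one of {_DESIGNS}")
    if design == "paired-t" and isinstance(data, (tuple, list)) and len(data) == 2:
        data = np.stack([np.asarray(data[0]), np.asarray(data[1])], axis=1)
    data = np.asarray(data, dtype=float)
    if design in ("paired-t", "rm-anova-F"):
        if data.ndim < 3:
            raise ValueError("need (n_subjects, n_conditions, ...) data")
        n, k = data.shape[:2]
        shape = data.shape[2:]
        if design == "paired-t" and k != 2:
            raise ValueError("paired-t requires exactly 2 conditions")
        if design == "rm-anova-F" and k < 2:
            raise ValueError("rm-anova-F requires >= 2 conditions")
        x = data.reshape(n, k, -1)
    else:
        if data.ndim < 2:
            raise ValueError("need (n_subjects, ...) data")
        n = data.shape[0]
        shape = data.shape[1:]
        x = data.reshape(n, -1)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    cov = None
    if design == "pearson-r":
        if covariate is None:
            raise ValueError("pearson-r requires a subject-level covariate")
        cov = np.asarray(covariate, dtype=float)
        if cov.shape != (n,):
            raise ValueError("covariate must be one value per subject")
    return x, cov, shape, n


def pointwise_statistic(data, design: str, covariate=None) -> StatMap:
    """Node-wise parametric statistic for the given design.

    Nodes with zero variance are set to 0 and flagged.
    """
    x, cov, shape, n = _prepare(data, design, covariate)
    if design == "paired-t":
        vals, zero = _t_from_diffs(x[:, 0, :] - x[:, 1, :])
        kind, df = "t", (n - 1,)
    elif design == "one-sample-t":
        vals, zero = _t_from_diffs(x)
        kind, df = "t", (n - 1,)
    elif design == "pearson-r":
        vals, zero = _pearson_r(x, cov)
        kind, df = "r", (n - 2,)
    else:
        vals, zero = _rm_anova_f(x)
        k = x.shape[1]
        kind, df = "F", (k - 1, (k - 1) * (n - 1))
    return StatMap(values=vals.reshape(shape), kind=kind, df=df,
                   n_subjects=n, zero_variance=zero.reshape(shape))


def _default_threshold(kind: str, df: tuple[int, ...], alpha: float) -> float:
    """Parametric cluster-forming critical value at two-sided `alpha`
    (one-sided for F)."""
    if kind == "t":
        return float(sps.t.ppf(1 - alpha / 2, df[0]))
    if kind == "r":
        tcrit = sps.t.ppf(1 - alpha / 2, df[0])
        return float(tcrit / math.sqrt(df[0] + tcrit ** 2))
    return float(sps.f.ppf(1 - alpha, df[0], df[1]))


# ---------------------------------------------------------------------------
# clustering

def _csr(graph: AdjacencyGraph):
    return edges_to_csr(graph.n_nodes, graph.edges)


def _signed_clusters(values: np.ndarray, indptr, indices,
                     threshold: float, two_sided: bool) -> list[Cluster]:
    clusters: list[Cluster] = []
    signs = (1, -1) if two_sided else (1,)
    for sign in signs:
        active = (sign * values) > threshold
        if not active.any():
            continue
        labels, n_labels = label_components(active, indptr, indices)
        for lab in range(n_labels):
            nodes = np.nonzero(labels == lab)[0]
            clusters.append(Cluster(nodes=nodes,
                                    mass=float(values[nodes].sum()),
                                    sign=sign))
    return clusters


def form_clusters(stat_map: StatMap, graph: AdjacencyGraph,
                  threshold: float) -> list[Cluster]:
    """Suprathreshold connected components and their signed masses.

    Positive and negative excursions are clustered separately (positive
    only for F maps); mass is the sum of statistic values in the
    cluster.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if stat_map.flat.size != graph.n_nodes:
        raise ValueError("stat map does not match the graph")
    indptr, indices = _csr(graph)
    return _signed_clusters(stat_map.flat, indptr, indices, threshold,
                            stat_map.two_sided)


def _max_cluster_mass(values, indptr, indices, threshold, two_sided) -> float:
    best = 0.0
    signs = (1, -1) if two_sided else (1,)
    for sign in signs:
        sv = sign * values
        active = sv > threshold
        if not active.any():
            continue
        labels, n_labels = label_components(active, indptr, indices)
        if n_labels:
            masses = np.bincount(labels[active], weights=sv[active],
                                 minlength=n_labels)
            best = max(best, float(masses.max()))
    return best


# ---------------------------------------------------------------------------
# permutation schemes

def _count_distinct(design: str, n: int, k: int = 2) -> float:
    if design in ("paired-t", "one-sample-t"):
        return 2.0 ** n
    if design == "pearson-r":
        return float(math.factorial(n))
    return float(math.factorial(k)) ** n


def _perm_stat_maps(x, cov, design, n_perm, rng):
    """Yield (n_perm, n_nodes) permutation statistic maps plus an
    exhaustive flag.  Sign-flip designs with 2^n <= n_perm and
    correlation designs with n! <= n_perm enumerate every distinct
    permutation instead of sampling."""
    exhaustive = False
    if design in ("paired-t", "one-sample-t"):
        d = x[:, 0, :] - x[:, 1, :] if design == "paired-t" else x
        n = d.shape[0]
        if 2.0 ** n <= n_perm:
            exhaustive = True
            bits = np.arange(2 ** n, dtype=np.int64)
            signs = 1 - 2.0 * ((bits[:, None] >> np.arange(n)) & 1)
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        msq = (d ** 2).mean(axis=0)
        m = signs @ d / n
        var = np.maximum(msq[None, :] - m ** 2, 0.0) * (n / (n - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, m / np.sqrt(var / n), 0.0)
        return t, exhaustive
    if design == "pearson-r":
        n = x.shape[0]
        if math.factorial(n) <= n_perm:
            exhaustive = True
            orders = np.array(list(iter_permutations(range(n))))
        else:
            orders = np.array([rng.permutation(n) for _ in range(n_perm)])
        sx = x.std(axis=0, ddof=1)
        zx = np.where(sx > 0, (x - x.mean(axis=0)) / sx, 0.0)
        sc = cov.std(ddof=1)
        zc = (cov - cov.mean()) / sc if sc > 0 else np.zeros_like(cov)
        r = (zc[orders] @ zx) / (n - 1)
        return np.clip(r, -1.0, 1.0), exhaustive
    # rm-anova-F: shuffle condition labels within each subject
    n, k, n_nodes = x.shape
    out = np.empty((n_perm, n_nodes))
    rows = np.arange(n)[:, None]
    for p in range(n_perm):
        idx = np.argsort(rng.random((n, k)), axis=1)
        out[p], _ = _rm_anova_f(x[rows, idx, :])
    return out, exhaustive


# ---------------------------------------------------------------------------
# the CBnPP test

def cbnpp_test(data, design: str, graph: AdjacencyGraph,
               n_perm: int = 5000, alpha: float = 0.05,
               seed: int | None = 0, covariate=None,
               threshold: float | None = None) -> ClusterResult:
    """Cluster-based nonparametric permutation test.

    The observed statistic map is thresholded at the parametric critical
    value (two-sided ``alpha`` by default), clustered through the graph,
    and each cluster's |mass| is referred to the permutation
    distribution of the maximum |cluster mass| (zero when a permutation
    yields no cluster).
    """
    x, cov, shape, n = _prepare(data, design, covariate)
    if graph.n_nodes != int(np.prod(shape)):
        raise ValueError("graph does not match the data lattice")
    observed = pointwise_statistic(data, design, covariate)
    thr = (threshold if threshold is not None
           else _default_threshold(observed.kind, observed.df, alpha))
    indptr, indices = _csr(graph)
    clusters = _signed_clusters(observed.flat, indptr, indices, thr,
                                observed.two_sided)

    rng = np.random.default_rng(seed)
    maps, exhaustive = _perm_stat_maps(x, cov, design, n_perm, rng)
    null = np.array([
        _max_cluster_mass(maps[p], indptr, indices, thr, observed.two_sided)
        for p in range(maps.shape[0])
    ])
    n_eff = null.size
    for c in clusters:
        c.p = float((1 + np.sum(null >= abs(c.mass))) / (1 + n_eff))
    clusters.sort(key=lambda c: c.p)
    note = ("exhaustive enumeration of all distinct permutations"
            if exhaustive else "")
    return ClusterResult(clusters=clusters, null_max_mass=null,
                         n_perm=n_eff, seed=seed, alpha=alpha,
                         threshold=thr, stat=observed, shape=shape,
                         exhaustive=exhaustive, note=note)


# ---------------------------------------------------------------------------
# TFCE

def _resolve_dh(values: np.ndarray, params: TfceParams) -> float:
    if params.dh is not None:
        return params.dh
    vmax = float(np.abs(values).max())
    return vmax / 100.0 if vmax > 0 else 1.0


def tfce_transform(stat_map: StatMap | np.ndarray, graph: AdjacencyGraph,
                   params: TfceParams = TfceParams()) -> np.ndarray:
    """Signed TFCE enhancement of a statistic map.

    Positive and negative parts are enhanced separately and recombined
    with their signs; the output has the lattice shape of the input.
    """
    values = stat_map.values if isinstance(stat_map, StatMap) else np.asarray(stat_map, float)
    flat = values.ravel().astype(float)
    indptr, indices = _csr(graph)
    dh = _resolve_dh(flat, params)
    pos = tfce_enhance(np.maximum(flat, 0.0), indptr, indices,
                       params.E, params.H, dh)
    neg = tfce_enhance(np.maximum(-flat, 0.0), indptr, indices,
                       params.E, params.H, dh)
    return (pos - neg).reshape(values.shape)


def tfce_test(data, design: str, graph: AdjacencyGraph,
              n_perm: int = 5000, alpha: float = 0.05,
              params: TfceParams = TfceParams(),
              seed: int | None = 0, covariate=None) -> ClusterResult:
    """TFCE permutation test: node-wise corrected P values against the
    permutation distribution of max |TFCE|.

    The integration step dh is fixed from the observed map and reused
    for every permutation so enhanced values are commensurable.
    """
    x, cov, shape, n = _prepare(data, design, covariate)
    if graph.n_nodes != int(np.prod(shape)):
        raise ValueError("graph does not match the data lattice")
    observed = pointwise_statistic(data, design, covariate)
    indptr, indices = _csr(graph)
    dh = _resolve_dh(observed.flat, params)
    fixed = TfceParams(E=params.E, H=params.H, dh=dh)

    def enhance(flat: np.ndarray) -> np.ndarray:
        pos = tfce_enhance(np.maximum(flat, 0.0), indptr, indices,
                           fixed.E, fixed.H, dh)
        if observed.two_sided:
            neg = tfce_enhance(np.maximum(-flat, 0.0), indptr, indices,
                               fixed.E, fixed.H, dh)
            return pos - neg
        return pos

    enhanced = enhance(observed.flat)
    rng = np.random.default_rng(seed)
    maps, exhaustive = _perm_stat_maps(x, cov, design, n_perm, rng)
    null = np.array([float(np.abs(enhance(maps[p])).max())
                     for p in range(maps.shape[0])])
    n_eff = null.size
    node_p = (1 + (null[None, :] >= np.abs(enhanced)[:, None]).sum(axis=1)) \
        / (1 + n_eff)

    # report suprathreshold-P regions as clusters for convenience
    sig = node_p <= alpha
    clusters: list[Cluster] = []
    if sig.any():
        labels, n_labels = label_components(sig, indptr, indices)
        for lab in range(n_labels):
            nodes = np.nonzero(labels == lab)[0]
            clusters.append(Cluster(
                nodes=nodes, mass=float(enhanced[nodes].sum()),
                sign=int(np.sign(enhanced[nodes].sum()) or 1),
                p=float(node_p[nodes].min())))
    note = ("exhaustive enumeration of all distinct permutations"
            if exhaustive else "")
    return ClusterResult(clusters=clusters, null_max_mass=null,
                         n_perm=n_eff, seed=seed, alpha=alpha,
                         threshold=0.0, stat=observed, shape=shape,
                         exhaustive=exhaustive, note=note,
                         node_p=node_p.reshape(shape),
                         enhanced=enhanced.reshape(shape))


# ---------------------------------------------------------------------------
# compact triangular mode maps

@dataclass
class CompactModeMap:
    """Electrode-cluster summary of a 3-D analysis.

    ``mean_stat[mode, time]`` is the statistic averaged over the
    electrode cluster's channels; ``opaque[mode, time]`` marks cells
    where (i) at least one member channel sat in a significant cluster
    and (ii) the parametric P of the cluster-mean statistic is below
    ``p_threshold``.  ``triangular(b)`` lays a time bin out as an
    initial-order x end-order matrix (NaN off the lattice).
    """

    mean_stat: np.ndarray
    opaque: np.ndarray
    mode_labels: list[ModeLabel]
    p_threshold: float

    def triangular(self, time_bin: int) -> np.ndarray:
        ps = sorted({lab.p for lab in self.mode_labels})
        qs = sorted({lab.q for lab in self.mode_labels})
        out = np.full((len(ps), len(qs)), np.nan)
        for i, lab in enumerate(self.mode_labels):
            out[ps.index(lab.p), qs.index(lab.q)] = self.mean_stat[i, time_bin]
        return out


def compact_mode_map(result: ClusterResult, stat_map: StatMap,
                     mode_labels: list[ModeLabel],
                     electrode_cluster: list[int],
                     p_threshold: float = 0.025) -> CompactModeMap:
    """Reorganise a 3-D [channel, mode, time] result per mode and time
    bin for one electrode cluster (no further statistical test is run;
    the parametric P of the cluster-mean statistic only gates opacity).
    """
    if len(result.shape) != 3:
        raise ValueError("compact maps require a 3-D [channel, mode, time] result")
    n_ch, n_modes, n_time = result.shape
    if n_modes != len(mode_labels):
        raise ValueError("mode label count mismatch")
    chans = np.asarray(sorted(electrode_cluster), dtype=np.intp)
    values = stat_map.values.reshape(result.shape)
    mean_stat = values[chans].mean(axis=0)          # (n_modes, n_time)

    sig_nodes = result.significant_nodes()
    sig_mask = np.zeros(result.shape, dtype=bool)
    if sig_nodes.size:
        sig_mask.ravel()[sig_nodes] = True
    member_sig = sig_mask[chans].any(axis=0)        # (n_modes, n_time)

    if stat_map.kind == "t":
        par_p = 2 * sps.t.sf(np.abs(mean_stat), stat_map.df[0])
    elif stat_map.kind == "r":
        t_equiv = mean_stat * np.sqrt(stat_map.df[0]) \
            / np.sqrt(np.maximum(1 - mean_stat ** 2, 1e-12))
        par_p = 2 * sps.t.sf(np.abs(t_equiv), stat_map.df[0])
    else:
        par_p = sps.f.sf(mean_stat, stat_map.df[0], stat_map.df[1])
    opaque = member_sig & (par_p < p_threshold)
    return CompactModeMap(mean_stat=mean_stat, opaque=opaque,
                          mode_labels=list(mode_labels),
                          p_threshold=p_threshold)


# ---------------------------------------------------------------------------
# helpers

def stack_mode_tensors(per_subject, conditions) -> np.ndarray:
    """Stack per-subject {condition: ModeTensor} dicts into the
    (n_subj, n_cond, n_modes, n_channels, n_times) array the tests
    consume."""
    arrs = []
    for subj in per_subject:
        arrs.append(np.stack([subj[c].values for c in conditions], axis=0))
    return np.stack(arrs, axis=0)
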