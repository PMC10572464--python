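"""Threshold-free cluster enhancement (TFCE) and network-based statistics.

The edgewise group-contrast map is enhanced without choosing a single
cluster-forming threshold: for every edge (i, j),

    TFCE(i, j) = integral from h0 to h(i,j) of e(h)^E * h^H dh

where h runs over statistic heights, e(h) is the extent of the connected
suprathreshold neighborhood containing the edge at height h, and E, H are
the extension and height exponents (defaults 0.5 and 2, the canonical TFCE
choices).  The integral is discretized with a midpoint rule over ``n_steps``
levels.

Two neighborhood definitions are supported:

* ``matrix_image_4`` (default): ROIs are first sorted by average-linkage
  hierarchical clustering of the group-mean |z| so that correlated ROIs are
  adjacent, and the sorted N x N statistic matrix is treated as a 2-D image
  with 4-connectivity.  This is how connectivity-matrix TFCE is done when the
  matrix itself is the enhancement domain, and is why the sorting step exists.
* ``edge_graph``: suprathreshold edges are neighbors iff they share an ROI
  (the NBS notion of connectedness); ROI sorting is irrelevant here.

Inference is by permutation of group labels: the maximum TFCE score (peak)
and maximum cluster mass of each permuted dataset build null distributions,
giving peak-level FWE-corrected p-values and cluster-level uncorrected
p-values with the add-one estimator p = (1 + #{null >= observed}) / (1 + n).

The network-based statistic (NBS) is included as the fixed-threshold
comparator: edges with |stat| above a hard threshold are grouped into
shared-ROI components whose size is tested against the permutation null of
maximum component size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .atlas import NetworkAtlas
from .connectivity import ConnectivityMatrix
from .design import StudyDesign
from .edge_stats import EdgeStatMap, pooled_t, stack_z

__all__ = [
    "TFCEParams",
    "TFCEResult",
    "Cluster",
    "sort_rois",
    "tfce_enhance",
    "permutation_inference",
    "nbs",
    "extract_report",
]

NEIGHBORHOODS = ("matrix_image_4", "edge_graph")


@dataclass
class TFCEParams:
    """TFCE configuration: exponents, integration grid, tails, neighborhood."""

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    h0: float = 0.0
    two_sided: bool = True
    neighborhood: str = "matrix_image_4"

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("TFCE exponents must be non-negative")
        if self.n_steps < 10:
            raise ValueError("n_steps must be at least 10")
        if self.h0 < 0:
            raise ValueError("h0 must be non-negative")
        if self.neighborhood not in NEIGHBORHOODS:
            raise ValueError(f"neighborhood must be one of {NEIGHBORHOODS}")


@dataclass
class Cluster:
    """A connected set of suprathreshold edges with its permutation p-values."""

    cluster_id: str
    edges: list[tuple[str, str]]
    mass: float
    p_uncorrected: float
    peak_tfce: float
    peak_p_fwe: float
    sign: str  # "positive" or "negative"
    networks_involved: set[str] = field(default_factory=set)
    edge_stats: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("a cluster must contain at least one edge")
        if self.mass <= 0:
            raise ValueError("cluster mass must be positive")

    @property
    def size(self) -> int:
        return len(self.edges)


@dataclass
class TFCEResult:
    """Observed TFCE map, ROI ordering, clusters, and permutation nulls."""

    tfce_map: np.ndarray
    roi_order: np.ndarray
    clusters: list[Cluster]
    null_peaks: np.ndarray
    null_masses: np.ndarray
    n_permutations: int
    seed: int
    roi_labels: tuple[str, ...]
    stat_map: EdgeStatMap | None = None
    params: TFCEParams | None = None
    tfce_threshold: float = 0.0
    contrast: str = ""


# ---------------------------------------------------------------------------
# hierarchical ROI sorting


def sort_rois(z_matrices: list[ConnectivityMatrix]) -> np.ndarray:
    """Dendrogram leaf order from average-linkage clustering of 1 - |mean z|.

    Deterministic given the input; a single pair tie-breaks to input order.
    """
    mean_z = stack_z(z_matrices).mean(axis=0)
    return leaf_order_from_similarity(np.abs(mean_z))


def leaf_order_from_similarity(similarity: np.ndarray) -> np.ndarray:
    n = similarity.shape[0]
    if n <= 2:
        return np.arange(n)
    dist = 1.0 - np.abs(similarity)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    link = linkage(squareform(dist, checks=False), method="average")
    return np.asarray(leaves_list(link))


# ---------------------------------------------------------------------------
# TFCE enhancement


try:  # optional compiled kernel; the numpy path below gives identical results
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@_njit(cache=True)
def _uf_find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        nxt = parent[x]
        parent[x] = root
        x = nxt
    return root


@_njit(cache=True)
def _tfce_image_kernel(mat, n_steps, E, H, h0):
    """Incremental union-find TFCE on a 2-D image with 4-connectivity.

    Processes height levels top-down, activating pixels as the threshold
    drops and merging them with active 4-neighbors; at each level every
    active pixel accumulates size(component)^E * h^H * dh.  Identical sums
    to labeling the thresholded image at every level, in O(levels * pixels).
    """
    n = mat.shape[0]
    flat = mat.ravel()
    out = np.zeros(n * n)
    hmax = flat.max()
    if hmax <= h0:
        return out.reshape(n, n)
    dh = (hmax - h0) / n_steps
    order = np.argsort(-flat)
    parent = np.full(n * n, -1, dtype=np.int64)
    size = np.zeros(n * n, dtype=np.int64)
    active = np.empty(n * n, dtype=np.int64)
    n_active = 0
    ptr = 0
    for k in range(n_steps - 1, -1, -1):
        h = h0 + (k + 0.5) * dh
        while ptr < n * n and flat[order[ptr]] > h:
            c = order[ptr]
            ptr += 1
            parent[c] = c
            size[c] = 1
            active[n_active] = c
            n_active += 1
            i = c // n
            j = c % n
            for step in range(4):
                if step == 0:
                    ok = i > 0
                    nb = c - n
                elif step == 1:
                    ok = i < n - 1
                    nb = c + n
                elif step == 2:
                    ok = j > 0
                    nb = c - 1
                else:
                    ok = j < n - 1
                    nb = c + 1
                if ok and parent[nb] >= 0:
                    ra = _uf_find(parent, c)
                    rb = _uf_find(parent, nb)
                    if ra != rb:
                        parent[rb] = ra
                        size[ra] += size[rb]
        if n_active == 0:
            continue
        weight = h**H * dh
        for a in range(n_active):
            c = active[a]
            out[c] += size[_uf_find(parent, c)] ** E * weight
    return out.reshape(n, n)


def _tfce_one_tail(mat: np.ndarray, params: TFCEParams) -> np.ndarray:
    """Enhance one non-negative symmetric matrix (already in sorted order)."""
    out = np.zeros_like(mat)
    hmax = float(mat.max())
    if hmax <= params.h0:
        return out
    dh = (hmax - params.h0) / params.n_steps
    heights = params.h0 + (np.arange(params.n_steps) + 0.5) * dh
    if params.neighborhood == "matrix_image_4":
        if _HAVE_NUMBA:
            return _tfce_image_kernel(
                np.ascontiguousarray(mat),
                params.n_steps,
                float(params.E),
                float(params.H),
                float(params.h0),
            )
        for h in heights:
            mask = mat > h
            if not mask.any():
                continue
            labels, _ = ndimage.label(mask)
            sizes = np.bincount(labels.ravel())
            out[mask] += sizes[labels[mask]] ** params.E * h**params.H * dh
    else:  # edge_graph
        n = mat.shape[0]
        iu = np.triu_indices(n, k=1)
        vals = mat[iu]
        for h in heights:
            sup = vals > h
            if not sup.any():
                continue
            extents = _edge_graph_extents(iu[0][sup], iu[1][sup], n)
            contrib = extents**params.E * h**params.H * dh
            incr = np.zeros_like(vals)
            incr[sup] = contrib
            out[iu] += incr
        out = out + out.T
    return out


def _edge_graph_extents(ia: np.ndarray, ja: np.ndarray, n: int) -> np.ndarray:
    """For suprathreshold edges (ia, ja), the size of each edge's shared-ROI
    connected component (number of suprathreshold edges in it)."""
    comp = _node_components(ia, ja, n)
    edge_comp = comp[ia]
    counts = np.bincount(edge_comp)
    return counts[edge_comp].astype(float)


def _node_components(ia: np.ndarray, ja: np.ndarray, n: int) -> np.ndarray:
    """Union-find connected components of the graph with edges (ia, ja)."""
    parent = np.arange(n)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for a, b in zip(ia.tolist(), ja.tolist()):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    return np.array([find(i) for i in range(n)])


def tfce_enhance(
    stat_map: EdgeStatMap | np.ndarray,
    roi_order: np.ndarray | None = None,
    params: TFCEParams | None = None,
) -> np.ndarray:
    """Signed TFCE map of a symmetric edge-statistic matrix.

    The positive tail is enhanced as-is; with ``two_sided`` the negated map's
    enhancement is subtracted, so negative-tail scores carry a negative sign.
    ``roi_order`` only matters for the ``matrix_image_4`` neighborhood, where
    component formation happens on the sorted matrix image.
    """
    params = params or TFCEParams()
    stat = stat_map.stat if isinstance(stat_map, EdgeStatMap) else np.asarray(stat_map, float)
    n = stat.shape[0]
    order = np.arange(n) if roi_order is None else np.asarray(roi_order)
    inv = np.empty_like(order)
    inv[order] = np.arange(n)

    sorted_stat = stat[np.ix_(order, order)]
    pos = _tfce_one_tail(np.maximum(sorted_stat, 0.0), params)
    result = pos
    if params.two_sided:
        neg = _tfce_one_tail(np.maximum(-sorted_stat, 0.0), params)
        result = pos - neg
    return result[np.ix_(inv, inv)]


# ---------------------------------------------------------------------------
# component extraction shared by TFCE clusters and NBS


def _components_from_mask(
    mask: np.ndarray, roi_order: np.ndarray, neighborhood: str
) -> list[np.ndarray]:
    """Connected components of a symmetric boolean edge mask.

    Returns one (k, 2) array of original ROI index pairs (i < j) per
    component.  ``matrix_image_4`` forms components on the ROI-sorted matrix
    image with 4-connectivity; ``edge_graph`` via shared ROIs.
    """
    n = mask.shape[0]
    comps: list[np.ndarray] = []
    if neighborhood == "matrix_image_4":
        img = mask[np.ix_(roi_order, roi_order)]
        labels, n_lab = ndimage.label(img)
        for lab in range(1, n_lab + 1):
            p, q = np.nonzero(labels == lab)
            a, b = roi_order[p], roi_order[q]
            pairs = np.unique(np.sort(np.stack([a, b], axis=1), axis=1), axis=0)
            pairs = pairs[pairs[:, 0] != pairs[:, 1]]
            if len(pairs):
                comps.append(pairs)
        # symmetric halves are one image: transposed duplicates collapse here
        comps = _merge_overlapping(comps)
    else:
        iu = np.triu_indices(n, k=1)
        sup = mask[iu]
        ia, ja = iu[0][sup], iu[1][sup]
        if ia.size:
            node_comp = _node_components(ia, ja, n)
            for c in np.unique(node_comp[ia]):
                sel = node_comp[ia] == c
                comps.append(np.stack([ia[sel], ja[sel]], axis=1))
    return comps


def _merge_overlapping(comps: list[np.ndarray]) -> list[np.ndarray]:
    """Merge components sharing any edge (the two mirror-image halves of a
    symmetric matrix can label one cluster twice)."""
    merged: list[set[tuple[int, int]]] = []
    for c in comps:
        edges = {(int(a), int(b)) for a, b in c}
        hits = [m for m in merged if m & edges]
        for m in hits:
            edges |= m
            merged.remove(m)
        merged.append(edges)
    return [np.array(sorted(m)) for m in merged]


def _max_component_mass(
    tfce_sym: np.ndarray,
    abs_src: np.ndarray,
    threshold: float,
    roi_order: np.ndarray,
    neighborhood: str,
) -> float:
    """Maximum cluster mass of a signed TFCE map at a fixed threshold.

    Mass counts each unordered edge once (sums restricted to the upper
    triangle in the sorted frame, so a mirror-image half carries the full
    mass and the other half zero; the maximum is unaffected).
    """
    best = 0.0
    if neighborhood == "matrix_image_4":
        perm = np.ix_(roi_order, roi_order)
        src_upper = np.triu(abs_src[perm], k=1)
        for sign_mat in (tfce_sym, -tfce_sym):
            mask = sign_mat[perm] > threshold
            labels, n_lab = ndimage.label(mask)
            if n_lab:
                masses = ndimage.sum_labels(src_upper, labels, np.arange(1, n_lab + 1))
                best = max(best, float(np.max(masses)))
    else:
        n = tfce_sym.shape[0]
        iu = np.triu_indices(n, k=1)
        for sign_mat in (tfce_sym, -tfce_sym):
            sup = sign_mat[iu] > threshold
            ia, ja = iu[0][sup], iu[1][sup]
            if ia.size:
                comp = _node_components(ia, ja, n)[ia]
                masses = np.bincount(comp, weights=abs_src[iu][sup])
                best = max(best, float(masses.max()))
    return best


# ---------------------------------------------------------------------------
# permutation engine


def _parse_contrast(contrast) -> tuple[str, str]:
    if isinstance(contrast, str):
        parts = contrast.replace(">", "-").split("-")
        if len(parts) != 2:
            raise ValueError(f"cannot parse contrast {contrast!r}; use 'A-B'")
        return parts[0].strip(), parts[1].strip()
    a, b = contrast
    return a, b


def _sym_from_ut(values: np.ndarray, n: int, iu) -> np.ndarray:
    m = np.zeros((n, n))
    m[iu] = values
    return m + m.T


class _ContrastData:
    """Upper-triangle subject-by-edge matrix for a two-group contrast."""

    def __init__(self, z_matrices, design: StudyDesign, contrast):
        self.group_a, self.group_b = _parse_contrast(contrast)
        by_id = {m.subject_id: m for m in z_matrices}
        subs_a = design.subjects_in(self.group_a)
        subs_b = design.subjects_in(self.group_b)
        for g, subs in ((self.group_a, subs_a), (self.group_b, subs_b)):
            if len(subs) < 2:
                raise ValueError(f"group {g!r} needs at least 2 subjects")
        missing = [s for s in subs_a + subs_b if s not in by_id]
        if missing:
            raise ValueError(f"no connectivity matrix for subjects {missing[:5]}")
        self.mats = [by_id[s] for s in subs_a + subs_b]
        self.labels = self.mats[0].roi_labels
        self.n = len(self.labels)
        self.iu = np.triu_indices(self.n, k=1)
        Z = stack_z(self.mats)
        self.X = Z[:, self.iu[0], self.iu[1]]  # (n_subjects, n_edges)
        self.n_a = len(subs_a)
        self.n_b = len(subs_b)

    def t_values(self, perm: np.ndarray | None = None) -> np.ndarray:
        X = self.X if perm is None else self.X[perm]
        return pooled_t(X[: self.n_a, None, :], X[self.n_a:, None, :])[0]

    def t_matrix(self, perm: np.ndarray | None = None) -> np.ndarray:
        return _sym_from_ut(self.t_values(perm), self.n, self.iu)


def _draw_permutations(
    rng: np.random.Generator, n_subjects: int, n_a: int, n_permutations: int
) -> list[np.ndarray]:
    """Label re-randomizations of the contrast's subjects, identity excluded."""
    from math import comb

    if comb(n_subjects, n_a) <= 1:
        raise ValueError("groups too small for any distinct label permutation")
    identity = np.zeros(n_subjects, bool)
    identity[:n_a] = True
    perms = []
    while len(perms) < n_permutations:
        p = rng.permutation(n_subjects)
        if np.array_equal(p < n_a, identity):
            continue
        perms.append(p)
    return perms


def permutation_inference(
    z_matrices: list[ConnectivityMatrix],
    design: StudyDesign,
    contrast,
    params: TFCEParams | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    atlas: NetworkAtlas | None = None,
    cluster_rule: str = "null95",
    mass_kind: str = "stat",
) -> TFCEResult:
    """TFCE group inference with a permutation maximum-statistic null.

    The observed two-sample t map is enhanced; each permutation shuffles
    group labels among the contrast's subjects, recomputes the t and TFCE
    maps, and records the maximum |TFCE| (peak) and maximum cluster mass.
    Observed clusters are connected components of edges whose |TFCE| exceeds
    the 95th percentile of the pooled null edgewise |TFCE| distribution
    (``cluster_rule="null95"``, the default) or all nonzero-TFCE edges
    (``cluster_rule="nonzero"``).  Mass is the sum of |t| over a cluster's
    edges (``mass_kind="stat"``) or of |TFCE| (``mass_kind="tfce"``).
    """
    params = params or TFCEParams()
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    if cluster_rule not in ("null95", "nonzero"):
        raise ValueError("cluster_rule must be 'null95' or 'nonzero'")
    data = _ContrastData(z_matrices, design, contrast)
    n, iu = data.n, data.iu

    # The leaf order uses the mean |z| over all contrast subjects, which is
    # invariant under label permutation, so it is computed once.
    roi_order = sort_rois(data.mats)

    obs_stat = data.t_matrix()
    obs_tfce = tfce_enhance(obs_stat, roi_order, params)

    rng = np.random.default_rng(seed)
    perms = _draw_permutations(rng, data.n_a + data.n_b, data.n_a, n_permutations)
    null_tfce_ut = np.empty((n_permutations, iu[0].size))
    null_stat_ut = np.empty_like(null_tfce_ut)
    null_peaks = np.empty(n_permutations)
    for k, perm in enumerate(perms):
        t_mat = data.t_matrix(perm)
        tf = tfce_enhance(t_mat, roi_order, params)
        null_stat_ut[k] = t_mat[iu]
        null_tfce_ut[k] = tf[iu]
        null_peaks[k] = np.abs(tf).max()

    if cluster_rule == "null95":
        threshold = float(np.percentile(np.abs(null_tfce_ut), 95.0))
    else:
        threshold = 0.0

    null_masses = np.zeros(n_permutations)
    for k in range(n_permutations):
        tf = _sym_from_ut(null_tfce_ut[k], n, iu)
        src = _sym_from_ut(null_stat_ut[k], n, iu) if mass_kind == "stat" else tf
        null_masses[k] = _max_component_mass(
            tf, np.abs(src), threshold, roi_order, params.neighborhood
        )

    clusters = _extract_clusters(
        obs_tfce,
        obs_stat,
        threshold,
        roi_order,
        params,
        null_peaks,
        null_masses,
        n_permutations,
        data.labels,
        atlas,
        mass_kind,
        two_sided=params.two_sided,
    )

    return TFCEResult(
        tfce_map=obs_tfce,
        roi_order=roi_order,
        clusters=clusters,
        null_peaks=null_peaks,
        null_masses=null_masses,
        n_permutations=n_permutations,
        seed=seed,
        roi_labels=data.labels,
        stat_map=EdgeStatMap(
            stat=obs_stat,
            stat_kind="t",
            df=(data.n_a + data.n_b - 2,),
            contrast=f"{data.group_a}>{data.group_b}",
            roi_labels=data.labels,
        ),
        params=params,
        tfce_threshold=threshold,
        contrast=f"{data.group_a}>{data.group_b}",
    )


def _pvalue(null: np.ndarray, observed: float) -> float:
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


def _extract_clusters(
    tfce_map,
    stat,
    threshold,
    roi_order,
    params,
    null_peaks,
    null_masses,
    n_permutations,
    labels,
    atlas,
    mass_kind,
    two_sided,
):
    clusters: list[Cluster] = []
    tails = (("positive", tfce_map), ("negative", -tfce_map)) if two_sided else (
        ("positive", tfce_map),
    )
    raw: list[tuple[str, np.ndarray]] = []
    for sign, m in tails:
        for comp in _components_from_mask(m > threshold, roi_order, params.neighborhood):
            raw.append((sign, comp))

    def cluster_mass(comp: np.ndarray) -> float:
        src = stat if mass_kind == "stat" else tfce_map
        return float(np.abs(src[comp[:, 0], comp[:, 1]]).sum())

    raw.sort(key=lambda item: -cluster_mass(item[1]))
    for k, (sign, comp) in enumerate(raw, start=1):
        edges = [(labels[i], labels[j]) for i, j in comp]
        stats = [float(stat[i, j]) for i, j in comp]
        mass = cluster_mass(comp)
        peak = float(np.abs(tfce_map[comp[:, 0], comp[:, 1]]).max())
        clusters.append(
            Cluster(
                cluster_id=f"COI{k}",
                edges=edges,
                mass=mass,
                p_uncorrected=_pvalue(null_masses, mass),
                peak_tfce=peak,
                peak_p_fwe=_pvalue(null_peaks, peak),
                sign=sign,
                networks_involved=atlas.networks_of_edges(edges) if atlas else set(),
                edge_stats=stats,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# NBS comparator


def nbs(
    stat_map: EdgeStatMap | None,
    z_matrices: list[ConnectivityMatrix],
    design: StudyDesign,
    contrast,
    edge_threshold: float = 3.0,
    n_permutations: int = 1000,
    seed: int = 0,
    atlas: NetworkAtlas | None = None,
) -> list[Cluster]:
    """Network-based statistic: hard-thresholded components with a
    permutation null of maximum component size.

    Per tail, edges with statistic above ``edge_threshold`` form shared-ROI
    connected components.  ``peak_p_fwe`` carries the component-size FWE p
    (the NBS statistic); ``p_uncorrected`` a mass-based permutation p;
    ``peak_tfce`` the component's max |t|.
    """
    if edge_threshold <= 0:
        raise ValueError("edge_threshold must be positive")
    data = _ContrastData(z_matrices, design, contrast)
    n, iu = data.n, data.iu
    obs = stat_map.stat if stat_map is not None else data.t_matrix()

    rng = np.random.default_rng(seed)
    perms = _draw_permutations(rng, data.n_a + data.n_b, data.n_a, n_permutations)
    null_sizes = np.zeros(n_permutations)
    null_masses = np.zeros(n_permutations)
    for k, perm in enumerate(perms):
        t_mat = data.t_matrix(perm)
        size, mass = _nbs_max_component(t_mat, edge_threshold, n)
        null_sizes[k] = size
        null_masses[k] = mass

    clusters: list[Cluster] = []
    raw: list[tuple[str, np.ndarray]] = []
    for sign, m in (("positive", obs), ("negative", -obs)):
        for comp in _components_from_mask(m > edge_threshold, np.arange(n), "edge_graph"):
            raw.append((sign, comp))
    raw.sort(key=lambda item: -len(item[1]))
    for k, (sign, comp) in enumerate(raw, start=1):
        edges = [(data.labels[i], data.labels[j]) for i, j in comp]
        stats = [float(obs[i, j]) for i, j in comp]
        mass = float(np.abs(obs[comp[:, 0], comp[:, 1]]).sum())
        clusters.append(
            Cluster(
                cluster_id=f"NBS{k}",
                edges=edges,
                mass=mass,
                p_uncorrected=_pvalue(null_masses, mass),
                peak_tfce=float(np.abs(obs[comp[:, 0], comp[:, 1]]).max()),
                peak_p_fwe=_pvalue(null_sizes, float(len(comp))),
                sign=sign,
                networks_involved=atlas.networks_of_edges(edges) if atlas else set(),
                edge_stats=stats,
            )
        )
    return clusters


def _nbs_max_component(t_mat: np.ndarray, threshold: float, n: int) -> tuple[float, float]:
    best_size, best_mass = 0.0, 0.0
    for m in (t_mat, -t_mat):
        for comp in _components_from_mask(m > threshold, np.arange(n), "edge_graph"):
            best_size = max(best_size, float(len(comp)))
            best_mass = max(best_mass, float(np.abs(t_mat[comp[:, 0], comp[:, 1]]).sum()))
    return best_size, best_mass


# ---------------------------------------------------------------------------
# report extraction


def extract_report(
    result: TFCEResult | list[Cluster], atlas: NetworkAtlas | None = None
) -> pd.DataFrame:
    """Flat edge-list report: one row per cluster edge, ordered within each
    cluster by |stat| descending, carrying the cluster's mass and p-values."""
    clusters = result.clusters if isinstance(result, TFCEResult) else result
    rows = []
    for cl in clusters:
        order = np.argsort([-abs(s) for s in cl.edge_stats])
        for rank in order:
            a, b = cl.edges[rank]
            rows.append(
                {
                    "cluster_id": cl.cluster_id,
                    "sign": cl.sign,
                    "mass": cl.mass,
                    "p_uncorrected": cl.p_uncorrected,
                    "peak_p_fwe": cl.peak_p_fwe,
                    "roi_a": a,
                    "roi_b": b,
                    "stat": cl.edge_stats[rank],
                }
            )
            if atlas is not None:
                for roi in (a, b):
                    if roi not in atlas.roi_labels:
                        raise ValueError(f"report ROI {roi!r} not in atlas")
    columns = [
        "cluster_id",
        "sign",
        "mass",
        "p_uncorrected",
        "peak_p_fwe",
        "roi_a",
        "roi_b",
        "stat",
    ]
    return pd.DataFrame(rows, columns=columns)
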