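"""Quantitative sulcal pattern analysis.

Sulcal basins are catchment regions of the smoothed curvature map found by
an ascending watershed restricted to concave (negative-curvature) surface;
each basin carries scale-free geometric features (3D position in a
size-normalised frame, depth normalised by the surface's maximum depth,
area normalised by total surface area).  A subject's basins are put in
one-to-one correspondence with a template's by spectral matching on the
basin adjacency graph, and similarity indices (SI in [0, 1]) summarise how
closely the subject's sulcal arrangement matches the template's — per
feature, for corresponding basins, for inter-sulcal relationships
(within-brain feature differences), and for the whole pattern with a
penalty for unmatched (extra or missing) folds.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import scipy.linalg as sla
from scipy.optimize import linear_sum_assignment

from .geometry import mean_curvature, smooth_vertex_field, vertex_areas
from .mesh import TriMesh, VertexField

__all__ = [
    "SulcalBasin",
    "BasinGraph",
    "Matching",
    "SimilarityRecord",
    "FeatureWeights",
    "watershed_basins",
    "basin_features",
    "build_basin_graph",
    "spectral_match",
    "similarity_index",
    "save_basin_graph",
    "load_basin_graph",
]

# exponential-kernel similarity scales per feature (normalised units)
TAU_POSITION = 0.2
TAU_DEPTH = 0.2
TAU_AREA = 0.05
COST_CUTOFF = 1.0  # assignment cost above which a pair is left unmatched
FEATURES = ("position", "depth", "area")


@dataclasses.dataclass
class FeatureWeights:
    """Relative weight of position / depth / area; normalised to sum 1."""

    position: float = 1 / 3
    depth: float = 1 / 3
    area: float = 1 / 3

    def __post_init__(self) -> None:
        s = self.position + self.depth + self.area
        if s <= 0:
            raise ValueError("weights must have positive sum")
        self.position /= s
        self.depth /= s
        self.area /= s

    def as_array(self) -> np.ndarray:
        return np.array([self.position, self.depth, self.area])


@dataclasses.dataclass
class SulcalBasin:
    id: int
    vertices: np.ndarray  # vertex indices
    area: float = 0.0  # mm^2 (sum of member vertex areas)
    centroid: np.ndarray | None = None  # normalised frame
    mean_depth: float = 0.0  # / max surface depth
    norm_area: float = 0.0  # / total surface area


@dataclasses.dataclass
class BasinGraph:
    basins: list[SulcalBasin]
    edges: set[tuple[int, int]]  # basin-id pairs sharing a watershed ridge

    @property
    def n(self) -> int:
        return len(self.basins)

    def basin_ids(self) -> list[int]:
        return [b.id for b in self.basins]

    def feature_matrix(self) -> np.ndarray:
        """(n, 5): centroid xyz, normalised depth, normalised area."""
        return np.array(
            [[*b.centroid, b.mean_depth, b.norm_area] for b in self.basins]
        )


@dataclasses.dataclass
class Matching:
    pairs: list[tuple[int, int]]  # (subject basin id, template basin id)
    unmatched_subject: list[int]
    unmatched_template: list[int]

    def __post_init__(self) -> None:
        s_ids = [p[0] for p in self.pairs]
        t_ids = [p[1] for p in self.pairs]
        if len(set(s_ids)) != len(s_ids) or len(set(t_ids)) != len(t_ids):
            raise ValueError("matching is not one-to-one")


@dataclasses.dataclass
class SimilarityRecord:
    """SI per feature x scope, plus the weights used."""

    corresponding: dict[str, float]
    inter_sulcal: dict[str, float]
    whole_pattern: dict[str, float]
    weights: FeatureWeights

    def as_dict(self) -> dict:
        return {
            "corresponding_regions": self.corresponding,
            "inter_sulcal": self.inter_sulcal,
            "whole_pattern": self.whole_pattern,
            "weights": dataclasses.asdict(self.weights),
        }


# ---------------------------------------------------------------------------
# watershed
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}
        self.minval: dict[int, float] = {}

    def make(self, i: int, val: float) -> None:
        self.parent[i] = i
        self.minval[i] = val

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        # deeper basin (smaller minimum) absorbs the shallower
        if self.minval[rb] < self.minval[ra]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        return ra


def watershed_basins(
    mesh: TriMesh,
    curvature: VertexField,
    smooth_iters: int = 10,
    merge_ridge: float = 0.0,
) -> tuple[BasinGraph, np.ndarray]:
    """Watershed of the smoothed curvature map over the sulcal set {H < 0}.

    Vertices are flooded in ascending curvature order; a vertex touching a
    single existing basin joins it, a new local minimum opens a basin, and
    where several basins meet the ridge is recorded.  Adjacent basins whose
    separating ridge height (ridge curvature minus the shallower basin's
    minimum) is below ``merge_ridge`` are merged, so ``merge_ridge = 0``
    keeps every catchment and ``merge_ridge = inf`` reduces the partition
    to the connected components of the sulcal set.

    Returns (graph, labels) with per-vertex basin label (-1 outside).
    """
    sm = smooth_vertex_field(curvature, smooth_iters)
    vals = sm.values
    sulcal = np.nonzero(vals < 0)[0]
    labels = -np.ones(mesh.n_vertices, dtype=np.int64)
    if len(sulcal) == 0:
        warnings.warn("no negative-curvature vertices; empty basin graph")
        return BasinGraph([], set()), labels

    # vertex neighbour lists (within whole mesh)
    e = mesh.edges()
    nbr: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
    for a, b in e:
        nbr[a].append(b)
        nbr[b].append(a)

    order = sulcal[np.argsort(vals[sulcal], kind="stable")]
    uf = _UnionFind()
    ridge_pairs: list[tuple[int, int]] = []
    next_id = 0
    for v in order:
        roots = {uf.find(labels[u]) for u in nbr[v] if labels[u] >= 0}
        if not roots:
            uf.make(next_id, vals[v])
            labels[v] = next_id
            next_id += 1
            continue
        roots = sorted(roots, key=lambda r: uf.minval[r])
        deepest = roots[0]
        for r in roots[1:]:
            if vals[v] - uf.minval[r] < merge_ridge:
                deepest = uf.union(deepest, r)
            else:
                ridge_pairs.append((deepest, r))
        labels[v] = deepest

    # resolve final roots and compact ids
    final_root = {i: uf.find(i) for i in range(next_id)}
    roots = sorted(set(final_root.values()))
    compact = {r: k for k, r in enumerate(roots)}
    for v in sulcal:
        labels[v] = compact[final_root[labels[v]]]
    edges = set()
    for a, b in ridge_pairs:
        ca, cb = compact[final_root[a]], compact[final_root[b]]
        if ca != cb:
            edges.add((min(ca, cb), max(ca, cb)))
    basins = [
        SulcalBasin(id=k, vertices=np.nonzero(labels == k)[0])
        for k in range(len(roots))
    ]
    return BasinGraph(basins, edges), labels


def basin_features(
    graph: BasinGraph,
    mesh: TriMesh,
    depth: VertexField,
    areas: VertexField | None = None,
) -> BasinGraph:
    """Fill scale-free geometric features in place (and return the graph).

    Positions are area-weighted centroids in the normalised frame (surface
    centroid at the origin, unit RMS vertex radius), depths are divided by
    the surface's maximum depth, areas by the total surface area.
    """
    if areas is None:
        areas = vertex_areas(mesh)
    a = areas.values
    total_area = a.sum()
    w = a / total_area
    center = (mesh.vertices * w[:, None]).sum(axis=0)
    centered = mesh.vertices - center
    rms = np.sqrt(np.mean(np.sum(centered**2, axis=1)))
    frame = centered / rms
    dmax = depth.values.max()
    dnorm = depth.values / dmax if dmax > 0 else np.zeros_like(depth.values)
    for b in graph.basins:
        av = a[b.vertices]
        if av.sum() <= 0:
            raise ValueError(f"basin {b.id} has zero area")
        b.area = float(av.sum())
        b.centroid = (frame[b.vertices] * av[:, None]).sum(axis=0) / av.sum()
        b.mean_depth = float(np.average(dnorm[b.vertices], weights=av))
        b.norm_area = float(av.sum() / total_area)
    return graph


def build_basin_graph(
    mesh: TriMesh,
    spacing: float = 1.5,
    kernel_diameter: float = 15.0,
    smooth_iters: int = 10,
    merge_ridge: float = 0.0,
) -> BasinGraph:
    """Curvature -> watershed -> features, the full per-subject pattern stage."""
    from .morphometry import hull_surface, sulcal_depth

    curv = mean_curvature(mesh)
    graph, _ = watershed_basins(mesh, curv, smooth_iters, merge_ridge)
    if graph.n == 0:
        return graph
    hull = hull_surface(mesh, spacing, kernel_diameter)
    depth = sulcal_depth(mesh, hull, spacing, kernel_diameter)
    return basin_features(graph, mesh, depth)


# ---------------------------------------------------------------------------
# spectral matching
# ---------------------------------------------------------------------------


def _spectral_embedding(graph: BasinGraph, weights: FeatureWeights, k: int) -> np.ndarray:
    """Rows of the k smallest non-trivial eigenvectors of the normalised
    Laplacian with feature-similarity edge weights."""
    n = graph.n
    F = graph.feature_matrix()
    wf = np.concatenate(
        [np.full(3, weights.position), [weights.depth], [weights.area]]
    )
    W = np.zeros((n, n))
    sigma = 0.5
    for i, j in graph.edges:
        d2 = np.sum((wf * (F[i] - F[j])) ** 2)
        W[i, j] = W[j, i] = np.exp(-d2 / sigma**2)
    if not graph.edges:  # disconnected point cloud: fall back to complete graph
        for i in range(n):
            for j in range(i + 1, n):
                d2 = np.sum((wf * (F[i] - F[j])) ** 2)
                W[i, j] = W[j, i] = np.exp(-d2 / sigma**2)
    deg = W.sum(axis=1)
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    L = np.eye(n) - dinv[:, None] * W * dinv[None, :]
    evals, evecs = sla.eigh(L)
    return evecs[:, 1 : 1 + k]


def _align_embeddings(
    es: np.ndarray, et: np.ndarray, fs: np.ndarray, ft: np.ndarray
) -> np.ndarray:
    """Resolve the eigenvector sign/order/rotation ambiguity of the subject
    embedding against the template's.

    A raw-feature Hungarian pre-match supplies tentative correspondences,
    then an orthogonal Procrustes rotation aligns the subject embedding to
    the template's over those rows.  (A rotation, not just per-axis sign
    and order, is required: repeated Laplacian eigenvalues leave the basis
    free inside each degenerate eigenspace.)
    """
    pre_cost = np.linalg.norm(fs[:, None, :] - ft[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(pre_cost)
    R, _ = sla.orthogonal_procrustes(es[ri], et[ci])
    return es @ R


def spectral_match(
    subject: BasinGraph,
    template: BasinGraph,
    weights: FeatureWeights | None = None,
    cost_cutoff: float = COST_CUTOFF,
) -> Matching:
    """One-to-one basin correspondence by spectral graph matching.

    Basins are embedded in the smallest non-trivial eigenvectors of each
    graph's feature-weighted normalised Laplacian (k = min(5, n-1)); the
    assignment cost is the Euclidean distance in the concatenation of the
    aligned spectral embedding and the raw features, solved by the
    Hungarian algorithm; pairs costlier than ``cost_cutoff`` stay
    unmatched.
    """
    weights = weights or FeatureWeights()
    if subject.n == 0 or template.n == 0:
        raise ValueError("cannot match an empty basin graph")
    fs, ft = subject.feature_matrix(), template.feature_matrix()
    sub_ids, tem_ids = subject.basin_ids(), template.basin_ids()
    k = min(5, subject.n - 1, template.n - 1)
    if k < 1:
        warnings.warn("fewer than 2 basins on one side; feature-only matching")
        cost = np.linalg.norm(fs[:, None, :] - ft[None, :, :], axis=2)
    else:
        es = _spectral_embedding(subject, weights, k)
        et = _spectral_embedding(template, weights, k)
        es = _align_embeddings(es, et, fs, ft)
        zs = np.hstack([es, fs])
        zt = np.hstack([et, ft])
        cost = np.linalg.norm(zs[:, None, :] - zt[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(cost)
    pairs, ms, mt = [], set(), set()
    for i, j in zip(ri, ci):
        if cost[i, j] <= cost_cutoff:
            pairs.append((sub_ids[i], tem_ids[j]))
            ms.add(sub_ids[i])
            mt.add(tem_ids[j])
    return Matching(
        pairs,
        [i for i in sub_ids if i not in ms],
        [j for j in tem_ids if j not in mt],
    )


# ---------------------------------------------------------------------------
# similarity indices
# ---------------------------------------------------------------------------


def _per_feature(F: np.ndarray, idx: np.ndarray) -> dict[str, np.ndarray]:
    return {"position": F[idx, :3], "depth": F[idx, 3], "area": F[idx, 4]}


def _pair_sim(a, b, tau: float) -> float:
    d = np.linalg.norm(a - b) if np.ndim(a) else abs(a - b)
    return float(np.exp(-d / tau))


def similarity_index(
    matching: Matching,
    subject: BasinGraph,
    template: BasinGraph,
    weights: FeatureWeights | None = None,
    taus: dict[str, float] | None = None,
) -> SimilarityRecord:
    """SI per feature and scope from a basin matching.

    Per matched pair the feature similarity is exp(-d/tau); the
    corresponding-regions SI averages it over pairs; the inter-sulcal SI
    averages exp(-||(f_i - f_k) - (f_j - f_l)|| / tau) over pairs of
    matched pairs (within-brain feature differences, invariant to a rigid
    translation of all subject centroids); the whole-pattern SI is the mean
    of the two, discounted by the matched fraction
    2|matched| / (n_subject + n_template) so extra or missing folds lower
    it.  ``combined`` is the weighted sum over features.
    """
    weights = weights or FeatureWeights()
    taus = taus or {"position": TAU_POSITION, "depth": TAU_DEPTH, "area": TAU_AREA}
    empty = {f: 0.0 for f in (*FEATURES, "combined")}
    if not matching.pairs:
        return SimilarityRecord(dict(empty), dict(empty), dict(empty), weights)

    sid = {b: k for k, b in enumerate(subject.basin_ids())}
    tid = {b: k for k, b in enumerate(template.basin_ids())}
    si = np.array([sid[p[0]] for p in matching.pairs])
    ti = np.array([tid[p[1]] for p in matching.pairs])
    Fs = _per_feature(subject.feature_matrix(), si)
    Ft = _per_feature(template.feature_matrix(), ti)
    p = len(matching.pairs)
    n_total = subject.n + template.n
    discount = 2.0 * p / n_total

    corr: dict[str, float] = {}
    inter: dict[str, float] = {}
    whole: dict[str, float] = {}
    for f in FEATURES:
        tau = taus[f]
        corr[f] = float(
            np.mean([_pair_sim(Fs[f][a], Ft[f][a], tau) for a in range(p)])
        )
        if p >= 2:
            sims = []
            for a in range(p):
                for b in range(p):
                    if a == b:
                        continue
                    ds = Fs[f][a] - Fs[f][b]
                    dt = Ft[f][a] - Ft[f][b]
                    sims.append(_pair_sim(ds, dt, tau))
            inter[f] = float(np.mean(sims))
        else:
            inter[f] = 1.0  # vacuous: no within-brain relations to compare
        whole[f] = 0.5 * (corr[f] + inter[f]) * discount
    wf = weights.as_array()
    for d in (corr, inter, whole):
        d["combined"] = float(np.dot(wf, [d[f] for f in FEATURES]))
    return SimilarityRecord(corr, inter, whole, weights)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_basin_graph(graph: BasinGraph, path: str | Path) -> None:
    payload = {
        "basins": [
            {
                "id": b.id,
                "vertices": np.asarray(b.vertices).tolist(),
                "area": b.area,
                "centroid": None if b.centroid is None else list(b.centroid),
                "mean_depth": b.mean_depth,
                "norm_area": b.norm_area,
            }
            for b in graph.basins
        ],
        "edges": sorted(list(e) for e in graph.edges),
    }
    Path(path).write_text(json.dumps(payload))


def load_basin_graph(path: str | Path) -> BasinGraph:
    payload = json.loads(Path(path).read_text())
    basins = [
        SulcalBasin(
            id=b["id"],
            vertices=np.asarray(b["vertices"], dtype=np.int64),
            area=b["area"],
            centroid=None if b["centroid"] is None else np.asarray(b["centroid"]),
            mean_depth=b["mean_depth"],
            norm_area=b["norm_area"],
        )
        for b in payload["basins"]
    ]
    edges = {tuple(e) for e in payload["edges"]}
    return BasinGraph(basins, edges)
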