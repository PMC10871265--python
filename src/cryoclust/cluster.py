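"""Clustering embeddings and similarity graphs.

Spatial route: a distance measure is chosen from 22 candidates by the
best silhouette score of the ground-truth classes on the training split;
then DBSCAN / OPTICS / BIRCH / Affinity Propagation hyperparameters are
tuned by exhaustive grid search, scored by the maximal-matching F-score
(FMMF) restricted to the training images.  Graph route: eight classical
community-detection methods applied directly to the similarity graph.

Binary dissimilarity measures (Dice, Jaccard, ...) are evaluated on the
nonzero-indicator pattern of the vectors.  Measures undefined on the data
at hand (singular covariance for Mahalanobis, negative entries for
Jensen-Shannon, ...) are skipped with a log entry.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN, OPTICS, AffinityPropagation, Birch
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score

from . import metrics as _metrics
from .commonline import SimilarityGraph, shift_positive, symmetrize
from .metrics import NOISE, fmmf, labels_to_partition

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURES",
    "BINARY_MEASURES",
    "GRAPH_METHODS",
    "MeasureUndefinedError",
    "SearchSpace",
    "ClusterAssignment",
    "distance_matrix",
    "select_distance",
    "tune_and_fit",
    "graph_cluster",
    "GridTunedClusterer",
]

#: the 22 candidate measures, in the order used for tie-breaking
MEASURES = (
    "braycurtis", "canberra", "chebyshev", "cityblock", "correlation",
    "cosine", "dice", "euclidean", "hamming", "jaccard", "jensenshannon",
    "kulsinski", "mahalanobis", "matching", "minkowski", "rogerstanimoto",
    "russellrao", "seuclidean", "sokalmichener", "sokalsneath",
    "sqeuclidean", "yule",
)

#: measures defined on boolean vectors; applied to the nonzero pattern
BINARY_MEASURES = frozenset(
    {"dice", "jaccard", "kulsinski", "matching", "rogerstanimoto",
     "russellrao", "sokalmichener", "sokalsneath", "yule", "hamming"}
)

GRAPH_METHODS = (
    "scc", "wcc", "walktrap", "edge_betweenness", "greedy_modularity",
    "k_clique", "label_prop_semisync", "label_prop_async",
)


class MeasureUndefinedError(ValueError):
    """The distance measure is not defined on this data."""


def _binary_counts(U: np.ndarray, V: np.ndarray):
    U = U.astype(float)
    V = V.astype(float)
    ctt = U @ V.T
    ctf = U @ (1 - V).T
    cft = (1 - U) @ V.T
    cff = (1 - U) @ (1 - V).T
    return ctt, ctf, cft, cff


def _kulsinski(U, V):
    # classic scipy definition: (c_TF + c_FT - c_TT + n) / (c_FT + c_TF + n)
    ctt, ctf, cft, _ = _binary_counts(U, V)
    n = U.shape[1]
    return (ctf + cft - ctt + n) / (cft + ctf + n)


def _sokalmichener(U, V):
    # classic scipy definition: 2R / (S + 2R), R = c_TF + c_FT, S = c_FF + c_TT
    ctt, ctf, cft, cff = _binary_counts(U, V)
    R = ctf + cft
    return np.divide(2 * R, ctt + cff + 2 * R,
                     out=np.zeros_like(R), where=(ctt + cff + 2 * R) > 0)


def distance_matrix(X: np.ndarray, measure: str) -> np.ndarray:
    """Pairwise distances under one of the 22 measures.

    Raises :class:`MeasureUndefinedError` when the measure cannot be
    evaluated on this data.
    """
    X = np.asarray(X, dtype=float)
    if measure not in MEASURES and measure != "precomputed":
        raise ValueError(f"unknown measure {measure!r}")
    if measure in BINARY_MEASURES:
        B = (X != 0)
        if measure == "kulsinski":
            D = _kulsinski(B, B)
        elif measure == "sokalmichener":
            D = _sokalmichener(B, B)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                D = cdist(B, B, measure)
        if not np.all(np.isfinite(D)):
            raise MeasureUndefinedError(
                f"{measure} undefined on this sign pattern"
            )
        np.fill_diagonal(D, 0.0)
        return D
    if measure == "jensenshannon" and X.min() < 0:
        raise MeasureUndefinedError("jensenshannon requires nonnegative data")
    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            if measure == "mahalanobis":
                cov = np.cov(X, rowvar=False)
                VI = np.linalg.inv(np.atleast_2d(cov))
                D = cdist(X, X, "mahalanobis", VI=VI)
            else:
                D = cdist(X, X, measure)
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError) as exc:
        raise MeasureUndefinedError(f"{measure}: {exc}") from exc
    if not np.all(np.isfinite(D)):
        raise MeasureUndefinedError(f"{measure} produced non-finite distances")
    np.fill_diagonal(D, 0.0)
    return D


def select_distance(
    emb: np.ndarray,
    train_idx: np.ndarray,
    train_labels: np.ndarray,
    candidates: tuple[str, ...] = MEASURES,
) -> str:
    """Choose the measure whose ground-truth-class silhouette on the
    training split is highest; ties go to the first candidate in order."""
    emb = np.asarray(emb, dtype=float)
    Xt = emb[np.asarray(train_idx)]
    yt = np.asarray(train_labels)
    if len(np.unique(yt)) < 2:
        raise ValueError("need >= 2 training classes to select a distance")
    if np.all(Xt.max(axis=0) == Xt.min(axis=0)):
        raise ValueError(
            "constant embedding: silhouette is undefined for every measure"
        )
    best_name, best_sil = None, -np.inf
    for name in candidates:
        try:
            D = distance_matrix(Xt, name)
            sil = silhouette_score(D, yt, metric="precomputed")
        except (MeasureUndefinedError, ValueError) as exc:
            logger.info("distance %s skipped: %s", name, exc)
            continue
        if np.isfinite(sil) and sil > best_sil:
            best_name, best_sil = name, sil
    if best_name is None:
        raise ValueError("no candidate distance measure is defined "
                         "on this embedding")
    return best_name


def _grid(start, stop, step):
    vals = np.arange(start, stop + step / 2, step)
    return [round(float(v), 10) for v in vals]


@dataclass
class SearchSpace:
    """Hyperparameter grids for the four spatial clustering algorithms."""

    dbscan_eps: list = field(default_factory=lambda: _grid(0.25, 3.0, 0.25))
    dbscan_min_samples: list = field(default_factory=lambda: list(range(2, 11)))
    optics_max_eps: list = field(default_factory=lambda: _grid(0.25, 3.0, 0.25))
    optics_min_samples: list = field(default_factory=lambda: list(range(2, 11)))
    birch_threshold: list = field(default_factory=lambda: _grid(0.1, 1.0, 0.1))
    birch_branching_factor: list = field(
        default_factory=lambda: list(range(10, 101, 10))
    )
    affinity_damping: list = field(default_factory=lambda: _grid(0.5, 1.0, 0.1))

    def grid_points(self, algo: str) -> list[dict]:
        if algo == "dbscan":
            keys = ("eps", "min_samples")
            axes = (self.dbscan_eps, self.dbscan_min_samples)
        elif algo == "optics":
            keys = ("max_eps", "min_samples")
            axes = (self.optics_max_eps, self.optics_min_samples)
        elif algo == "birch":
            keys = ("threshold", "branching_factor")
            axes = (self.birch_threshold, self.birch_branching_factor)
        elif algo == "affinity":
            keys = ("damping",)
            axes = (self.affinity_damping,)
        else:
            raise ValueError(f"unknown algorithm {algo!r}")
        return [dict(zip(keys, combo)) for combo in itertools.product(*axes)]


@dataclass
class ClusterAssignment:
    """Per-image cluster labels (NOISE = -1 allowed) with provenance."""

    labels: np.ndarray
    algorithm: str
    params: dict = field(default_factory=dict)
    measure: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        # contiguous ids ordered by first appearance; NOISE preserved
        mapping: dict[int, int] = {}
        out = np.full_like(self.labels, NOISE)
        for i, lab in enumerate(self.labels):
            if lab == NOISE:
                continue
            if lab not in mapping:
                mapping[lab] = len(mapping)
            out[i] = mapping[lab]
        self.labels = out

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()) - {NOISE})

    def partition(self, noise_as_singletons: bool = True) -> list[set]:
        return labels_to_partition(
            self.labels, noise_as_singletons=noise_as_singletons
        )


def _fit_one(algo: str, params: dict, emb: np.ndarray, D: np.ndarray,
             seed: int | None) -> np.ndarray:
    if algo == "dbscan":
        return DBSCAN(metric="precomputed", **params).fit_predict(D)
    if algo == "optics":
        return OPTICS(metric="precomputed", **params).fit_predict(D)
    if algo == "birch":
        # BIRCH's CF-tree is Euclidean by construction; the chosen measure
        # does not apply here
        return Birch(n_clusters=None, **params).fit_predict(emb)
    if algo == "affinity":
        if not 0.5 <= params["damping"] < 1.0:
            raise ValueError("damping must be in [0.5, 1)")
        with warnings.catch_warnings():
            warnings.filterwarnings("error", category=ConvergenceWarning)
            model = AffinityPropagation(
                affinity="precomputed", random_state=seed, **params
            )
            return model.fit_predict(-D)
    raise ValueError(f"unknown algorithm {algo!r}")


def _train_fmmf(labels: np.ndarray, train_idx: np.ndarray,
                train_truth: np.ndarray, drop_noise: bool) -> float:
    sub = labels[train_idx]
    pred = labels_to_partition(sub, noise_as_singletons=not drop_noise)
    true = labels_to_partition(train_truth, noise_label=None)
    if not pred:
        return -np.inf
    return fmmf(pred, true)[2]


def tune_and_fit(
    emb: np.ndarray,
    algo: str,
    space: SearchSpace | None = None,
    measure: str = "euclidean",
    train_idx: np.ndarray | None = None,
    train_truth: np.ndarray | None = None,
    drop_noise: bool = False,
    seed: int | None = 0,
) -> ClusterAssignment:
    """Exhaustive grid search scored by training-split FMMF.

    Each grid point fits on *all* points; the FMMF of the induced
    partition restricted to the training images against the true training
    classes picks the winner.  Ties break by higher silhouette, then
    fewer clusters, then first grid point.
    """
    emb = np.asarray(emb, dtype=float)
    space = space or SearchSpace()
    if train_idx is None:
        train_idx = np.arange(len(emb))
    train_idx = np.asarray(train_idx)
    if train_truth is None:
        raise ValueError("train_truth labels are required for tuning")
    train_truth = np.asarray(train_truth)
    D = distance_matrix(emb, measure)
    best = None  # (score, silhouette, -n_clusters, -order, labels, params)
    for order, params in enumerate(space.grid_points(algo)):
        try:
            labels = _fit_one(algo, params, emb, D, seed)
        except Exception as exc:  # failed grid point (e.g. AP divergence)
            logger.info("%s %s failed: %s", algo, params, exc)
            continue
        score = _train_fmmf(labels, train_idx, train_truth, drop_noise)
        sil, _, _ = _metrics.unsupervised_scores(emb, labels, measure)
        sil = -np.inf if sil is None else sil
        n_cl = len(set(labels.tolist()) - {NOISE})
        key = (score, sil, -n_cl, -order)
        if best is None or key > best[0]:
            best = (key, labels, params)
    if best is None:
        raise RuntimeError(f"every {algo} grid point failed")
    key, labels, params = best
    n_cl = len(set(labels.tolist()) - {NOISE})
    if n_cl <= 1 or n_cl == 0:
        warnings.warn(
            f"best {algo} fit found {n_cl} cluster(s); returning it anyway"
        )
    return ClusterAssignment(
        labels=labels,
        algorithm=algo,
        params=params,
        measure=measure,
        meta={"train_fmmf": key[0], "silhouette": key[1]},
    )


class GridTunedClusterer(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper around distance selection + grid tuning.

    ``fit(X, y)`` expects ground-truth labels ``y`` for the training rows
    given by ``train_idx`` (all rows by default); with
    ``measure='auto'`` the distance is first chosen by training-class
    silhouette.  Fitted attributes: ``labels_``, ``measure_``,
    ``best_params_``, ``assignment_``.
    """

    def __init__(
        self,
        algorithm: str = "optics",
        measure: str = "auto",
        space: SearchSpace | None = None,
        train_idx=None,
        drop_noise: bool = False,
        random_state: int | None = 0,
    ):
        self.algorithm = algorithm
        self.measure = measure
        self.space = space
        self.train_idx = train_idx
        self.drop_noise = drop_noise
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("semi-supervised tuning requires labels y")
        y = np.asarray(y)
        idx = (np.arange(len(X)) if self.train_idx is None
               else np.asarray(self.train_idx))
        measure = self.measure
        if measure == "auto":
            measure = select_distance(X, idx, y[idx] if len(y) == len(X)
                                      else y)
        truth = y[idx] if len(y) == len(X) else y
        self.assignment_ = tune_and_fit(
            X, self.algorithm, self.space, measure, idx, truth,
            self.drop_noise, self.random_state,
        )
        self.labels_ = self.assignment_.labels
        self.measure_ = measure
        self.best_params_ = self.assignment_.params
        return self


def _communities_to_labels(n: int, comms) -> np.ndarray:
    labels = np.full(n, NOISE, dtype=int)
    for k, comm in enumerate(comms):
        for v in comm:
            labels[int(v)] = k
    # nodes left out (e.g. by k-clique) become singleton clusters
    nxt = len(comms)
    for v in np.flatnonzero(labels == NOISE):
        labels[v] = nxt
        nxt += 1
    return labels


def graph_cluster(
    g: SimilarityGraph,
    method: str,
    params: dict | None = None,
    seed: int | None = 0,
) -> ClusterAssignment:
    """Partition the similarity graph with one of eight classical methods.

    Methods defined only for undirected graphs symmetrise a directed
    input first (logged); weighted methods use shift-to-positive weights.
    """
    import networkx as nx

    params = dict(params or {})
    if method not in GRAPH_METHODS:
        raise ValueError(f"unknown graph clustering method {method!r}")
    n = g.n_nodes

    needs_undirected = method in (
        "wcc", "walktrap", "greedy_modularity", "k_clique",
        "label_prop_semisync",
    )
    h = g
    if needs_undirected and g.directed:
        logger.info("%s requires an undirected graph; symmetrising", method)
        h = symmetrize(g)

    if method == "scc":
        if not g.directed:
            raise ValueError("scc requires a directed graph")
        comms = list(nx.strongly_connected_components(g.to_networkx()))
    elif method == "wcc":
        G = h.to_networkx()
        comms = list(nx.connected_components(G))
    elif method == "walktrap":
        ig_g = h.to_igraph(positive_weights=True)
        if ig_g.is_directed():
            ig_g = ig_g.as_undirected(combine_edges="max")
        steps = int(params.pop("steps", 4))
        comms = ig_g.community_walktrap(
            weights="weight", steps=steps
        ).as_clustering()
        comms = [list(c) for c in comms]
    elif method == "edge_betweenness":
        ig_g = g.to_igraph(positive_weights=True)
        dend = ig_g.community_edge_betweenness(directed=g.directed)
        comms = [list(c) for c in dend.as_clustering()]
    elif method == "greedy_modularity":
        G = h.to_networkx()
        shifted = shift_positive(h.weight)
        for (u, v, d), w in zip(G.edges(data=True), shifted):
            d["weight"] = float(w)
        comms = list(nx.community.greedy_modularity_communities(
            G, weight="weight"))
    elif method == "k_clique":
        G = h.to_networkx()
        comms = [set(c) for c in
                 nx.community.k_clique_communities(G, int(params.pop("k", 3)))]
    elif method == "label_prop_semisync":
        comms = list(nx.community.label_propagation_communities(
            h.to_networkx()))
    else:  # label_prop_async
        G = g.to_networkx()
        shifted = shift_positive(g.weight)
        for (u, v, d), w in zip(G.edges(data=True), shifted):
            d["weight"] = float(w)
        comms = list(nx.community.asyn_lpa_communities(
            G, weight="weight", seed=seed))
    labels = _communities_to_labels(n, comms)
    return ClusterAssignment(
        labels=labels, algorithm=method, params=params,
        measure=g.measure,
        meta={"directed": g.directed, "seed": seed},
    )
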