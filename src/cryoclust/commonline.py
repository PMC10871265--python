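"""Common-line similarity graphs between 2D projection images.

By the projection slice theorem, two 2D projections of the same 3D object
share a common 1D line projection.  Each image is reduced to its set of 1D
line projections over angles [0, 180) at a fixed step; every image pair is
scored by the best-matching signal pair under a chosen measure; per-node
Z-scored scores define a directed top-k (or global top-m-edge) similarity
graph.

Line projections use an exactly mass-conserving pixel-splatting projector:
each pixel centre is rotated and its full intensity is distributed
linearly between the two adjacent signal bins.  Signals live on a padded
bin grid (length ``N + 2*pad``) so no mass is clipped at any angle; at
0 degrees the central ``N`` bins are exactly the image's column sums.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "DISTANCE_MEASURES",
    "SIMILARITY_MEASURES",
    "LineProjectionStack",
    "SimilarityGraph",
    "line_projections",
    "line_projection_stack",
    "pair_score",
    "score_all_pairs",
    "build_similarity_graph",
    "symmetrize",
    "shift_positive",
    "CommonLineGraph",
    "read_graph_tsv",
    "write_graph_tsv",
]

#: measures where the optimum is the minimum
DISTANCE_MEASURES = ("L1", "L2", "wasserstein")
#: measures where the optimum is the maximum
SIMILARITY_MEASURES = ("cosine", "correlation")


@dataclass
class LineProjectionStack:
    """Per-image A x L matrices of 1D line projections (A angles, L bins)."""

    signals: np.ndarray  # (n, A, L)
    angles: np.ndarray  # degrees in [0, 180)

    @property
    def n_images(self) -> int:
        return self.signals.shape[0]


@dataclass
class SimilarityGraph:
    """Weighted graph over image indices.

    Edge arrays are parallel: ``raw_score`` is the optimal pair score,
    ``weight`` the per-node Z-scored (distance-negated) weight, and
    ``angle_src``/``angle_dst`` the best common-line angle pair.
    """

    n_nodes: int
    src: np.ndarray
    dst: np.ndarray
    raw_score: np.ndarray
    weight: np.ndarray
    angle_src: np.ndarray
    angle_dst: np.ndarray
    directed: bool = True
    measure: str = "L2"
    mode: str = "top_k"
    meta: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def to_networkx(self):
        import networkx as nx

        G = nx.DiGraph() if self.directed else nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        for s, d, r, w, a, b in zip(
            self.src, self.dst, self.raw_score, self.weight,
            self.angle_src, self.angle_dst,
        ):
            G.add_edge(int(s), int(d), weight=float(w), raw_score=float(r),
                       angle_src=float(a), angle_dst=float(b))
        return G

    def to_igraph(self, positive_weights: bool = True):
        import igraph as ig

        g = ig.Graph(
            n=self.n_nodes,
            edges=list(zip(self.src.tolist(), self.dst.tolist())),
            directed=self.directed,
        )
        w = shift_positive(self.weight) if positive_weights else self.weight
        g.es["weight"] = w.tolist()
        return g


def shift_positive(w: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Make weights strictly positive (w - min + eps) when any are <= 0."""
    w = np.asarray(w, dtype=float)
    if len(w) == 0 or w.min() > 0:
        return w
    return w - w.min() + eps


def _pad_width(n: int) -> int:
    # diagonal of the image must fit; preserve parity so that at 0 degrees
    # bins align exactly with pixel columns
    return int(np.ceil(n * (np.sqrt(2) - 1) / 2)) + 1


def line_projections(
    image: np.ndarray, angle_step_deg: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """1D line projections of a square image -> (signals (A, L), angles).

    The signal at angle theta is the set of line integrals perpendicular
    to direction theta — equivalently the column sums of the image rotated
    by -theta about its centre ((N-1)/2 convention) — computed by exact
    linear splatting of pixel intensities onto ``L = N + 2*pad`` bins.
    Every signal sums to the image's total intensity exactly.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square; pad it first")
    if not np.isclose(180.0 / angle_step_deg, round(180.0 / angle_step_deg)):
        raise ValueError("angle_step_deg must divide 180")
    n = image.shape[0]
    angles = np.arange(0.0, 180.0, angle_step_deg)
    L = n + 2 * _pad_width(n)
    c = (n - 1) / 2
    off = np.arange(n) - c
    vv, uu = np.meshgrid(off, off, indexing="ij")  # v = row, u = column
    u, v, vals = uu.ravel(), vv.ravel(), image.ravel()
    out = np.zeros((len(angles), L))
    centre = (L - 1) / 2
    for ai, theta in enumerate(np.deg2rad(angles)):
        t = u * np.cos(theta) + v * np.sin(theta) + centre
        i0 = np.floor(t).astype(int)
        f = t - i0
        np.add.at(out[ai], i0, vals * (1 - f))
        np.add.at(out[ai], i0 + 1, vals * f)
    return out, angles


def line_projection_stack(
    images: np.ndarray, angle_step_deg: float = 5.0
) -> LineProjectionStack:
    out = [line_projections(im, angle_step_deg) for im in images]
    return LineProjectionStack(
        signals=np.stack([s for s, _ in out]), angles=out[0][1]
    )


def _signal_measure_matrix(
    lp_i: np.ndarray, lp_j: np.ndarray, measure: str
) -> tuple[np.ndarray, bool]:
    """All-by-all score matrix between two A x L signal sets.

    Returns (matrix, larger_is_better).  Undefined entries (zero-variance
    signals under correlation, zero-norm under cosine) are set to -inf so
    they are skipped by the arg-max, matching the convention that such
    pairs score similarity 0.
    """
    if measure == "L1":
        return cdist(lp_i, lp_j, "cityblock"), False
    if measure == "L2":
        return cdist(lp_i, lp_j, "euclidean"), False
    if measure == "wasserstein":
        return _wasserstein_matrix(lp_i, lp_j), False
    if measure in ("cosine", "correlation"):
        bad_i = (
            lp_i.std(axis=1) == 0 if measure == "correlation"
            else np.linalg.norm(lp_i, axis=1) == 0
        )
        bad_j = (
            lp_j.std(axis=1) == 0 if measure == "correlation"
            else np.linalg.norm(lp_j, axis=1) == 0
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = 1.0 - cdist(lp_i, lp_j, measure.replace("L", ""))
        sim = np.nan_to_num(sim, nan=0.0)
        if bad_i.any() or bad_j.any():
            logger.warning(
                "%s undefined for %d degenerate signals; scored 0 and "
                "skipped for the optimum", measure,
                int(bad_i.sum() + bad_j.sum()),
            )
            sim[bad_i, :] = -np.inf
            sim[:, bad_j] = -np.inf
        return sim, True
    raise ValueError(f"unknown measure {measure!r}")


def _wasserstein_matrix(lp_i: np.ndarray, lp_j: np.ndarray) -> np.ndarray:
    # shift to nonnegative, normalise to unit mass, then 1D W1 distance is
    # the L1 distance between CDFs (unit bin width)
    def cdfs(lp):
        shifted = lp - lp.min(axis=1, keepdims=True)
        mass = shifted.sum(axis=1, keepdims=True)
        if np.any(mass == 0):
            raise ValueError("zero-mass signal under wasserstein measure")
        return np.cumsum(shifted / mass, axis=1)

    return cdist(cdfs(lp_i), cdfs(lp_j), "cityblock")


def pair_score(
    lp_i: np.ndarray,
    lp_j: np.ndarray,
    measure: str = "L2",
    angles: np.ndarray | None = None,
    shift_search: int = 0,
) -> tuple[float, float, float]:
    """Best common-line score between two images' line-projection sets.

    Evaluates the measure on all A x A signal pairs and returns the
    optimum (minimum for distances, maximum for similarities) with its
    angle pair; exact ties break to the lexicographically smallest
    ``(angle_i, angle_j)``.  With ``shift_search = w`` the signals are
    additionally compared over integer relative shifts in [-w, w] and the
    best shift is taken (for imperfectly centred images).
    """
    lp_i = np.asarray(lp_i, dtype=float)
    lp_j = np.asarray(lp_j, dtype=float)
    if lp_i.shape[1] != lp_j.shape[1]:
        raise ValueError("signal lengths differ")
    if angles is None:
        angles = np.arange(lp_i.shape[0]) * (180.0 / lp_i.shape[0])
    best_M = None
    for sh in range(-shift_search, shift_search + 1):
        shifted = np.roll(lp_j, sh, axis=1) if sh else lp_j
        M, larger = _signal_measure_matrix(lp_i, shifted, measure)
        if best_M is None:
            best_M = M
        else:
            best_M = np.maximum(best_M, M) if larger else np.minimum(best_M, M)
    M, larger = best_M, measure in SIMILARITY_MEASURES
    flat = np.argmax(M) if larger else np.argmin(M)
    ai, aj = np.unravel_index(flat, M.shape)
    score = M[ai, aj]
    if not np.isfinite(score):
        # every pair degenerate under a similarity measure
        return 0.0, float(angles[0]), float(angles[0])
    return float(score), float(angles[ai]), float(angles[aj])


def score_all_pairs(
    stack: LineProjectionStack, measure: str = "L2", shift_search: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete off-diagonal score matrix with best-angle annotations.

    Returns ``(scores, angle_src, angle_dst)``, each n x n; entry (i, j)
    holds the best score of image pair (i, j) and the corresponding
    common-line angles of images i and j.
    """
    n = stack.n_images
    scores = np.zeros((n, n))
    a_src = np.zeros((n, n))
    a_dst = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s, ai, aj = pair_score(
                stack.signals[i], stack.signals[j], measure,
                angles=stack.angles, shift_search=shift_search,
            )
            scores[i, j] = scores[j, i] = s
            a_src[i, j], a_dst[i, j] = ai, aj
            a_src[j, i], a_dst[j, i] = aj, ai
    return scores, a_src, a_dst


def build_similarity_graph(
    scores: np.ndarray,
    angle_src: np.ndarray | None = None,
    angle_dst: np.ndarray | None = None,
    measure: str = "L2",
    mode: str = "top_k",
    k: int = 5,
    m: int = 3000,
    global_zscore: bool = False,
) -> SimilarityGraph:
    """Z-score the candidate scores and keep the strongest edges.

    Per source node, its n-1 off-diagonal candidate scores are Z-scored
    (``global_zscore=True`` Z-scores over the whole matrix instead);
    distance measures are negated after Z-scoring so that larger weight
    always means more similar.  ``top_k`` keeps the k largest-weight
    out-edges per node (directed); ``top_m_edges`` keeps the m largest
    weights globally.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if scores.shape != (n, n):
        raise ValueError("scores must be square")
    if angle_src is None:
        angle_src = np.zeros_like(scores)
    if angle_dst is None:
        angle_dst = np.zeros_like(scores)
    offdiag = ~np.eye(n, dtype=bool)
    W = np.full((n, n), -np.inf)
    if global_zscore:
        vals = scores[offdiag]
        sd = vals.std()
        if sd == 0:
            warnings.warn("zero variance of candidate scores; weights set to 0")
            W[offdiag] = 0.0
        else:
            W[offdiag] = (scores[offdiag] - vals.mean()) / sd
    else:
        for i in range(n):
            row = scores[i, offdiag[i]]
            sd = row.std()
            if sd == 0:
                warnings.warn(
                    f"node {i}: zero variance of candidate scores; weights 0"
                )
                W[i, offdiag[i]] = 0.0
            else:
                W[i, offdiag[i]] = (row - row.mean()) / sd
    if measure in DISTANCE_MEASURES:
        W[offdiag] = -W[offdiag]

    if mode == "top_k":
        if k >= n:
            warnings.warn(f"k={k} >= n={n}; keeping all edges")
            k = n - 1
        src, dst = [], []
        for i in range(n):
            order = np.argsort(-W[i], kind="stable")  # ties -> smaller dst
            keep = [j for j in order if j != i][:k]
            src.extend([i] * len(keep))
            dst.extend(keep)
    elif mode == "top_m_edges":
        cand = np.argwhere(offdiag)
        vals = W[cand[:, 0], cand[:, 1]]
        order = np.argsort(-vals, kind="stable")[: min(m, len(vals))]
        src = cand[order, 0].tolist()
        dst = cand[order, 1].tolist()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    src = np.asarray(src, dtype=int)
    dst = np.asarray(dst, dtype=int)
    return SimilarityGraph(
        n_nodes=n,
        src=src,
        dst=dst,
        raw_score=scores[src, dst],
        weight=W[src, dst],
        angle_src=angle_src[src, dst],
        angle_dst=angle_dst[src, dst],
        directed=True,
        measure=measure,
        mode=mode,
        meta={"k": k, "m": m, "global_zscore": global_zscore},
    )


def symmetrize(g: SimilarityGraph) -> SimilarityGraph:
    """Undirected graph: edge {u, v} iff u->v or v->u, weight = max."""
    if not g.directed:
        return g
    best: dict[tuple[int, int], int] = {}
    for e in range(g.n_edges):
        key = (min(g.src[e], g.dst[e]), max(g.src[e], g.dst[e]))
        if key not in best or g.weight[e] > g.weight[best[key]]:
            best[key] = e
    idx = np.array([best[k] for k in sorted(best)], dtype=int)
    keys = np.array(sorted(best), dtype=int)
    return replace(
        g,
        src=keys[:, 0] if len(keys) else np.array([], dtype=int),
        dst=keys[:, 1] if len(keys) else np.array([], dtype=int),
        raw_score=g.raw_score[idx],
        weight=g.weight[idx],
        angle_src=g.angle_src[idx],
        angle_dst=g.angle_dst[idx],
        directed=False,
    )


class CommonLineGraph(BaseEstimator):
    """Estimator building the common-line similarity graph of an image stack.

    Parameters follow the graph-construction conventions above.  After
    ``fit(images)`` the fitted graph is available as ``graph_`` (directed)
    and the raw score matrix as ``scores_``.
    """

    def __init__(
        self,
        measure: str = "L2",
        angle_step_deg: float = 5.0,
        mode: str = "top_k",
        k: int = 5,
        m: int = 3000,
        directed: bool = True,
        global_zscore: bool = False,
        shift_search: int = 0,
    ):
        self.measure = measure
        self.angle_step_deg = angle_step_deg
        self.mode = mode
        self.k = k
        self.m = m
        self.directed = directed
        self.global_zscore = global_zscore
        self.shift_search = shift_search

    def fit(self, X, y=None):
        images = X.images if hasattr(X, "images") else np.asarray(X)
        stack = line_projection_stack(images, self.angle_step_deg)
        self.stack_ = stack
        self.scores_, a_src, a_dst = score_all_pairs(
            stack, self.measure, self.shift_search
        )
        g = build_similarity_graph(
            self.scores_, a_src, a_dst, self.measure, self.mode,
            self.k, self.m, self.global_zscore,
        )
        self.graph_ = g if self.directed else symmetrize(g)
        return self

    def fit_transform(self, X, y=None) -> SimilarityGraph:
        return self.fit(X).graph_


def write_graph_tsv(path, g: SimilarityGraph) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# n_nodes={g.n_nodes} directed={int(g.directed)} "
            f"measure={g.measure} mode={g.mode}\n"
        )
        fh.write("src\tdst\traw_score\tweight\tangle_src\tangle_dst\n")
        for e in range(g.n_edges):
            fh.write(
                f"{g.src[e]}\t{g.dst[e]}\t{g.raw_score[e]:.10g}\t"
                f"{g.weight[e]:.10g}\t{g.angle_src[e]:g}\t{g.angle_dst[e]:g}\n"
            )


def read_graph_tsv(path) -> SimilarityGraph:
    """Import an edge list (e.g. precomputed SLICEM scores)."""
    meta = {"n_nodes": 0, "directed": 1, "measure": "L2", "mode": "top_k"}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
            elif line and not line.startswith("src\t"):
                rows.append(line.split("\t"))
    arr = np.array(rows, dtype=float) if rows else np.zeros((0, 6))
    n_nodes = int(meta["n_nodes"]) or (int(arr[:, :2].max()) + 1 if len(arr) else 0)
    return SimilarityGraph(
        n_nodes=n_nodes,
        src=arr[:, 0].astype(int),
        dst=arr[:, 1].astype(int),
        raw_score=arr[:, 2],
        weight=arr[:, 3],
        angle_src=arr[:, 4],
        angle_dst=arr[:, 5],
        directed=bool(int(meta["directed"])),
        measure=str(meta["measure"]),
        mode=str(meta["mode"]),
    )
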