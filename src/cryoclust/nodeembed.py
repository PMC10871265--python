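"""Vector embeddings of similarity-graph nodes.

Three methods behind one interface, all deterministic under a seed:

* :class:`Node2Vec` — biased second-order random walks (return parameter
  p, in-out parameter q) fed to skip-gram with negative sampling.  The
  skip-gram trainer is a compact numpy implementation of SGNS.
* :class:`GraphWave` — structure-only spectral embedding: for each heat
  scale s the wavelet ``psi_a = U diag(exp(-s*lambda)) U^T delta_a`` is
  summarised by its empirical characteristic function sampled at evenly
  spaced points; structurally equivalent nodes get identical embeddings.
* :class:`DGIEmbedder` — Deep Graph Infomax over a one-layer GCN encoder:
  node/summary pairs from the true attribute matrix are discriminated
  from row-shuffled corruptions; gradients are computed analytically.

Z-scored edge weights may be negative; every consumer that needs a valid
probability or Laplacian applies the per-graph shift ``w - min + eps``,
which preserves the similarity ranking.

Any callable ``(graph, attrs, seed) -> n x d matrix`` plugs into the
pipeline in place of these classes.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .commonline import SimilarityGraph, shift_positive, symmetrize

__all__ = [
    "Node2Vec",
    "GraphWave",
    "DGIEmbedder",
    "node2vec_embed",
    "graphwave_embed",
    "dgi_gcn_embed",
]


def _adjacency(g: SimilarityGraph, symmetric: bool) -> np.ndarray:
    h = symmetrize(g) if (symmetric and g.directed) else g
    A = np.zeros((g.n_nodes, g.n_nodes))
    w = shift_positive(h.weight)
    A[h.src, h.dst] = w
    if not h.directed:
        A[h.dst, h.src] = w
    return A


class Node2Vec(BaseEstimator):
    """Biased random-walk + skip-gram (SGNS) node embedding.

    Walks follow edge direction on directed graphs; transition
    probabilities are proportional to shift-positive edge weights with
    the standard p/q second-order bias.  ``fit`` stores ``embedding_``
    (n x dim); nodes never visited by any walk get zero vectors.
    """

    def __init__(
        self,
        dim: int = 128,
        p: float = 1.0,
        q: float = 1.0,
        walks_per_node: int = 10,
        walk_length: int = 80,
        window: int = 10,
        n_negatives: int = 5,
        epochs: int = 3,
        learning_rate: float = 0.025,
        random_state: int = 0,
    ):
        self.dim = dim
        self.p = p
        self.q = q
        self.walks_per_node = walks_per_node
        self.walk_length = walk_length
        self.window = window
        self.n_negatives = n_negatives
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _walks(self, g: SimilarityGraph, rng) -> list[list[int]]:
        n = g.n_nodes
        nbrs: list[np.ndarray] = [None] * n
        wts: list[np.ndarray] = [None] * n
        for v in range(n):
            mask = g.src == v
            nbrs[v] = g.dst[mask]
            wts[v] = g.weight[mask]
        if not g.directed:
            # include reverse direction for undirected graphs
            for v in range(n):
                mask = g.dst == v
                nbrs[v] = np.concatenate([nbrs[v], g.src[mask]])
                wts[v] = np.concatenate([wts[v], g.weight[mask]])
        # per-node shift to strictly positive: w - min + eps
        for v in range(n):
            if len(wts[v]):
                wts[v] = wts[v] - wts[v].min() + 1e-6
        nbr_sets = [set(a.tolist()) for a in nbrs]
        walks = []
        for _ in range(self.walks_per_node):
            for start in range(n):
                walk = [start]
                while len(walk) < self.walk_length:
                    cur = walk[-1]
                    if len(nbrs[cur]) == 0:
                        break
                    w = wts[cur].copy()
                    if len(walk) >= 2:
                        prev = walk[-2]
                        for idx, x in enumerate(nbrs[cur]):
                            if x == prev:
                                w[idx] /= self.p
                            elif x not in nbr_sets[prev]:
                                w[idx] /= self.q
                    probs = w / w.sum()
                    walk.append(int(rng.choice(nbrs[cur], p=probs)))
                walks.append(walk)
        return walks

    def fit(self, g: SimilarityGraph, y=None):
        if g.n_nodes < 2:
            raise ValueError("graph must have >= 2 nodes")
        if self.walk_length < self.window:
            raise ValueError("walk_length must be >= window")
        rng = np.random.default_rng(self.random_state)
        walks = self._walks(g, rng)
        centers, contexts = [], []
        for walk in walks:
            arr = walk
            for i, c in enumerate(arr):
                lo = max(0, i - self.window)
                hi = min(len(arr), i + self.window + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers.append(c)
                        contexts.append(arr[j])
        centers = np.asarray(centers, dtype=int)
        contexts = np.asarray(contexts, dtype=int)
        n = g.n_nodes
        counts = np.bincount(contexts, minlength=n).astype(float)
        visited = np.bincount(
            np.concatenate([centers, contexts]), minlength=n
        ) > 0
        noise = counts**0.75
        noise = noise / noise.sum() if noise.sum() else np.full(n, 1 / n)
        W_in = (rng.random((n, self.dim)) - 0.5) / self.dim
        W_out = (rng.random((n, self.dim)) - 0.5) / self.dim
        n_pairs = len(centers)
        batch = 1024
        step = 0
        total = max(1, self.epochs * ((n_pairs + batch - 1) // batch))
        for _ in range(self.epochs):
            order = rng.permutation(n_pairs)
            for s in range(0, n_pairs, batch):
                idx = order[s:s + batch]
                lr = self.learning_rate * max(
                    1e-4, 1 - step / total
                )
                step += 1
                c, o = centers[idx], contexts[idx]
                neg = rng.choice(n, size=(len(idx), self.n_negatives),
                                 p=noise)
                vc = W_in[c]  # (b, d)
                uo = W_out[o]  # (b, d)
                un = W_out[neg]  # (b, k, d)
                pos_s = 1 / (1 + np.exp(
                    -np.clip(np.sum(vc * uo, axis=1), -10, 10)))
                neg_s = 1 / (1 + np.exp(
                    -np.clip(np.einsum("bd,bkd->bk", vc, un), -10, 10)))
                g_pos = (pos_s - 1)[:, None]  # d/duo
                g_neg = neg_s[:, :, None]
                grad_vc = g_pos * uo + np.einsum("bk,bkd->bd", neg_s, un)
                # accumulate, then normalise by per-node multiplicity so a
                # node repeated within the batch still takes an O(lr) step
                upd_in = np.zeros_like(W_in)
                np.add.at(upd_in, c, grad_vc)
                cnt = np.bincount(c, minlength=n)[:, None]
                W_in -= lr * upd_in / np.maximum(cnt, 1)
                upd_out = np.zeros_like(W_out)
                np.add.at(upd_out, o, g_pos * vc)
                np.add.at(
                    upd_out, neg.ravel(),
                    (g_neg * vc[:, None, :]).reshape(-1, self.dim),
                )
                cnt_o = (np.bincount(o, minlength=n)
                         + np.bincount(neg.ravel(), minlength=n))[:, None]
                W_out -= lr * upd_out / np.maximum(cnt_o, 1)
        if not visited.all():
            warnings.warn(
                f"{int((~visited).sum())} isolated node(s) embedded as zero"
            )
            W_in[~visited] = 0.0
        self.embedding_ = W_in
        return self


class GraphWave(BaseEstimator):
    """Spectral heat-wavelet structural embedding.

    The graph is symmetrised for the Laplacian; features are the real and
    imaginary parts of the empirical characteristic function of each
    node's heat wavelet at ``n_sample_points`` points evenly spaced in
    ``[0, t_max]``, for each heat scale.  Output dimension is
    ``2 * n_sample_points * len(scales)``.

    ``scales="auto"`` (default) picks two scales from the Laplacian
    spectrum, ``-ln(eta)/sqrt(lambda_2 * lambda_max)`` for eta in
    {0.95, 0.70}; a fixed scale that is large relative to the spectrum
    makes every heat wavelet collapse onto the constant eigenvector and
    the embedding degenerate.  Fitted attribute ``scales_`` holds the
    scales actually used.
    """

    def __init__(self, scales="auto", n_sample_points: int = 50,
                 t_max: float = 100.0):
        self.scales = scales
        self.n_sample_points = n_sample_points
        self.t_max = t_max

    def fit(self, g: SimilarityGraph, y=None):
        A = _adjacency(g, symmetric=True)
        A = np.maximum(A, A.T)
        L = np.diag(A.sum(axis=1)) - A
        lam, U = np.linalg.eigh(L)
        if isinstance(self.scales, str) and self.scales == "auto":
            pos = lam[lam > 1e-9]
            if len(pos):
                geo = np.sqrt(pos.min() * pos.max())
                self.scales_ = (-np.log(0.95) / geo, -np.log(0.70) / geo)
            else:
                self.scales_ = (1.0,)
        else:
            self.scales_ = tuple(self.scales)
        ts = np.linspace(0, self.t_max, self.n_sample_points)
        feats = []
        for s in self.scales_:
            H = U @ np.diag(np.exp(-s * lam)) @ U.T  # heat kernel
            # column a = psi_a; characteristic fn over its n coefficients
            phase = np.exp(1j * ts[None, None, :] * H.T[:, :, None])
            phi = phase.mean(axis=1)  # (n, n_points)
            feats.append(np.real(phi))
            feats.append(np.imag(phi))
        self.embedding_ = np.hstack(feats)
        return self


def _prelu(x, a):
    return np.where(x > 0, x, a * x)


class DGIEmbedder(BaseEstimator):
    """Deep Graph Infomax with a one-layer GCN encoder (numpy).

    The encoder is ``Z = PReLU(A_hat X W)`` over the symmetrised,
    self-looped, symmetrically degree-normalised adjacency.  A bilinear
    discriminator separates true (node, graph-summary) pairs from pairs
    built on a row-shuffled attribute matrix; W, the bilinear matrix and
    the PReLU slope are trained with Adam on the analytic gradients.
    """

    def __init__(self, dim: int = 128, epochs: int = 100,
                 learning_rate: float = 1e-3, random_state: int = 0):
        self.dim = dim
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, g: SimilarityGraph, X: np.ndarray = None, y=None):
        if X is None:
            raise ValueError("DGI requires node attributes X")
        X = np.asarray(X, dtype=float)
        if X.shape[0] != g.n_nodes:
            raise ValueError(
                f"attribute rows ({X.shape[0]}) != nodes ({g.n_nodes})"
            )
        # standardise attributes for stable training
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        A = _adjacency(g, symmetric=True)
        A = np.maximum(A, A.T) + np.eye(g.n_nodes)
        dinv = 1.0 / np.sqrt(A.sum(axis=1))
        Ahat = A * dinv[:, None] * dinv[None, :]
        rng = np.random.default_rng(self.random_state)
        n, d = X.shape
        k = self.dim
        W = rng.normal(0, np.sqrt(2.0 / d), size=(d, k))
        M = np.eye(k) + rng.normal(0, 0.01, size=(k, k))
        a = 0.25  # PReLU slope
        AX = Ahat @ X
        params = [W, M, np.array([a])]
        mom = [np.zeros_like(p) for p in params]
        vel = [np.zeros_like(p) for p in params]
        t = 0
        for _ in range(self.epochs):
            Xc = X[rng.permutation(n)]
            AXc = Ahat @ Xc
            H, Hc = AX @ W, AXc @ W
            a = float(params[2][0])
            Z, Zc = _prelu(H, a), _prelu(Hc, a)
            s = 1 / (1 + np.exp(-Z.mean(axis=0)))
            Ms = M @ s
            dpos = Z @ Ms
            dneg = Zc @ Ms
            sp = 1 / (1 + np.exp(-dpos))
            sn = 1 / (1 + np.exp(-dneg))
            g_d = (sp - 1) / n
            g_dc = sn / n
            zsum = Z.T @ g_d + Zc.T @ g_dc  # (k,)
            gM = np.outer(zsum, s)
            gs = M.T @ zsum
            gZ = np.outer(g_d, Ms) + (s * (1 - s) * gs)[None, :] / n
            gZc = np.outer(g_dc, Ms)
            gH = gZ * np.where(H > 0, 1.0, a)
            gHc = gZc * np.where(Hc > 0, 1.0, a)
            ga = np.sum(gZ * np.where(H > 0, 0.0, H)) + np.sum(
                gZc * np.where(Hc > 0, 0.0, Hc)
            )
            gW = AX.T @ gH + AXc.T @ gHc
            t += 1
            for p, gr, m_, v_ in zip(
                params, [gW, gM, np.array([ga])], mom, vel
            ):
                m_ += (1 - 0.9) * (gr - m_)
                v_ += (1 - 0.999) * (gr**2 - v_)
                mhat = m_ / (1 - 0.9**t)
                vhat = v_ / (1 - 0.999**t)
                p -= self.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
            M = params[1]
        W = params[0]
        a = float(params[2][0])
        self.embedding_ = _prelu(AX @ W, a)
        return self


def node2vec_embed(g: SimilarityGraph, seed: int = 0, **params) -> np.ndarray:
    return Node2Vec(random_state=seed, **params).fit(g).embedding_


def graphwave_embed(g: SimilarityGraph, **params) -> np.ndarray:
    return GraphWave(**params).fit(g).embedding_


def dgi_gcn_embed(
    g: SimilarityGraph, node_attrs: np.ndarray, seed: int = 0, **params
) -> np.ndarray:
    return DGIEmbedder(random_state=seed, **params).fit(g, node_attrs).embedding_
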