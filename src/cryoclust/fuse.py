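"""Fusing image and graph-node embeddings, with variance-rule reduction.

Embeddings are concatenated (before or after reduction) and reduced by
PCA when dense, or by uncentred truncated SVD when sparse (fraction of
exactly-zero entries above a cutoff); components explaining less than a
variance-ratio threshold (default 2%) are dropped, keeping at least two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["FusionConfig", "VarianceReducer", "reduce", "combine", "sparsity"]


@dataclass
class FusionConfig:
    mode: str = "concat_then_reduce"
    var_threshold: float = 0.02
    sparsity_cutoff: float = 0.5
    standardize: bool = True

    def __post_init__(self):
        if not 0 < self.var_threshold < 1:
            raise ValueError("var_threshold must be in (0, 1)")
        if self.mode not in (
            "concat_then_reduce", "reduce_then_concat", "image_only",
            "node_only",
        ):
            raise ValueError(f"unknown fusion mode {self.mode!r}")


def sparsity(X: np.ndarray) -> float:
    """Fraction of exactly-zero entries."""
    X = np.asarray(X)
    return float((X == 0).mean())


class VarianceReducer(BaseEstimator, TransformerMixin):
    """PCA (dense) / uncentred truncated SVD (sparse) keeping components
    whose explained-variance ratio reaches ``var_threshold`` (minimum 2).

    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making outputs reproducible.  Fitted
    attributes: ``components_``, ``explained_variance_ratio_``, ``mean_``
    (None on the SVD branch), ``branch_`` ("pca" or "svd").
    """

    def __init__(self, var_threshold: float = 0.02,
                 sparsity_cutoff: float = 0.5):
        self.var_threshold = var_threshold
        self.sparsity_cutoff = sparsity_cutoff

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need an n x d matrix with n >= 2")
        if np.all(X.max(axis=0) == X.min(axis=0)):
            raise ValueError("zero-variance matrix cannot be reduced")
        self.branch_ = "svd" if sparsity(X) > self.sparsity_cutoff else "pca"
        if self.branch_ == "pca":
            self.mean_ = X.mean(axis=0)
            Xc = X - self.mean_
        else:
            self.mean_ = None
            Xc = X
        _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        ratio = S**2 / np.sum(S**2)
        n_keep = max(2, int(np.sum(ratio >= self.var_threshold)))
        n_keep = min(n_keep, len(S))
        # deterministic sign: largest-|loading| entry positive
        for i in range(n_keep):
            j = np.argmax(np.abs(Vt[i]))
            if Vt[i, j] < 0:
                Vt[i] = -Vt[i]
        self.components_ = Vt[:n_keep]
        self.explained_variance_ratio_ = ratio[:n_keep]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.mean_ is not None:
            X = X - self.mean_
        return X @ self.components_.T


def reduce(
    emb: np.ndarray, var_threshold: float = 0.02, sparsity_cutoff: float = 0.5
) -> np.ndarray:
    return VarianceReducer(var_threshold, sparsity_cutoff).fit_transform(emb)


def _standardize(X: np.ndarray) -> np.ndarray:
    # zero mean, unit variance per column; zero-variance columns dropped
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    return (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]


def combine(
    img_emb: np.ndarray | None,
    node_emb: np.ndarray | None,
    cfg: FusionConfig | None = None,
) -> np.ndarray:
    """Fuse image and node embeddings per the configured mode.

    Blocks are column-standardised before concatenation (so one block's
    scale cannot dominate) unless ``cfg.standardize`` is False.  Rows
    stay index-aligned with the input images.
    """
    cfg = cfg or FusionConfig()
    red = lambda X: reduce(X, cfg.var_threshold, cfg.sparsity_cutoff)
    if cfg.mode == "image_only":
        if img_emb is None:
            raise ValueError("image_only mode requires an image embedding")
        return red(img_emb)
    if cfg.mode == "node_only":
        if node_emb is None:
            raise ValueError("node_only mode requires a node embedding")
        return red(node_emb)
    if img_emb is None or node_emb is None:
        raise ValueError(f"mode {cfg.mode!r} requires both embeddings")
    img_emb = np.asarray(img_emb, dtype=float)
    node_emb = np.asarray(node_emb, dtype=float)
    if img_emb.shape[0] != node_emb.shape[0]:
        raise ValueError("row counts differ; embeddings must be index-aligned")
    if cfg.mode == "reduce_then_concat":
        img_emb, node_emb = red(img_emb), red(node_emb)
    prep = _standardize if cfg.standardize else np.asarray
    fused = np.hstack([prep(img_emb), prep(node_emb)])
    if cfg.mode == "concat_then_reduce":
        fused = red(fused)
    return fused
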