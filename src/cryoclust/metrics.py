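"""Cluster-comparison metrics for projection sorting.

Predicted groups of projection images are compared against ground-truth
particle classes with set-overlap F-scores borrowed from the protein-complex
prediction literature:

* **F-similarity** between a predicted and a true cluster: harmonic mean of
  the overlap precision ``|P∩T|/|P|`` and recall ``|P∩T|/|T|``.
* **FMMF** — maximal-matching F-score: a maximum-weight one-to-one bipartite
  matching on the F-similarity matrix; matched weight normalised by the
  number of predicted (precision) or true (recall) clusters.
* **CMMF** — community-wise maximum F-score: each cluster keeps its single
  best partner, without the one-to-one constraint.
* **Qi F-score** — a cluster pair "matches" when the overlap statistic
  ``|P∩T|² / (|P|·|T|)`` reaches a threshold ω (default 0.25).
* **UnSPA** — geometric mean of sensitivity and an unbiased PPV computed on
  raw overlap counts.

Partitions are sequences of nonempty sets of hashable item ids.  Helpers
convert flat label vectors (with an optional noise label) to partitions.

Unsupervised indices (silhouette under an arbitrary distance measure,
Calinski-Harabasz, Davies-Bouldin) are delegated to scikit-learn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Hashable, Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "EvalReport",
    "f_similarity",
    "fmmf",
    "cmmf",
    "qi_fscore",
    "unspa",
    "unsupervised_scores",
    "labels_to_partition",
    "partition_to_labels",
    "evaluate_partition",
    "harmonic_mean",
]

#: label used for points a density-based clusterer declines to assign
NOISE = -1


@dataclass
class EvalReport:
    """Named metric values for one clustering result."""

    fmm_precision: float = math.nan
    fmm_recall: float = math.nan
    fmmf: float = math.nan
    cmmf_precision: float = math.nan
    cmmf_recall: float = math.nan
    cmmf: float = math.nan
    unspa: float = math.nan
    qi_precision: float = math.nan
    qi_recall: float = math.nan
    qi_f: float = math.nan
    n_pred_clusters: int = 0
    n_true_clusters: int = 0
    silhouette: float | None = None
    calinski_harabasz: float | None = None
    davies_bouldin: float | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.update(d.pop("extra"))
        return d


def harmonic_mean(p: float, r: float) -> float:
    """2pr/(p+r), defined as 0 when p + r = 0."""
    return 0.0 if p + r == 0 else 2.0 * p * r / (p + r)


def _check_partition(part: Sequence[set], name: str) -> list[set]:
    part = [set(c) for c in part]
    if not part:
        raise ValueError(f"{name} partition is empty")
    if any(len(c) == 0 for c in part):
        raise ValueError(f"{name} partition contains an empty cluster")
    return part


def f_similarity(P: Iterable[Hashable], T: Iterable[Hashable]) -> float:
    """F-similarity of two clusters: harmonic mean of overlap precision/recall."""
    P, T = set(P), set(T)
    if not P or not T:
        raise ValueError("f_similarity requires nonempty sets")
    o = len(P & T)
    if o == 0:
        return 0.0
    return harmonic_mean(o / len(P), o / len(T))


def _fsim_matrix(pred: list[set], true: list[set]) -> np.ndarray:
    M = np.zeros((len(pred), len(true)))
    for i, P in enumerate(pred):
        for j, T in enumerate(true):
            o = len(P & T)
            if o:
                p = o / len(P)
                r = o / len(T)
                M[i, j] = 2 * p * r / (p + r)
    return M


def fmmf(pred: Sequence[set], true: Sequence[set]) -> tuple[float, float, float]:
    """Maximal-matching F-score (precision, recall, F).

    A maximum-weight bipartite matching is computed on the pairwise
    F-similarity matrix; the total matched weight is divided by the number
    of predicted clusters (precision) and true clusters (recall).
    """
    pred = _check_partition(pred, "pred")
    true = _check_partition(true, "true")
    M = _fsim_matrix(pred, true)
    ri, ci = linear_sum_assignment(M, maximize=True)
    w = float(M[ri, ci].sum())
    p = w / len(pred)
    r = w / len(true)
    return p, r, harmonic_mean(p, r)


def cmmf(pred: Sequence[set], true: Sequence[set]) -> tuple[float, float, float]:
    """Community-wise maximum F-score: per-cluster best match, averaged."""
    pred = _check_partition(pred, "pred")
    true = _check_partition(true, "true")
    M = _fsim_matrix(pred, true)
    p = float(M.max(axis=1).mean())
    r = float(M.max(axis=0).mean())
    return p, r, harmonic_mean(p, r)


def qi_fscore(
    pred: Sequence[set], true: Sequence[set], omega_threshold: float = 0.25
) -> tuple[float, float, float]:
    """Qi et al. F-score with overlap statistic ω = |P∩T|²/(|P||T|) ≥ threshold."""
    pred = _check_partition(pred, "pred")
    true = _check_partition(true, "true")
    omega = np.zeros((len(pred), len(true)))
    for i, P in enumerate(pred):
        for j, T in enumerate(true):
            o = len(P & T)
            omega[i, j] = o * o / (len(P) * len(T))
    matched = omega >= omega_threshold
    p = float(matched.any(axis=1).mean())
    r = float(matched.any(axis=0).mean())
    return p, r, harmonic_mean(p, r)


def unspa(pred: Sequence[set], true: Sequence[set]) -> float:
    """Unbiased Sn-PPV accuracy: sqrt(Sn × PPV) on raw overlap counts.

    Sn sums, over true clusters, the best overlap with any predicted cluster
    (normalised by total true size); the unbiased PPV does the same with the
    roles swapped, normalised by total predicted size.
    """
    pred = _check_partition(pred, "pred")
    true = _check_partition(true, "true")
    O = np.zeros((len(pred), len(true)))
    for i, P in enumerate(pred):
        for j, T in enumerate(true):
            O[i, j] = len(P & T)
    sn = float(O.max(axis=0).sum()) / sum(len(T) for T in true)
    ppv = float(O.max(axis=1).sum()) / sum(len(P) for P in pred)
    return math.sqrt(sn * ppv)


def labels_to_partition(
    labels: Sequence[Hashable],
    noise_label: Hashable = NOISE,
    noise_as_singletons: bool = True,
) -> list[set]:
    """Group item indices by label.

    Noise-labelled items become singleton clusters (so they penalise
    precision) unless ``noise_as_singletons`` is False, in which case they
    are dropped from the partition.
    """
    clusters: dict[Hashable, set] = {}
    singles: list[set] = []
    for i, lab in enumerate(labels):
        if lab == noise_label:
            if noise_as_singletons:
                singles.append({i})
        else:
            clusters.setdefault(lab, set()).add(i)
    return [clusters[k] for k in sorted(clusters, key=repr)] + singles


def partition_to_labels(part: Sequence[set], n_items: int) -> np.ndarray:
    """Inverse of :func:`labels_to_partition`; unassigned items get NOISE."""
    labels = np.full(n_items, NOISE, dtype=int)
    for k, c in enumerate(part):
        for i in c:
            labels[i] = k
    return labels


def unsupervised_scores(
    emb: np.ndarray, labels: Sequence[int], measure: str = "euclidean"
) -> tuple[float | None, float | None, float | None]:
    """(silhouette, Calinski-Harabasz, Davies-Bouldin) ignoring noise points.

    Silhouette is computed under ``measure`` (see cluster.distance_matrix);
    the other two indices are Euclidean by definition.  With fewer than two
    clusters all three are returned as None.
    """
    from sklearn.metrics import (
        calinski_harabasz_score,
        davies_bouldin_score,
        silhouette_score,
    )

    from .cluster import distance_matrix

    labels = np.asarray(labels)
    keep = labels != NOISE
    labels, emb = labels[keep], np.asarray(emb)[keep]
    if len(np.unique(labels)) < 2 or len(labels) - 1 < len(np.unique(labels)):
        return None, None, None
    D = distance_matrix(emb, measure)
    sil = float(silhouette_score(D, labels, metric="precomputed"))
    ch = float(calinski_harabasz_score(emb, labels))
    db = float(davies_bouldin_score(emb, labels))
    return sil, ch, db


def evaluate_partition(
    pred: Sequence[set],
    true: Sequence[set],
    emb: np.ndarray | None = None,
    measure: str = "euclidean",
    n_items: int | None = None,
    omega_threshold: float = 0.25,
) -> EvalReport:
    """All supervised metrics (and optionally unsupervised ones) in one report."""
    fp, fr, ff = fmmf(pred, true)
    cp, cr, cf = cmmf(pred, true)
    qp, qr, qf = qi_fscore(pred, true, omega_threshold)
    rep = EvalReport(
        fmm_precision=fp,
        fmm_recall=fr,
        fmmf=ff,
        cmmf_precision=cp,
        cmmf_recall=cr,
        cmmf=cf,
        unspa=unspa(pred, true),
        qi_precision=qp,
        qi_recall=qr,
        qi_f=qf,
        n_pred_clusters=len(pred),
        n_true_clusters=len(true),
    )
    if emb is not None:
        if n_items is None:
            n_items = len(emb)
        labels = partition_to_labels(pred, n_items)
        rep.silhouette, rep.calinski_harabasz, rep.davies_bouldin = (
            unsupervised_scores(emb, labels, measure)
        )
    return rep
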