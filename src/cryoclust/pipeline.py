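"""End-to-end orchestration: method combinations, AutoML ranking, plots.

A :class:`MethodCombo` names one path through the pipeline — image
embedding (none / tiny-cnn / siamese), similarity-graph spec, node
embedding (none / node2vec / graphwave / dgi-gcn / user callable),
fusion mode, and a clusterer (one of the four tuned spatial algorithms
or one of the eight graph methods).  :func:`run_automl` fixes one 70-30
class split, tunes every combo on the training classes, ranks by
training FMMF, and reports train / test / overall metrics per combo.
"""

from __future__ import annotations

import hashlib
import logging
import traceback
from dataclasses import dataclass, field

import numpy as np

from . import fuse as _fuse
from .cluster import (
    GRAPH_METHODS,
    ClusterAssignment,
    SearchSpace,
    graph_cluster,
    select_distance,
    tune_and_fit,
)
from .commonline import CommonLineGraph, SimilarityGraph
from .imgembed import SiameseEmbedder, pretrained_embed, split_complexes
from .metrics import (
    EvalReport,
    evaluate_partition,
    labels_to_partition,
    unsupervised_scores,
)
from .nodeembed import DGIEmbedder, GraphWave, Node2Vec
from .simulate import ProjectionSet

logger = logging.getLogger(__name__)

__all__ = [
    "MethodCombo", "RunConfig", "evaluate_method", "run_automl",
    "tsne_plot", "default_combos",
]

SPATIAL_ALGOS = ("dbscan", "optics", "birch", "affinity")


@dataclass
class MethodCombo:
    """One pipeline configuration (see module docstring)."""

    image_method: str | None = None  # None | "tiny-cnn" | "siamese" | ...
    node_method: object = None  # None | method name | callable
    graph_measure: str = "L2"
    graph_mode: str = "top_k"
    k: int = 5
    m: int = 3000
    directed: bool = True
    fusion_mode: str = "concat_then_reduce"
    clusterer: str = "optics"
    distance: str = "auto"
    angle_step_deg: float = 5.0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image_method is None and self.node_method is None \
                and self.clusterer not in GRAPH_METHODS:
            raise ValueError(
                "combo needs at least one representation source or a "
                "graph clusterer"
            )

    def describe(self) -> str:
        node = (self.node_method if isinstance(self.node_method, (str,
                type(None))) else getattr(self.node_method, "__name__",
                                          "custom"))
        bits = []
        if self.image_method:
            bits.append(f"img={self.image_method}")
        if node:
            bits.append(f"node={node}")
        bits.append(
            f"graph={self.graph_measure} {self.graph_mode} "
            f"{'dir' if self.directed else 'undir'}"
        )
        if self.image_method and node:
            bits.append(f"fuse={self.fusion_mode}")
        bits.append(f"cluster={self.clusterer}")
        return ", ".join(bits)


@dataclass
class RunConfig:
    combos: list = field(default_factory=list)
    seed: int = 0
    train_frac: float = 0.7
    output_dir: str | None = None
    cache: bool = True
    search_space: SearchSpace = field(default_factory=SearchSpace)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(open(path))
        combos = [MethodCombo(**c) for c in raw.pop("combos", [])]
        space = raw.pop("search_space", None)
        cfg = cls(combos=combos, **raw)
        if space:
            cfg.search_space = SearchSpace(**space)
        return cfg


def default_combos() -> list[MethodCombo]:
    """The default AutoML search list: embedding combos mirroring the
    strongest published settings, plus graph clusterers on L2/cosine
    graphs (directed and undirected)."""
    combos: list[MethodCombo] = []
    for img in ("siamese", "tiny-cnn"):
        for node in ("node2vec", "graphwave", "dgi-gcn"):
            for mode in ("concat_then_reduce", "reduce_then_concat"):
                for algo in SPATIAL_ALGOS:
                    combos.append(MethodCombo(
                        image_method=img, node_method=node,
                        fusion_mode=mode, clusterer=algo,
                    ))
    for measure in ("L2", "cosine"):
        for directed in (True, False):
            for method in GRAPH_METHODS:
                if method == "scc" and not directed:
                    continue
                combos.append(MethodCombo(
                    graph_measure=measure, directed=directed,
                    clusterer=method,
                ))
    return combos


def _hash_key(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
        else:
            h.update(repr(p).encode())
    return h.hexdigest()


class _Cache(dict):
    def get_or(self, key, fn):
        if key not in self:
            self[key] = fn()
        return self[key]


def _node_embedding(combo: MethodCombo, g: SimilarityGraph,
                    img_emb, seed: int) -> np.ndarray:
    nm = combo.node_method
    if callable(nm):
        return np.asarray(nm(g, img_emb, seed))
    if nm == "node2vec":
        return Node2Vec(random_state=seed,
                        **combo.params.get("node2vec", {})).fit(g).embedding_
    if nm == "graphwave":
        return GraphWave(**combo.params.get("graphwave", {})).fit(g).embedding_
    if nm == "dgi-gcn":
        attrs = img_emb
        if attrs is None:
            attrs = pretrained_embed(
                _node_embedding._ps, "tiny-cnn", seed=seed
            )
        return DGIEmbedder(random_state=seed,
                           **combo.params.get("dgi", {})).fit(
            g, attrs).embedding_
    raise ValueError(f"unknown node embedding method {nm!r}")


def evaluate_method(
    ps: ProjectionSet,
    combo: MethodCombo,
    truth: np.ndarray | None = None,
    seed: int = 0,
    train_classes: set | None = None,
    cache: _Cache | None = None,
    search_space: SearchSpace | None = None,
) -> EvalReport:
    """Run one combo end to end and score it against the truth labels.

    Any stage failure is caught: the report comes back with
    ``extra['failed']`` set and the failing stage recorded, so an AutoML
    sweep continues past broken combos.
    """
    truth = ps.labels if truth is None else np.asarray(truth)
    cache = cache if cache is not None else _Cache()
    stage = "setup"
    rep = EvalReport()
    rep.extra["combo"] = combo.describe()
    rep.extra["seed"] = seed
    try:
        if truth is None:
            raise ValueError("ground-truth labels are required for tuning")
        n = len(ps)
        if train_classes is None:
            train_classes, _ = split_complexes(truth, seed=seed)
        train_idx = np.flatnonzero(np.isin(truth, list(train_classes)))
        test_idx = np.setdiff1d(np.arange(n), train_idx)

        needs_graph = combo.node_method is not None or \
            combo.clusterer in GRAPH_METHODS
        g = None
        if needs_graph:
            stage = "graph"
            key = _hash_key("graph", ps.images, combo.graph_measure,
                            combo.graph_mode, combo.k, combo.m,
                            combo.directed, combo.angle_step_deg)
            g = cache.get_or(key, lambda: CommonLineGraph(
                measure=combo.graph_measure, mode=combo.graph_mode,
                k=combo.k, m=combo.m, directed=combo.directed,
                angle_step_deg=combo.angle_step_deg,
            ).fit_transform(ps.images))

        img_emb = None
        if combo.image_method is not None:
            stage = "image_embedding"
            if combo.image_method == "siamese":
                key = _hash_key("siamese", ps.images, truth,
                                sorted(map(repr, train_classes)), seed,
                                repr(combo.params.get("siamese", {})))

                def _train():
                    sub = ps.subset(train_idx)
                    est = SiameseEmbedder(
                        random_state=seed,
                        **combo.params.get("siamese", {}),
                    ).fit(sub, truth[train_idx])
                    return est.transform(ps.images)

                img_emb = cache.get_or(key, _train)
            else:
                key = _hash_key("img", ps.images, combo.image_method, seed)
                img_emb = cache.get_or(key, lambda: pretrained_embed(
                    ps, combo.image_method, seed=seed))

        node_emb = None
        if combo.node_method is not None:
            stage = "node_embedding"
            _node_embedding._ps = ps
            key = _hash_key("node", repr(combo.node_method), g.src, g.dst,
                            g.weight, seed,
                            repr(sorted(combo.params.items())),
                            "none" if img_emb is None else img_emb)
            node_emb = cache.get_or(
                key, lambda: _node_embedding(combo, g, img_emb, seed))

        if combo.clusterer in GRAPH_METHODS:
            stage = "graph_clustering"
            assignment = graph_cluster(
                g, combo.clusterer, combo.params.get("graph", {}), seed=seed
            )
            measure = None
        else:
            stage = "fusion"
            if img_emb is not None and node_emb is not None:
                cfg = _fuse.FusionConfig(mode=combo.fusion_mode)
            elif img_emb is not None:
                cfg = _fuse.FusionConfig(mode="image_only")
            else:
                cfg = _fuse.FusionConfig(mode="node_only")
            emb = _fuse.combine(img_emb, node_emb, cfg)
            stage = "clustering"
            measure = combo.distance
            if measure == "auto":
                measure = select_distance(emb, train_idx, truth[train_idx])
            assignment = tune_and_fit(
                emb, combo.clusterer, search_space, measure,
                train_idx, truth[train_idx], seed=seed,
            )
            rep.silhouette, rep.calinski_harabasz, rep.davies_bouldin = \
                unsupervised_scores(emb, assignment.labels, measure)

        stage = "evaluation"
        true_part = labels_to_partition(truth, noise_label=None)
        pred_part = assignment.partition()
        full = evaluate_partition(pred_part, true_part)
        for f in ("fmm_precision", "fmm_recall", "fmmf", "cmmf_precision",
                  "cmmf_recall", "cmmf", "unspa", "qi_precision",
                  "qi_recall", "qi_f", "n_pred_clusters", "n_true_clusters"):
            setattr(rep, f, getattr(full, f))
        for name, idx in (("train", train_idx), ("test", test_idx)):
            if len(idx) == 0:
                continue
            sub_pred = labels_to_partition(assignment.labels[idx])
            sub_true = labels_to_partition(truth[idx], noise_label=None)
            subrep = evaluate_partition(sub_pred, sub_true)
            rep.extra[f"{name}_fmmf"] = subrep.fmmf
            rep.extra[f"{name}_cmmf"] = subrep.cmmf
            rep.extra[f"{name}_qi_f"] = subrep.qi_f
        rep.extra.update(
            algorithm=assignment.algorithm,
            chosen_params=assignment.params,
            chosen_distance=measure,
            failed=False,
        )
    except Exception as exc:
        logger.warning("combo %s failed at %s: %s", combo.describe(), stage,
                       exc)
        rep.extra.update(
            failed=True, stage=stage, error=f"{type(exc).__name__}: {exc}",
            traceback=traceback.format_exc(),
        )
    return rep


def run_automl(ps: ProjectionSet, config: RunConfig | None = None):
    """Tune every combo on one fixed class split; rank by training FMMF.

    Returns a pandas DataFrame (one row per non-failed combo, ranked)
    with overall/train/test metrics and full provenance columns.
    """
    import pandas as pd

    from . import __version__

    config = config or RunConfig()
    combos = config.combos or default_combos()
    if ps.labels is None:
        raise ValueError("AutoML needs ground-truth labels")
    train_classes, test_classes = split_complexes(
        ps.labels, config.train_frac, config.seed
    )
    cache = _Cache() if config.cache else None
    rows = []
    for combo in combos:
        rep = evaluate_method(
            ps, combo, seed=config.seed, train_classes=train_classes,
            cache=cache if config.cache else _Cache(),
            search_space=config.search_space,
        )
        row = rep.as_dict()
        row["software_version"] = __version__
        rows.append(row)
    df = pd.DataFrame(rows)
    ok = df[~df["failed"]].copy() if "failed" in df else df
    ok = ok.sort_values("train_fmmf", ascending=False,
                        kind="stable").reset_index(drop=True)
    if config.output_dir:
        from pathlib import Path

        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        ok.to_csv(out / "automl_report.tsv", sep="\t", index=False)
    return ok


def tsne_plot(emb, labels, measure: str = "euclidean", seed: int = 0,
              out_path=None):
    """2-D t-SNE of the embeddings under the chosen distance measure.

    Perplexity is ``min(30, (n - 1) / 3)``; points are coloured by label.
    Returns the 2-D coordinates; writes a PNG when ``out_path`` is given.
    """
    from sklearn.manifold import TSNE

    from .cluster import distance_matrix

    emb = np.asarray(emb, dtype=float)
    n = len(emb)
    if n < 5:
        raise ValueError("need at least 5 points for a t-SNE plot")
    D = distance_matrix(emb, measure)
    coords = TSNE(
        n_components=2, metric="precomputed", init="random",
        perplexity=min(30.0, (n - 1) / 3), random_state=seed,
    ).fit_transform(D)
    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        labels = np.asarray(labels)
        fig, ax = plt.subplots(figsize=(6, 5))
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(coords[m, 0], coords[m, 1], s=18, label=str(lab))
        if len(np.unique(labels)) <= 12:
            ax.legend(fontsize=7, markerscale=0.8)
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return coords
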