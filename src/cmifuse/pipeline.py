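"""End-to-end orchestration: features, classifier, CV metrics, ranking.

For each labeled (circRNA, miRNA) pair two views are assembled — the
attribute view [circRNA Jaccard profile || miRNA MLM embedding] and the
behavior view [LINE embedding of each endpoint] — fused into a shared
latent by the autoencoder-in-autoencoder network, and classified by
gradient-boosted trees (XGBoost; the boosting objective itself is
delegated to that library).  Evaluation follows stratified k-fold
cross-validation with accuracy, precision, recall, F1, Matthews
correlation, ROC AUC and PR AUC reported per fold and as mean +/- SD.

Leakage control: in ``fold_safe`` mode (default) the interaction graph
used for LINE training contains only training-fold positives, the fusion
network is fit on training-fold samples, all scalers are fit on training
data, and test latents come from frozen-parameter inference.
``full_graph`` mode embeds the complete known graph before splitting —
the protocol many published pipelines appear to use — and is provided
for comparison; the report header records which mode produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from xgboost import XGBClassifier

from .attribute import AttributeMatrix, circ_attribute_matrix, pair_attribute_view
from .data_io import (
    FoldSplit,
    InteractionSet,
    LabeledPairSet,
    SequenceRecord,
    sample_negatives,
    split_folds,
)
from .embedder import EmbedderConfig, mirna_attribute_matrix, train_mlm_embedder
from .fusion import (
    Ae2Model,
    FusionConfig,
    MinMaxScaler,
    ViewSet,
    infer_latent,
    train_ae2,
)
from .line import EmbeddingMatrix, build_graph, line_embed, pair_behavior_view

METRIC_NAMES = ("ACC", "Prec", "Rec", "F1", "MCC", "AUC", "AUPR")


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(labels: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    """Four-way cross-classification of binary labels vs predictions."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary")
    return ConfusionCounts(
        TP=int(((y == 1) & (p == 1)).sum()),
        FP=int(((y == 0) & (p == 1)).sum()),
        TN=int(((y == 0) & (p == 0)).sum()),
        FN=int(((y == 1) & (p == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, precision, recall, F1 and Matthews correlation.

    A metric whose denominator is zero is reported as None (undefined),
    never silently as 0.
    """
    out: dict[str, float | None] = {}
    out["ACC"] = (c.TP + c.TN) / c.n if c.n else None
    out["Prec"] = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else None
    out["Rec"] = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    if out["Prec"] is None or out["Rec"] is None or (out["Prec"] + out["Rec"]) == 0:
        out["F1"] = None
    else:
        out["F1"] = 2 * out["Prec"] * out["Rec"] / (out["Prec"] + out["Rec"])
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        out["MCC"] = None
    else:
        out["MCC"] = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(float(denom))
    return out


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals the fraction of concordant positive-negative score pairs, with
    ties counted half.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve by step integration.

    Sums precision times recall increment over descending unique score
    thresholds (the average-precision estimator).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    if n_pos == 0 or (y == 0).sum() == 0:
        raise ValueError("pr_auc requires both classes")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    pred_pos = np.arange(1, len(y) + 1)
    # only evaluate at threshold boundaries (last index of each tie block)
    boundary = np.append(s_sorted[1:] != s_sorted[:-1], True)
    precision = tp[boundary] / pred_pos[boundary]
    recall = tp[boundary] / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))


# ---------------------------------------------------------------------------
# classifier


DEFAULT_CLASSIFIER_PARAMS = {
    "n_estimators": 300,
    "max_depth": 6,
    "learning_rate": 0.1,
}


def train_classifier(
    features: np.ndarray,
    labels: Sequence[int],
    params: dict | None = None,
    seed: int = 0,
) -> XGBClassifier:
    """Fit a gradient-boosted-tree classifier emitting P(interaction).

    Single-threaded and seeded, so repeated fits on identical inputs give
    identical predicted probabilities.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    merged = dict(DEFAULT_CLASSIFIER_PARAMS)
    if params:
        merged.update(params)
    clf = XGBClassifier(
        **merged,
        n_jobs=1,
        random_state=seed,
        tree_method="hist",
        eval_metric="logloss",
    )
    clf.fit(np.asarray(features, float), y)
    return clf


# ---------------------------------------------------------------------------
# configuration and report


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline, fanned out from one seed."""

    kmer_k: int = 5
    kmer_stride: int = 1
    circular_windows: bool = False
    embedder: EmbedderConfig = field(default_factory=EmbedderConfig)
    mirna_pooling: str = "cls"
    line_dim: int = 128
    # Negatives per positive edge.  1 at desk scale: on sparse graphs of a
    # few hundred edges, larger K over-weights the repulsion between
    # non-adjacent same-community vertices and erodes block structure
    # (K=5 is the usual choice at the scale of real interaction networks).
    line_K: int = 1
    line_samples_per_edge: int = 200
    line_lr: float = 0.025
    fusion: FusionConfig = field(default_factory=FusionConfig)
    classifier_params: dict = field(default_factory=dict)
    n_folds: int = 5
    negative_ratio: float = 1.0
    leakage_mode: str = "fold_safe"
    view_ablation: str = "none"
    resample_negatives_per_fold: bool = False
    standardize_attribute_view: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.negative_ratio <= 0:
            raise ValueError("negative_ratio must be > 0")
        if self.leakage_mode not in ("fold_safe", "full_graph"):
            raise ValueError("leakage_mode must be 'fold_safe' or 'full_graph'")
        if self.view_ablation not in ("none", "attribute_only", "behavior_only"):
            raise ValueError("unknown view_ablation")


def _stage_seeds(master: int) -> dict[str, int]:
    """Fixed fan-out of the master seed into independent stage seeds."""
    rng = np.random.default_rng(master)
    names = ("negatives", "folds", "embedder", "line", "fusion", "classifier")
    vals = rng.integers(0, 2**31 - 1 - 10**6, size=len(names))
    return {k: int(v) for k, v in zip(names, vals)}


@dataclass
class EvalReport:
    """Per-fold and aggregate cross-validation metrics."""

    folds: list[dict[str, float | None]]
    leakage_mode: str
    config_seed: int

    def aggregate(self) -> dict[str, tuple[float, float] | None]:
        out: dict[str, tuple[float, float] | None] = {}
        for name in METRIC_NAMES:
            vals = [f[name] for f in self.folds if f[name] is not None]
            if not vals:
                out[name] = None
            else:
                arr = np.array(vals, dtype=float)
                out[name] = (float(arr.mean()), float(arr.std(ddof=0)))
        return out

    def mean(self, name: str) -> float:
        agg = self.aggregate()[name]
        if agg is None:
            raise ValueError(f"metric {name} undefined in every fold")
        return agg[0]

    def to_tsv(self) -> str:
        """Deterministic text serialization (used for byte-identity checks)."""
        lines = [f"# leakage_mode={self.leakage_mode}", f"# seed={self.config_seed}"]
        lines.append("fold\t" + "\t".join(METRIC_NAMES))
        for i, f in enumerate(self.folds, start=1):
            cells = ["NA" if f[n] is None else repr(f[n]) for n in METRIC_NAMES]
            lines.append(f"{i}\t" + "\t".join(cells))
        agg = self.aggregate()
        mean_cells, sd_cells = [], []
        for n in METRIC_NAMES:
            if agg[n] is None:
                mean_cells.append("NA")
                sd_cells.append("NA")
            else:
                mean_cells.append(repr(agg[n][0]))
                sd_cells.append(repr(agg[n][1]))
        lines.append("mean\t" + "\t".join(mean_cells))
        lines.append("sd\t" + "\t".join(sd_cells))
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        agg = self.aggregate()
        parts = []
        for n in METRIC_NAMES:
            if agg[n] is None:
                parts.append(f"{n}=NA")
            else:
                parts.append(f"{n}={agg[n][0]:.4f}+/-{agg[n][1]:.4f}")
        return f"[{self.leakage_mode}] " + " ".join(parts)


# ---------------------------------------------------------------------------
# feature assembly


def _sequence_features(
    circ_records: Sequence[SequenceRecord],
    mirna_records: Sequence[SequenceRecord],
    config: PipelineConfig,
    seeds: dict[str, int],
) -> tuple[AttributeMatrix, AttributeMatrix]:
    """Label-free, fold-independent sequence featurization.

    Both the Jaccard profile and the MLM embedder use sequences only
    (no interaction labels), so they are computed once for all folds.
    """
    circ_attr = circ_attribute_matrix(
        circ_records,
        k=config.kmer_k,
        stride=config.kmer_stride,
        circular=config.circular_windows,
    )
    emb_cfg = EmbedderConfig(**{**_cfg_dict(config.embedder), "seed": seeds["embedder"]})
    embedder = train_mlm_embedder(mirna_records, emb_cfg)
    mir_attr = mirna_attribute_matrix(embedder, mirna_records, config.mirna_pooling)
    return circ_attr, mir_attr


def _cfg_dict(cfg) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


def _view_rows(
    pairs: Sequence[tuple[str, str]],
    circ_attr: AttributeMatrix,
    mir_attr: AttributeMatrix,
    emb: EmbeddingMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    attr = np.array([pair_attribute_view(circ_attr, mir_attr, p) for p in pairs])
    beh = np.array([pair_behavior_view(emb, p) for p in pairs])
    return attr, beh


class _ViewScaler:
    """Train-fit scaling of the two pair views.

    The attribute view is standardized per coordinate (its Jaccard block
    lives in [0,1] while embedder coordinates are unbounded) and both
    views are then min-max mapped to [0,1] for the sigmoid fusion
    network.  Ablations zero one view before scaling, collapsing it to a
    constant that carries no signal.
    """

    def __init__(self, standardize_attribute: bool, ablation: str) -> None:
        self.standardize_attribute = standardize_attribute
        self.ablation = ablation

    def fit(self, attr: np.ndarray, beh: np.ndarray) -> "_ViewScaler":
        attr, beh = self._ablate(attr, beh)
        if self.standardize_attribute:
            self.mu = attr.mean(axis=0)
            self.sd = attr.std(axis=0)
            self.sd = np.where(self.sd <= 0, 1.0, self.sd)
            attr = (attr - self.mu) / self.sd
        self.attr_mm = MinMaxScaler().fit(attr.T)
        self.beh_mm = MinMaxScaler().fit(beh.T)
        return self

    def transform(self, attr: np.ndarray, beh: np.ndarray) -> ViewSet:
        attr, beh = self._ablate(attr, beh)
        if self.standardize_attribute:
            attr = (attr - self.mu) / self.sd
        return ViewSet(X=[self.attr_mm.transform(attr.T), self.beh_mm.transform(beh.T)])

    def _ablate(self, attr, beh):
        if self.ablation == "attribute_only":
            beh = np.zeros_like(beh)
        elif self.ablation == "behavior_only":
            attr = np.zeros_like(attr)
        return attr, beh


def _subset_interactions(
    interactions: InteractionSet, pairs: Sequence[tuple[str, str]]
) -> InteractionSet:
    return InteractionSet(
        pairs=list(pairs),
        circ_index=dict(interactions.circ_index),
        mirna_index=dict(interactions.mirna_index),
    )


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    circ_records: Sequence[SequenceRecord],
    mirna_records: Sequence[SequenceRecord],
    interactions: InteractionSet,
    config: PipelineConfig,
) -> EvalReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Negatives are sampled once up front (the labeled set is fixed before
    splitting); per fold, behavioral embeddings, scalers and the fusion
    network are fit according to ``config.leakage_mode``, the classifier
    is trained on training-fold latents, and test-fold pairs are scored
    through frozen-parameter latent inference.  Fully reproducible from
    ``config.seed``.
    """
    seeds = _stage_seeds(config.seed)
    labeled = sample_negatives(
        interactions, ratio=config.negative_ratio, seed=seeds["negatives"]
    )
    folds = split_folds(labeled, config.n_folds, seed=seeds["folds"])
    circ_attr, mir_attr = _sequence_features(
        circ_records, mirna_records, config, seeds
    )

    fold_metrics: list[dict[str, float | None]] = []
    for f in range(config.n_folds):
        fold_metrics.append(
            _run_fold(
                labeled, folds, f, interactions, circ_attr, mir_attr, config, seeds
            )
        )
    return EvalReport(
        folds=fold_metrics, leakage_mode=config.leakage_mode, config_seed=config.seed
    )


def _run_fold(
    labeled: LabeledPairSet,
    folds: FoldSplit,
    fold: int,
    interactions: InteractionSet,
    circ_attr: AttributeMatrix,
    mir_attr: AttributeMatrix,
    config: PipelineConfig,
    seeds: dict[str, int],
) -> dict[str, float | None]:
    train_idx = folds.train_indices(fold)
    test_idx = folds.test_indices(fold)
    train_pairs = [labeled.pairs[i] for i in train_idx]
    y_train = labeled.labels[train_idx]
    test_pairs = [labeled.pairs[i] for i in test_idx]
    y_test = labeled.labels[test_idx]

    if config.resample_negatives_per_fold:
        # Re-draw training negatives, avoiding positives and test pairs.
        pos_pairs = [p for p, y in zip(train_pairs, y_train) if y == 1]
        forbidden = set(labeled.pairs)
        rng = np.random.default_rng(seeds["negatives"] + 1000 + fold)
        circ_ids = list(interactions.circ_index)
        mirna_ids = list(interactions.mirna_index)
        fresh: list[tuple[str, str]] = []
        while len(fresh) < int((y_train == 0).sum()):
            c = circ_ids[int(rng.integers(len(circ_ids)))]
            m = mirna_ids[int(rng.integers(len(mirna_ids)))]
            if (c, m) in forbidden or (c, m) in fresh:
                continue
            fresh.append((c, m))
        train_pairs = pos_pairs + fresh
        y_train = np.array([1] * len(pos_pairs) + [0] * len(fresh))

    if config.leakage_mode == "fold_safe":
        graph_pairs = [p for p, y in zip(train_pairs, y_train) if y == 1]
    else:
        graph_pairs = list(interactions.pairs)
    graph = build_graph(_subset_interactions(interactions, graph_pairs))
    emb = line_embed(
        graph,
        total_dim=config.line_dim,
        K=config.line_K,
        samples_per_edge=config.line_samples_per_edge,
        lr=config.line_lr,
        seed=seeds["line"] + fold,
    )

    attr_tr, beh_tr = _view_rows(train_pairs, circ_attr, mir_attr, emb)
    attr_te, beh_te = _view_rows(test_pairs, circ_attr, mir_attr, emb)
    scaler = _ViewScaler(config.standardize_attribute_view, config.view_ablation)
    scaler.fit(attr_tr, beh_tr)
    views_train = scaler.transform(attr_tr, beh_tr)
    views_test = scaler.transform(attr_te, beh_te)

    fus_cfg = FusionConfig(
        **{**_cfg_dict(config.fusion), "seed": seeds["fusion"] + fold}
    )
    model = train_ae2(views_train, fus_cfg)
    X_train = model.H.T
    X_test = infer_latent(model, views_test).T

    clf = train_classifier(
        X_train, y_train, config.classifier_params, seed=seeds["classifier"] + fold
    )
    scores = clf.predict_proba(X_test)[:, 1].astype(float)
    preds = (scores >= 0.5).astype(int)

    result = metrics(confusion(y_test, preds))
    result["AUC"] = roc_auc(y_test, scores)
    result["AUPR"] = pr_auc(y_test, scores)
    return result


# ---------------------------------------------------------------------------
# fitting on all data and ranking candidates


@dataclass
class FittedPipeline:
    """Pipeline fit on the full labeled set, ready to score new pairs."""

    config: PipelineConfig
    circ_attr: AttributeMatrix
    mir_attr: AttributeMatrix
    embedding: EmbeddingMatrix
    scaler: _ViewScaler
    fusion_model: Ae2Model
    classifier: XGBClassifier
    training_positives: set[tuple[str, str]]

    def score_pairs(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        attr, beh = _view_rows(pairs, self.circ_attr, self.mir_attr, self.embedding)
        views = self.scaler.transform(attr, beh)
        X = infer_latent(self.fusion_model, views).T
        return self.classifier.predict_proba(X)[:, 1].astype(float)


def fit_pipeline(
    circ_records: Sequence[SequenceRecord],
    mirna_records: Sequence[SequenceRecord],
    interactions: InteractionSet,
    config: PipelineConfig,
) -> FittedPipeline:
    """Train the full pipeline on all known positives + sampled negatives."""
    seeds = _stage_seeds(config.seed)
    labeled = sample_negatives(
        interactions, ratio=config.negative_ratio, seed=seeds["negatives"]
    )
    circ_attr, mir_attr = _sequence_features(
        circ_records, mirna_records, config, seeds
    )
    graph = build_graph(interactions)
    emb = line_embed(
        graph,
        total_dim=config.line_dim,
        K=config.line_K,
        samples_per_edge=config.line_samples_per_edge,
        lr=config.line_lr,
        seed=seeds["line"],
    )
    attr, beh = _view_rows(labeled.pairs, circ_attr, mir_attr, emb)
    scaler = _ViewScaler(config.standardize_attribute_view, config.view_ablation)
    scaler.fit(attr, beh)
    views = scaler.transform(attr, beh)
    fus_cfg = FusionConfig(**{**_cfg_dict(config.fusion), "seed": seeds["fusion"]})
    model = train_ae2(views, fus_cfg)
    clf = train_classifier(
        model.H.T, labeled.labels, config.classifier_params, seed=seeds["classifier"]
    )
    return FittedPipeline(
        config=config,
        circ_attr=circ_attr,
        mir_attr=mir_attr,
        embedding=emb,
        scaler=scaler,
        fusion_model=model,
        classifier=clf,
        training_positives=set(interactions.pairs),
    )


@dataclass
class PredictionRanking:
    """Candidate pairs in non-increasing score order (lexicographic ties)."""

    entries: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        scores = [e[2] for e in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing")

    def top(self, n: int) -> list[tuple[str, str, float]]:
        return self.entries[:n]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("circ_id\tmirna_id\tscore\n")
            for c, m, s in self.entries:
                out.write(f"{c}\t{m}\t{s!r}\n")


def rank_candidates(
    fitted: FittedPipeline, candidate_pairs: Sequence[tuple[str, str]]
) -> PredictionRanking:
    """Score candidate pairs and order them by descending probability.

    Candidates must be disjoint from the training positives; ties are
    broken lexicographically by (circ_id, mirna_id).
    """
    overlap = sorted(set(candidate_pairs) & fitted.training_positives)
    if overlap:
        raise ValueError(f"candidates overlap training positives: {overlap}")
    scores = fitted.score_pairs(candidate_pairs)
    order = sorted(
        range(len(candidate_pairs)),
        key=lambda i: (-scores[i], candidate_pairs[i][0], candidate_pairs[i][1]),
    )
    entries = [
        (candidate_pairs[i][0], candidate_pairs[i][1], float(scores[i])) for i in order
    ]
    return PredictionRanking(entries=entries)
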