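"""LINE graph embeddings of the known interaction network (from scratch).

Behavioral features of circRNAs and miRNAs are learned from the bipartite
graph of known interactions.  Two proximities are modeled:

* first order — the joint probability of a direct edge,
  p1(c, m) = sigma(u_c . u_m);
* second order — the neighborhood-context distribution,
  p2(m | c) = exp(u'_m . u_c) / sum_k exp(u'_k . u_c),
  where u' are separate context vectors.

Training maximizes the edge-weighted log-likelihood with negative
sampling: each SGD step draws an edge from an alias table (probability
proportional to its weight) and K noise vertices from a distribution
proportional to degree^(3/4), and applies the sigmoid-based update in
both edge directions.  First-order training uses the same
negative-sampled estimator with vertex vectors playing the context role
(the exact first-order objective alone has a degenerate optimum at
infinite norms).  The exact (full-softmax) objectives and their analytic
gradients are provided as test oracles for small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from numba import njit

from .data_io import InteractionSet


class AliasTable:
    """Walker alias method: O(1) sampling from a discrete distribution."""

    def __init__(self, weights: np.ndarray) -> None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        n = len(weights)
        self.n = n
        self.prob = np.zeros(n)
        self.alias = np.zeros(n, dtype=int)
        scaled = weights * n / weights.sum()
        small = [i for i, w in enumerate(scaled) if w < 1.0]
        large = [i for i, w in enumerate(scaled) if w >= 1.0]
        while small and large:
            s, l = small.pop(), large.pop()
            self.prob[s] = scaled[s]
            self.alias[s] = l
            scaled[l] -= 1.0 - scaled[s]
            (small if scaled[l] < 1.0 else large).append(l)
        for i in small + large:
            self.prob[i] = 1.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        cols = rng.integers(0, self.n, size=size)
        keep = rng.random(size) < self.prob[cols]
        return np.where(keep, cols, self.alias[cols])


@dataclass
class InteractionGraph:
    """Undirected bipartite interaction graph with sampling tables.

    Vertices are ordered circRNAs first, then miRNAs, restricted to ids
    with at least one edge; ids from the universe with no edge are kept
    separately as cold vertices.  The edge alias table samples edges with
    probability proportional to weight; the noise alias table samples
    vertices with probability proportional to degree^(3/4).
    """

    vertex_ids: list[str]
    is_circ: np.ndarray  # bool per vertex
    edges: np.ndarray  # (n_edges, 2) vertex indices (circ, mirna)
    weights: np.ndarray  # (n_edges,)
    degrees: np.ndarray  # weighted degree per vertex
    cold_ids: list[str]
    edge_alias: AliasTable = field(repr=False)
    noise_alias: AliasTable = field(repr=False)
    index: dict[str, int] = field(repr=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def noise_distribution(self) -> np.ndarray:
        w = self.degrees**0.75
        return w / w.sum()


def build_graph(
    interactions: InteractionSet, weights: np.ndarray | None = None
) -> InteractionGraph:
    """Build an InteractionGraph (with alias tables) from known pairs."""
    if not interactions.pairs:
        raise ValueError("cannot build a graph from an empty edge list")
    circ_with_edge = {c for c, _ in interactions.pairs}
    mirna_with_edge = {m for _, m in interactions.pairs}
    warm_circ = [c for c in interactions.circ_index if c in circ_with_edge]
    warm_mirna = [m for m in interactions.mirna_index if m in mirna_with_edge]
    cold = [c for c in interactions.circ_index if c not in circ_with_edge]
    cold += [m for m in interactions.mirna_index if m not in mirna_with_edge]

    vertex_ids = warm_circ + warm_mirna
    index = {v: i for i, v in enumerate(vertex_ids)}
    edges = np.array([(index[c], index[m]) for c, m in interactions.pairs], dtype=int)
    if weights is None:
        weights = np.ones(len(edges))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("edge weights must be positive")
    degrees = np.zeros(len(vertex_ids))
    np.add.at(degrees, edges[:, 0], weights)
    np.add.at(degrees, edges[:, 1], weights)
    is_circ = np.array([i < len(warm_circ) for i in range(len(vertex_ids))])
    return InteractionGraph(
        vertex_ids=vertex_ids,
        is_circ=is_circ,
        edges=edges,
        weights=weights,
        degrees=degrees,
        cold_ids=cold,
        edge_alias=AliasTable(weights),
        noise_alias=AliasTable(degrees**0.75),
        index=index,
    )


Order = Literal["first", "second"]


@dataclass
class LineModel:
    """Vertex (and, for second order, context) vectors of one LINE order."""

    dim: int
    order: Order
    vertex_vectors: np.ndarray  # (n_vertices, dim)
    context_vectors: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.order == "second") != (self.context_vectors is not None):
            raise ValueError("context vectors present iff order == 'second'")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def first_order_prob(u_c: np.ndarray, u_m: np.ndarray) -> float:
    """First-order edge probability sigma(u_c . u_m)."""
    u_c, u_m = np.asarray(u_c, float), np.asarray(u_m, float)
    if u_c.shape != u_m.shape:
        raise ValueError("vector length mismatch")
    return float(_sigmoid(u_c @ u_m))


def second_order_prob(
    graph: InteractionGraph, model: LineModel, c: str, m: str
) -> float:
    """Context probability p2(m | c): softmax over all graph vertices."""
    if model.order != "second":
        raise ValueError("second_order_prob requires a second-order model")
    try:
        ci, mi = graph.index[c], graph.index[m]
    except KeyError as exc:
        raise KeyError(f"unknown vertex {exc.args[0]!r}") from None
    scores = model.context_vectors @ model.vertex_vectors[ci]
    scores = scores - scores.max()
    e = np.exp(scores)
    return float(e[mi] / e.sum())


def init_line_model(
    graph: InteractionGraph, dim: int, order: Order, seed: int = 0
) -> LineModel:
    """Seeded initialization: vertex vectors uniform in [-0.5/dim, 0.5/dim],
    context vectors zero (keeps every initial edge probability at 0.5)."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(-0.5 / dim, 0.5 / dim, size=(graph.n_vertices, dim))
    ctx = np.zeros((graph.n_vertices, dim)) if order == "second" else None
    return LineModel(dim=dim, order=order, vertex_vectors=u, context_vectors=ctx)


def exact_objective(graph: InteractionGraph, model: LineModel) -> float:
    """Edge-weighted log-likelihood (test oracle for small graphs).

    First order sums W_cm log sigma(u_c . u_m) over undirected edges;
    second order sums W_cm log p2 over both directions of each edge with
    the full softmax normalizer.
    """
    u = model.vertex_vectors
    if model.order == "first":
        dots = np.einsum("ij,ij->i", u[graph.edges[:, 0]], u[graph.edges[:, 1]])
        return float(np.sum(graph.weights * np.log(_sigmoid(dots))))
    ctx = model.context_vectors
    total = 0.0
    for (a, b), w in zip(graph.edges, graph.weights):
        for src, tgt in ((a, b), (b, a)):
            scores = ctx @ u[src]
            scores = scores - scores.max()
            total += w * (scores[tgt] - np.log(np.exp(scores).sum()))
    return float(total)


def exact_objective_grad(
    graph: InteractionGraph, model: LineModel
) -> tuple[np.ndarray, np.ndarray | None]:
    """Analytic full-batch gradient of exact_objective.

    Returns (d/d vertex_vectors, d/d context_vectors); the second element
    is None for first-order models.  Shares the trainer's likelihood
    math; checked against central differences in the tests.
    """
    u = model.vertex_vectors
    du = np.zeros_like(u)
    if model.order == "first":
        for (a, b), w in zip(graph.edges, graph.weights):
            g = w * (1.0 - _sigmoid(u[a] @ u[b]))
            du[a] += g * u[b]
            du[b] += g * u[a]
        return du, None
    ctx = model.context_vectors
    dctx = np.zeros_like(ctx)
    for (a, b), w in zip(graph.edges, graph.weights):
        for src, tgt in ((a, b), (b, a)):
            scores = ctx @ u[src]
            p = np.exp(scores - scores.max())
            p /= p.sum()
            # d/du_src: w * (u'_tgt - E_p[u'])
            du[src] += w * (ctx[tgt] - p @ ctx)
            dctx[tgt] += w * u[src]
            dctx -= w * p[:, None] * u[src][None, :]
    return du, dctx


class DivergenceError(RuntimeError):
    pass


@njit(cache=True)
def _sgd_kernel(u, ctx, edges, edge_idx, noise, K, lr, min_lr):
    """Sequential negative-sampled SGD over a presampled edge/noise stream.

    Mirrors the update rule documented in train_line; the noise stream
    wraps around when exhausted (it is sized with ample slack), and a
    noise draw matching either endpoint of the current positive pair is
    skipped after 100 rejected tries.
    """
    n_samples = edge_idx.shape[0]
    dim = u.shape[1]
    noise_pos = 0
    n_noise = noise.shape[0]
    dx = np.empty(dim)
    for step in range(n_samples):
        rho = lr + (min_lr - lr) * (step / n_samples)
        a = edges[edge_idx[step], 0]
        b = edges[edge_idx[step], 1]
        for direction in range(2):
            src = a if direction == 0 else b
            tgt = b if direction == 0 else a
            x = u[src]
            for d in range(dim):
                dx[d] = 0.0
            # positive update
            dot = 0.0
            for d in range(dim):
                dot += x[d] * ctx[tgt, d]
            g = rho * (1.0 - 1.0 / (1.0 + np.exp(-dot)))
            for d in range(dim):
                dx[d] += g * ctx[tgt, d]
                ctx[tgt, d] += g * x[d]
            # K negative updates, applied sequentially
            for _k in range(K):
                n = -1
                for _try in range(100):
                    v = noise[noise_pos]
                    noise_pos += 1
                    if noise_pos >= n_noise:
                        noise_pos = 0
                    if v != src and v != tgt:
                        n = v
                        break
                if n < 0:
                    break
                dot = 0.0
                for d in range(dim):
                    dot += x[d] * ctx[n, d]
                g = rho * (0.0 - 1.0 / (1.0 + np.exp(-dot)))
                for d in range(dim):
                    dx[d] += g * ctx[n, d]
                    ctx[n, d] += g * x[d]
            for d in range(dim):
                x[d] += dx[d]


def train_line(
    graph: InteractionGraph,
    dim: int,
    order: Order,
    K: int = 5,
    n_samples: int | None = None,
    lr: float = 0.025,
    seed: int = 0,
) -> LineModel:
    """Train one LINE order by negative-sampled asynchronous SGD.

    Each of ``n_samples`` steps (default 200 x n_edges) draws one edge and
    updates both directions: the positive (source, target) pair plus K
    noise targets drawn from degree^(3/4) (re-drawn if a noise vertex
    equals the positive target), applied sequentially.  The learning rate
    decays linearly from ``lr`` to ``lr/100``.  Deterministic per seed.
    """
    if dim < 1 or K < 1:
        raise ValueError("dim and K must be >= 1")
    if n_samples is None:
        n_samples = 200 * graph.n_edges
    model = init_line_model(graph, dim, order, seed=seed)
    u = model.vertex_vectors
    ctx = model.context_vectors if order == "second" else u
    rng = np.random.default_rng(seed + 1)

    if n_samples == 0:
        return model
    edge_idx = graph.edge_alias.sample(rng, n_samples).astype(np.int64)
    # Presample the noise stream in bulk with slack; a noise vertex equal
    # to either endpoint of the current positive pair is re-drawn (a
    # self-pair is not a valid pair in a bipartite interaction graph).
    noise = graph.noise_alias.sample(rng, max(3 * n_samples * K, 64)).astype(np.int64)
    _sgd_kernel(
        u,
        ctx,
        graph.edges.astype(np.int64),
        edge_idx,
        noise,
        K,
        float(lr),
        float(lr / 100.0),
    )
    if not np.all(np.isfinite(u)) or (order == "second" and not np.all(np.isfinite(ctx))):
        raise DivergenceError("non-finite embedding after training")
    return model


@dataclass
class EmbeddingMatrix:
    """Behavioral vectors per vertex id, with cold-vertex flags."""

    ids: list[str]
    vectors: np.ndarray
    cold: np.ndarray  # bool per id

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.cold = np.asarray(self.cold, dtype=bool)
        if len(self.ids) != len(self.vectors) or len(self.ids) != len(self.cold):
            raise ValueError("ids, vectors and cold flags must align")
        self._index = {v: i for i, v in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, node_id: str) -> np.ndarray:
        try:
            return self.vectors[self._index[node_id]]
        except KeyError:
            raise KeyError(f"unknown id {node_id!r}") from None

    def is_cold(self, node_id: str) -> bool:
        return bool(self.cold[self._index[node_id]])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            for i, row in zip(self.ids, self.vectors):
                out.write(i + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_word2vec(cls, path: str | Path) -> "EmbeddingMatrix":
        """Import word2vec-style text (count dim header, then id + floats)."""
        ids, rows = [], []
        with open(path) as handle:
            header = handle.readline().split()
            n, dim = int(header[0]), int(header[1])
            for line in handle:
                fields = line.split()
                ids.append(fields[0])
                rows.append([float(x) for x in fields[1 : dim + 1]])
        if len(ids) != n:
            raise ValueError("word2vec header count mismatch")
        vecs = np.array(rows)
        return cls(ids=ids, vectors=vecs, cold=np.zeros(len(ids), dtype=bool))


def line_embed(
    graph: InteractionGraph,
    total_dim: int = 128,
    K: int = 5,
    samples_per_edge: int = 200,
    lr: float = 0.025,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Concatenated first- and second-order embeddings (total_dim/2 each).

    The two orders are trained independently with derived seeds.  Cold
    vertices (ids with no known edge) receive the zero vector and are
    flagged; the method cannot say anything about them from topology.
    """
    if total_dim % 2:
        raise ValueError("total_dim must be even (split across two orders)")
    half = total_dim // 2
    n_samples = samples_per_edge * graph.n_edges
    m1 = train_line(graph, half, "first", K=K, n_samples=n_samples, lr=lr, seed=seed)
    m2 = train_line(
        graph, half, "second", K=K, n_samples=n_samples, lr=lr, seed=seed + 10007
    )
    warm = np.concatenate([m1.vertex_vectors, m2.vertex_vectors], axis=1)
    ids = graph.vertex_ids + graph.cold_ids
    vectors = np.vstack([warm, np.zeros((len(graph.cold_ids), total_dim))])
    cold = np.array([False] * graph.n_vertices + [True] * len(graph.cold_ids))
    return EmbeddingMatrix(ids=ids, vectors=vectors, cold=cold)


def pair_behavior_view(emb: EmbeddingMatrix, pair: tuple[str, str]) -> np.ndarray:
    """Behavior view of one pair: [circ embedding || miRNA embedding]."""
    c, m = pair
    return np.concatenate([emb.vector(c), emb.vector(m)])
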