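"""Multi-view fusion by a nested (autoencoder-in-autoencoder) network.

Each labeled pair has two views: an attribute view (sequence-derived) and
a behavior view (graph-derived).  A per-view autoencoder of C sigmoid
layers (C/2 encoding, C/2 decoding) learns an inner code Z_mid^v for each
view, while a per-view degradation network of S sigmoid layers maps one
shared latent matrix H (k x n) onto each view's inner code.  The coupled
objective

    sum_v ||X^v - Z_C^v||_F^2 + lambda * ||Z_mid^v - G_S^v||_F^2

is minimized by alternating Adam steps on the network parameters (H
fixed) and on H (parameters fixed).  The balance weight lambda trades
per-view fidelity (complementarity) against agreement of all views with
the shared latent (consistency).  H, with samples as columns, is the
fused feature representation consumed by the downstream classifier.

Inputs must be scaled to [0,1] per coordinate (sigmoid output layers
cannot reconstruct values outside (0,1)); see :class:`MinMaxScaler`.
Test-time latents are obtained by re-minimizing the degradation term over
a new H with parameters frozen (:func:`infer_latent`), never by touching
the trained weights — this keeps cross-validation honest.  The stored
training latents are produced by that same frozen-parameter inference
after the alternating loop, so training and test features go through an
identical pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .embedder import _Adam


class MinMaxScaler:
    """Per-coordinate min-max scaling to [0,1], fit on training data only.

    Transforming new data clips into [0,1]; constant coordinates map
    to 0.5.
    """

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, float)
        self.lo = X.min(axis=1, keepdims=True)
        self.span = X.max(axis=1, keepdims=True) - self.lo
        self.flat = self.span <= 0
        self.span = np.where(self.flat, 1.0, self.span)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = (np.asarray(X, float) - self.lo) / self.span
        out = np.where(self.flat, 0.5, out)
        return np.clip(out, 0.0, 1.0)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass
class ViewSet:
    """V view matrices X^v of shape (d_v, n) sharing the sample axis."""

    X: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.X:
            raise ValueError("at least one view required")
        self.X = [np.asarray(x, float) for x in self.X]
        n = self.X[0].shape[1]
        for v, x in enumerate(self.X):
            if x.ndim != 2 or x.shape[0] < 1:
                raise ValueError(f"view {v} must be a (d_v, n) matrix")
            if x.shape[1] != n:
                raise ValueError("views disagree on sample count")
            if not np.all(np.isfinite(x)):
                raise ValueError(f"view {v} contains non-finite entries")
            if x.min() < -1e-9 or x.max() > 1 + 1e-9:
                raise ValueError(
                    f"view {v} is not scaled to [0,1]; apply MinMaxScaler first"
                )

    @property
    def n(self) -> int:
        return self.X[0].shape[1]

    @property
    def V(self) -> int:
        return len(self.X)

    @property
    def dims(self) -> list[int]:
        return [x.shape[0] for x in self.X]


@dataclass
class FusionConfig:
    """Architecture and optimizer settings for the fusion network.

    C is the per-view autoencoder depth (even; C/2 encode + C/2 decode),
    S the degradation depth, k the shared latent dimension and ``lam``
    the consistency/complementarity balance.  ``h_learning_rate`` drives
    the latent-matrix updates (both the inner alternation steps and
    frozen-parameter inference), which tolerate a larger step size than
    the weight updates.
    """

    k: int = 64
    C: int = 4
    S: int = 2
    lam: float = 1.0
    epochs: int = 200
    learning_rate: float = 1e-3
    h_learning_rate: float = 0.05
    inner_H_steps: int = 5
    infer_steps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C % 2 or self.C < 2:
            raise ValueError("C must be even and >= 2")
        if min(self.k, self.S, self.epochs, self.inner_H_steps, self.infer_steps) < 1:
            raise ValueError("k, S, epochs, inner_H_steps, infer_steps must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


class FusionDivergenceError(RuntimeError):
    pass


def _geometric_widths(d_in: int, d_out: int, n_layers: int) -> list[int]:
    """Layer widths interpolating geometrically from d_in to d_out."""
    ratio = (d_out / d_in) ** (1.0 / n_layers)
    widths = [d_in]
    for i in range(1, n_layers):
        widths.append(max(1, int(round(d_in * ratio**i))))
    widths.append(d_out)
    return widths


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class Ae2Model:
    """Trained fusion network: per-view AE and degradation weights + H."""

    config: FusionConfig
    view_dims: list[int]
    params: dict[str, np.ndarray]
    H: np.ndarray | None = None
    loss_history: list[float] = field(default_factory=list)

    def ae_layer_count(self) -> int:
        return self.config.C

    def _ae_weights(self, v: int) -> list[tuple[np.ndarray, np.ndarray]]:
        return [
            (self.params[f"ae.{v}.{c}.W"], self.params[f"ae.{v}.{c}.b"])
            for c in range(self.config.C)
        ]

    def _dr_weights(self, v: int) -> list[tuple[np.ndarray, np.ndarray]]:
        return [
            (self.params[f"dr.{v}.{s}.W"], self.params[f"dr.{v}.{s}.b"])
            for s in range(self.config.S)
        ]


def _init_model(config: FusionConfig, view_dims: Sequence[int]) -> Ae2Model:
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}
    half = config.C // 2
    for v, d in enumerate(view_dims):
        enc = _geometric_widths(d, config.k, half)
        widths = enc + enc[-2::-1]  # mirror decoder back to d
        for c in range(config.C):
            fan_in, fan_out = widths[c], widths[c + 1]
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            params[f"ae.{v}.{c}.W"] = rng.uniform(-bound, bound, (fan_out, fan_in))
            params[f"ae.{v}.{c}.b"] = np.zeros(fan_out)
        dr_widths = _geometric_widths(config.k, config.k, config.S)
        for s in range(config.S):
            fan_in, fan_out = dr_widths[s], dr_widths[s + 1]
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            params[f"dr.{v}.{s}.W"] = rng.uniform(-bound, bound, (fan_out, fan_in))
            params[f"dr.{v}.{s}.b"] = np.zeros(fan_out)
    return Ae2Model(config=config, view_dims=list(view_dims), params=params)


def _chain_forward(weights, z0):
    zs = [np.asarray(z0, float)]
    for W, b in weights:
        zs.append(_sigmoid(W @ zs[-1] + b[:, None]))
    return zs


def first_ae_forward(
    model: Ae2Model, v: int, X_v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-view autoencoder pass: (inner code Z_mid, reconstruction Z_C)."""
    X_v = np.asarray(X_v, float)
    if X_v.shape[0] != model.view_dims[v]:
        raise ValueError(
            f"view {v} expects {model.view_dims[v]} features, got {X_v.shape[0]}"
        )
    zs = _chain_forward(model._ae_weights(v), X_v)
    return zs[model.config.C // 2], zs[-1]


def degradation_forward(model: Ae2Model, v: int, H: np.ndarray) -> np.ndarray:
    """Degradation pass: map the shared latent H onto view v's inner code."""
    H = np.asarray(H, float)
    if H.shape[0] != model.config.k:
        raise ValueError(f"H must have {model.config.k} rows, got {H.shape[0]}")
    return _chain_forward(model._dr_weights(v), H)[-1]


def objective_terms(
    model: Ae2Model, views: ViewSet, H: np.ndarray | None = None
) -> tuple[float, float]:
    """(sum of reconstruction terms, sum of raw degradation terms).

    The degradation term is returned unweighted; the full objective is
    recon + lam * degradation.
    """
    H = model.H if H is None else H
    recon = deg = 0.0
    for v, X in enumerate(views.X):
        z_mid, z_c = first_ae_forward(model, v, X)
        g_s = degradation_forward(model, v, H)
        recon += float(((X - z_c) ** 2).sum())
        deg += float(((z_mid - g_s) ** 2).sum())
    return recon, deg


def ae2_objective(
    model: Ae2Model, views: ViewSet, H: np.ndarray | None = None
) -> float:
    """Coupled loss: reconstruction + lam * degradation (Frobenius)."""
    recon, deg = objective_terms(model, views, H)
    loss = recon + model.config.lam * deg
    if not np.isfinite(loss):
        raise FusionDivergenceError("non-finite fusion objective")
    return loss


def _param_and_h_grads(model: Ae2Model, views: ViewSet, H: np.ndarray):
    """Analytic gradients of the coupled objective w.r.t. params and H."""
    cfg = model.config
    half = cfg.C // 2
    grads = {k: np.zeros_like(p) for k, p in model.params.items()}
    dH = np.zeros_like(H)
    loss = 0.0
    for v, X in enumerate(views.X):
        ae_w = model._ae_weights(v)
        dr_w = model._dr_weights(v)
        zs = _chain_forward(ae_w, X)
        gs = _chain_forward(dr_w, H)
        z_mid, z_c, g_s = zs[half], zs[-1], gs[-1]
        resid = z_c - X
        deg_resid = z_mid - g_s
        loss += float((resid**2).sum() + cfg.lam * (deg_resid**2).sum())

        # back through the autoencoder chain
        delta = 2.0 * resid * z_c * (1.0 - z_c)
        for c in range(cfg.C - 1, -1, -1):
            W, _ = ae_w[c]
            grads[f"ae.{v}.{c}.W"] += delta @ zs[c].T
            grads[f"ae.{v}.{c}.b"] += delta.sum(axis=1)
            if c == 0:
                break
            dprev = W.T @ delta
            if c == half:
                dprev += 2.0 * cfg.lam * deg_resid
            delta = dprev * zs[c] * (1.0 - zs[c])

        # back through the degradation chain
        delta = 2.0 * cfg.lam * (g_s - z_mid) * g_s * (1.0 - g_s)
        for s in range(cfg.S - 1, -1, -1):
            W, _ = dr_w[s]
            grads[f"dr.{v}.{s}.W"] += delta @ gs[s].T
            grads[f"dr.{v}.{s}.b"] += delta.sum(axis=1)
            dprev = W.T @ delta
            if s == 0:
                dH += dprev
            else:
                delta = dprev * gs[s] * (1.0 - gs[s])
    return grads, dH, loss


def _h_grad(model: Ae2Model, views: ViewSet, H: np.ndarray):
    """Gradient of the degradation term (times lam) w.r.t. H alone."""
    cfg = model.config
    half = cfg.C // 2
    dH = np.zeros_like(H)
    loss = 0.0
    for v, X in enumerate(views.X):
        z_mid = _chain_forward(model._ae_weights(v), X)[half]
        dr_w = model._dr_weights(v)
        gs = _chain_forward(dr_w, H)
        g_s = gs[-1]
        loss += float(cfg.lam * ((z_mid - g_s) ** 2).sum())
        delta = 2.0 * cfg.lam * (g_s - z_mid) * g_s * (1.0 - g_s)
        for s in range(cfg.S - 1, -1, -1):
            W, _ = dr_w[s]
            dprev = W.T @ delta
            if s == 0:
                dH += dprev
            else:
                delta = dprev * gs[s] * (1.0 - gs[s])
    return dH, loss


def train_ae2(views: ViewSet, config: FusionConfig) -> Ae2Model:
    """Fit the fusion network by alternating minimization.

    Per epoch: one full-batch Adam step on all weights with H fixed, then
    ``inner_H_steps`` Adam steps on H with weights fixed.  The loss is
    recorded per epoch; non-finite loss or growth beyond 10x the initial
    value raises.  After the loop the stored H is recomputed by
    frozen-parameter inference (see module docstring).  Deterministic for
    a fixed seed.
    """
    if views.n < 2:
        raise ValueError("need at least 2 samples")
    model = _init_model(config, views.dims)
    rng = np.random.default_rng(config.seed + 1)
    H = rng.uniform(-0.01, 0.01, size=(config.k, views.n))
    opt_p = _Adam(model.params, config.learning_rate)
    h_state = {"H": H}
    opt_h = _Adam(h_state, config.h_learning_rate)
    history: list[float] = []
    initial: float | None = None
    for epoch in range(config.epochs):
        grads, dH, loss = _param_and_h_grads(model, views, h_state["H"])
        if not np.isfinite(loss):
            raise FusionDivergenceError(f"non-finite loss at epoch {epoch}")
        if initial is None:
            initial = loss
        elif loss > 10.0 * initial:
            raise FusionDivergenceError(
                f"loss grew {loss / initial:.1f}x above initial at epoch {epoch}"
            )
        history.append(loss)
        opt_p.step(model.params, grads)
        for _ in range(config.inner_H_steps):
            dH, _ = _h_grad(model, views, h_state["H"])
            opt_h.step(h_state, {"H": dH})
    model.H = _infer_H(model, views)
    history.append(ae2_objective(model, views))
    model.loss_history = history
    return model


def _infer_H(model: Ae2Model, views: ViewSet) -> np.ndarray:
    """Minimize the degradation term over H with parameters frozen.

    H starts at zero (making each latent column a pure function of its
    input column) and takes ``infer_steps`` Adam steps.
    """
    cfg = model.config
    state = {"H": np.zeros((cfg.k, views.n))}
    opt = _Adam(state, cfg.h_learning_rate)
    for _ in range(cfg.infer_steps):
        dH, _ = _h_grad(model, views, state["H"])
        opt.step(state, {"H": dH})
    return state["H"]


def infer_latent(model: Ae2Model, new_views: ViewSet) -> np.ndarray:
    """Latent matrix (k x n_new) for new samples, parameters frozen.

    Runs the same optimization that produced the stored training latents;
    inferring the training samples therefore recovers model.H.
    """
    for v, d in enumerate(new_views.dims):
        if d != model.view_dims[v]:
            raise ValueError(
                f"view {v}: expected {model.view_dims[v]} features, got {d}"
            )
    return _infer_H(model, new_views)


def fused_features(model: Ae2Model, views: ViewSet | None = None) -> np.ndarray:
    """Fused feature table (samples as rows): H^T.

    With ``views=None`` the stored training latents are returned;
    otherwise latents are inferred for the given views.
    """
    if views is None:
        if model.H is None:
            raise ValueError("model has no stored latents; pass views")
        return model.H.T.copy()
    return infer_latent(model, views).T
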