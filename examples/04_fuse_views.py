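"""Fuse two feature views of the same samples into one shared latent.

The autoencoder-in-autoencoder network reconstructs each view with its
own autoencoder while a degradation network forces one shared latent
matrix H to explain every view's inner code.
"""

import numpy as np

from cmifuse import FusionConfig, ViewSet, fused_features, infer_latent, train_ae2

rng = np.random.default_rng(0)
views = ViewSet(X=[rng.random((20, 60)), rng.random((14, 60))])

model = train_ae2(views, FusionConfig(k=8, epochs=100, seed=0))
print(f"coupled loss: {model.loss_history[0]:.1f} -> {model.loss_history[-1]:.1f}")

F = fused_features(model)
print(f"fused features: {F.shape} (samples x latent dim)")

H_new = infer_latent(model, ViewSet(X=[x[:, :5] for x in views.X]))
print(f"latents for 5 new samples: {H_new.shape}")
recovered = np.sqrt(((infer_latent(model, views) - model.H) ** 2).mean())
print(f"RMSE of re-inferred training latents: {recovered:.2e}")

# New samples never touch the trained weights: their latents come from
# optimizing H alone, the same frozen-parameter path used in training.
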