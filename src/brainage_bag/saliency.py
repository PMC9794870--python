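"""SmoothGrad input-importance maps for the trained age predictors.

SmoothGrad averages the absolute input gradient of the model output over
noise-perturbed copies of one input: ``mean_i |d f(x + eps_i) / dx|`` with
``eps_i ~ N(0, sigma^2)`` and sigma expressed as a fraction of the input's
intensity range.  For CNNs the result is a per-voxel saliency volume; for
MLPs it is a per-feature importance score, reported as a ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nn import Sequential

__all__ = ["smoothgrad", "mlp_importance"]


def smoothgrad(
    net: Sequential,
    x: np.ndarray,
    n_samples: int = 25,
    noise_frac: float = 0.10,
    seed: int = 0,
) -> np.ndarray:
    """Mean absolute input gradient over noisy copies of ``x``.

    ``x`` is a single input in the network's native space: ``(features,)``
    for an MLP, ``(D, H, W)`` or ``(D, H, W, 1)`` for a CNN.  The noise sd is
    ``noise_frac * (x.max() - x.min())``; with ``noise_frac = 0`` (or in the
    limit sigma -> 0) the map equals the plain absolute gradient.  Inference
    mode throughout: dropout off, batch-norm running statistics.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    x = np.asarray(x, float)
    squeeze_channel = False
    if x.ndim == 3:
        x = x[..., None]
        squeeze_channel = True
    rng = np.random.default_rng(seed)
    sigma = noise_frac * (x.max() - x.min())
    batch = np.repeat(x[None], n_samples, axis=0)
    if sigma > 0:
        batch = batch + rng.normal(0.0, sigma, size=batch.shape)
    out = net.forward(batch, training=False)
    grads = net.backward(np.ones_like(out))
    sal = np.abs(grads).mean(axis=0)
    return sal[..., 0] if squeeze_channel else sal


def mlp_importance(
    net: Sequential,
    x: np.ndarray,
    feature_names: list[str],
    n_samples: int = 25,
    noise_frac: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """SmoothGrad feature importance for an MLP input, sorted descending.

    Returns a DataFrame with columns ``feature`` and ``importance``; ties
    break by schema order so the ranking is deterministic.
    """
    if len(feature_names) != x.shape[-1]:
        raise ValueError("feature_names must match the input width")
    sal = smoothgrad(net, np.asarray(x, float).reshape(-1), n_samples,
                     noise_frac, seed)
    frame = pd.DataFrame({"feature": feature_names, "importance": sal})
    return (frame.sort_values("importance", ascending=False, kind="stable")
            .reset_index(drop=True))
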