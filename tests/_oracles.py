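"""Independent solver oracles shared across test modules."""

import numpy as np


def brute_force_minimum(X, y, lam, alpha, span=3.0, stages=6, grid_n=41):
    """Zooming grid search over (beta0, beta): independent solver oracle."""
    n, p = X.shape
    center = np.zeros(p + 1)
    center[0] = y.mean()
    width = span
    best = None
    for _ in range(stages):
        axes = [np.linspace(c - width, c + width, grid_n) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        b0 = mesh[0].ravel()
        betas = np.stack([m.ravel() for m in mesh[1:]], axis=1)
        resid = y[None, :] - b0[:, None] - betas @ X.T
        pen = np.sum(0.5 * (1 - alpha) * betas**2 + alpha * np.abs(betas), axis=1)
        obj = (resid**2).sum(axis=1) / (2 * n) + lam * pen
        k = int(np.argmin(obj))
        center = np.concatenate([[b0[k]], betas[k]])
        best = float(obj[k])
        width = 2.5 * width / (grid_n - 1)
    return best, center
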