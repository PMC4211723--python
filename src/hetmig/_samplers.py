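"""MCMC building blocks: adaptive random-walk Metropolis and slice sampling.

The adaptive proposal follows Haario-style covariance adaptation with a
Robbins-Monro scale tweak toward a target acceptance rate; adaptation
runs only during burn-in so the post-burn chain is a valid Metropolis
sampler.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["AdaptiveMVN", "slice_sample"]


class AdaptiveMVN:
    """Multivariate normal random-walk proposal with covariance adaptation."""

    def __init__(self, dim: int, rng: np.random.Generator, init_scale: float = 0.1,
                 target_accept: float = 0.25):
        self.dim = dim
        self.rng = rng
        self.target = target_accept
        self.log_scale = math.log(init_scale)
        self._mean = np.zeros(dim)
        self._m2 = np.eye(dim) * 1e-6
        self._count = 0
        self._chol = np.eye(dim)
        self.adapting = True

    def propose(self, x: np.ndarray) -> np.ndarray:
        step = self._chol @ self.rng.standard_normal(self.dim)
        return x + math.exp(self.log_scale) * step

    def update(self, x: np.ndarray, accepted: bool) -> None:
        if not self.adapting:
            return
        self._count += 1
        delta = x - self._mean
        self._mean += delta / self._count
        self._m2 += np.outer(delta, x - self._mean)
        # Robbins-Monro on the global scale
        gamma = 1.0 / max(10, self._count) ** 0.6
        self.log_scale += gamma * ((1.0 if accepted else 0.0) - self.target)
        if self._count >= 2 * self.dim and self._count % 50 == 0:
            cov = self._m2 / (self._count - 1)
            cov = (2.38**2 / self.dim) * cov + 1e-9 * np.eye(self.dim)
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    def freeze(self) -> None:
        self.adapting = False


def slice_sample(logf, x0: float, rng: np.random.Generator, w: float = 1.0,
                 max_steps: int = 50) -> float:
    """One update of a univariate slice sampler (stepping-out + shrinkage)."""
    f0 = logf(x0)
    if not np.isfinite(f0):
        raise ValueError("slice sampler started at zero-density point")
    logy = f0 + math.log(rng.uniform(1e-300, 1.0))
    u = rng.uniform(0.0, w)
    lo, hi = x0 - u, x0 + (w - u)
    steps = max_steps
    while steps > 0 and logf(lo) > logy:
        lo -= w
        steps -= 1
    steps = max_steps
    while steps > 0 and logf(hi) > logy:
        hi += w
        steps -= 1
    for _ in range(200):
        x1 = rng.uniform(lo, hi)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0
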