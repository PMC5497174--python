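"""Shared numerical helpers: logit transforms, RNG streams, covariance repair."""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit as _logit


def logit(p, eps: float = 0.0):
    """Log-odds transform, optionally clipping into (eps, 1-eps)."""
    p = np.asarray(p, dtype=float)
    if eps:
        p = np.clip(p, eps, 1.0 - eps)
    return _logit(p)


def invlogit(x):
    return expit(x)


def rng_for(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream derived from a top-level integer seed.

    Uses the counter-based Philox bit generator keyed on (seed, *key) so
    independent pipeline stages can draw without sharing state.
    """
    if seed is None:
        raise ValueError("seed is required")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.Generator(np.random.Philox(ss))


def nearest_psd(cov: np.ndarray, floor: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping.

    Returns (repaired matrix, was_repaired).
    """
    cov = np.asarray(cov, dtype=float)
    sym = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(sym)
    if w.min() >= 0:
        return sym, False
    w = np.clip(w, floor, None)
    return (v * w) @ v.T, True


def check_prob(p, name: str = "probability"):
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return p
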