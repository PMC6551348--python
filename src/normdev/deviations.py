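"""Normative probability maps: subject-level Z deviations with
within-subject false-discovery-rate control.

Each subject's observed value at each vertex is standardized against the
normative predictive distribution, Z = (y - yhat) / sqrt(var_latent +
noise_var), giving a map of how far the individual departs from the typical
developmental pattern. Two-sided normal p-values are thresholded by
Benjamini-Hochberg within each subject (across that subject's vertices), and
the surviving vertices keep the sign of their deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def compute_z(y, yhat, var_latent, noise_var) -> np.ndarray:
    """Standardized deviations Z = (y - yhat) / sqrt(var_latent + noise_var).

    Elementwise over subjects x vertices; scalar variances broadcast.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    var_latent = np.asarray(var_latent, dtype=float)
    noise_var = np.asarray(noise_var, dtype=float)
    if np.any(var_latent < 0):
        raise ValueError("latent predictive variance must be >= 0")
    if np.any(noise_var <= 0):
        raise ValueError("noise variance must be > 0")
    return (y - yhat) / np.sqrt(var_latent + noise_var)


def bh_fdr(p, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level ``q``.

    Accepts a 1-D p-value vector or a 2-D array (step-up applied
    independently along the last axis, i.e. per row). Returns a boolean
    array of the same shape: reject all p <= p_(i*) where
    i* = max{i : p_(i) <= (i/m) q}.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros_like(p, dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 <= q < 1:
        raise ValueError("q must lie in [0, 1)")
    one_d = p.ndim == 1
    P = p[None, :] if one_d else p
    m = P.shape[-1]
    order = np.argsort(P, axis=-1)
    p_sorted = np.take_along_axis(P, order, axis=-1)
    thresh = (np.arange(1, m + 1) / m) * q
    passed = p_sorted <= thresh
    # largest passing index per row; -1 when none pass
    idx = np.where(passed.any(axis=-1), m - 1 - np.argmax(passed[..., ::-1],
                                                          axis=-1), -1)
    cutoff = np.where(idx >= 0,
                      np.take_along_axis(p_sorted, np.maximum(idx, 0)[..., None],
                                         axis=-1)[..., 0],
                      -np.inf)
    reject = P <= cutoff[..., None]
    return reject[0] if one_d else reject


@dataclass
class NormativeProbabilityMap:
    """Per-subject vertexwise deviation maps after within-subject FDR."""

    Z: np.ndarray            # subjects x vertices
    p: np.ndarray            # subjects x vertices, two-sided
    signed_mask: np.ndarray  # subjects x vertices in {-1, 0, +1}
    q: float
    valid_vertices: np.ndarray | None = None

    def __post_init__(self) -> None:
        nz = self.signed_mask != 0
        if np.any(np.sign(self.Z[nz]) != self.signed_mask[nz]):
            raise ValueError("mask sign disagrees with Z sign")


def npm_threshold(Z, q: float = 0.05, valid_vertices=None
                  ) -> NormativeProbabilityMap:
    """Threshold Z maps by within-subject BH-FDR at level ``q``.

    Two-sided p = 2*Phi(-|Z|); BH is applied across each subject's valid
    vertices (vertices excluded from fitting do not count toward m); the
    returned mask carries the sign of Z at rejected vertices.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z must be finite")
    p = 2.0 * stats.norm.sf(np.abs(Z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    mask = np.zeros_like(Z, dtype=np.int8)
    if valid_vertices is None:
        valid = np.ones(Z.shape[1], dtype=bool)
    else:
        valid = np.zeros(Z.shape[1], dtype=bool)
        valid[np.asarray(valid_vertices, dtype=int)] = True
    if valid.any() and q > 0:
        reject = bh_fdr(p[:, valid], q)
        sub = np.zeros_like(reject, dtype=np.int8)
        sub[reject] = np.sign(Z[:, valid][reject]).astype(np.int8)
        mask[:, valid] = sub
    return NormativeProbabilityMap(Z=Z, p=p, signed_mask=mask, q=q,
                                   valid_vertices=np.flatnonzero(valid))


def npm_from_predictions(y, pred, q: float = 0.05) -> NormativeProbabilityMap:
    """Convenience route from a PredictionSet to a thresholded NPM."""
    Z = compute_z(y, pred.yhat, pred.var_latent, pred.noise_var)
    n_vert = Z.shape[1]
    valid = np.setdiff1d(np.arange(n_vert), pred.failed_vertices)
    Z = np.where(np.isfinite(Z), Z, 0.0)  # failed vertices carry NaN
    return npm_threshold(Z, q=q, valid_vertices=valid)
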