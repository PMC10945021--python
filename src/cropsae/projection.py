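"""Exact sparsity-inducing projections.

The sparse supervised autoencoder keeps its first encoder layer inside an
l1,1 ball of radius ``eta``: the sum over input genes of the l1 norm of each
gene's fan-out weight row may not exceed ``eta``.  Projecting onto this ball
after every optimizer step zeroes entire rows, which removes the
corresponding genes from the model — structured feature selection.

The bilevel operator implemented here first allocates a per-row l1 budget by
projecting the vector of row norms onto the l1 ball of radius ``eta``, then
projects each row onto the l1 ball of its allocated budget.  Rows whose
budget is zero are set exactly to zero.  This two-stage construction is fast
(sort-based, exact) and idempotent; it is not in every case identical to the
Euclidean projection onto the l1,1 ball of the flattened matrix (which
soft-thresholds individual entries and therefore does not deselect whole
rows); the bilevel form is the one with feature-selection semantics.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "project_l1_ball",
    "project_l11_bilevel",
    "selected_feature_fraction",
]

_ZERO_TOL = 1e-12


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")


def project_l1_ball(v: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection of a vector onto the l1 ball of given radius.

    Sort-based exact algorithm (Held-Wolfe-Crowder / Duchi et al.),
    O(m log m).  Returns ``v`` unchanged (copied) when it already lies
    inside the ball.

    Parameters
    ----------
    v
        Vector with finite entries.
    radius
        Ball radius, must be positive.
    """
    v = np.asarray(v, dtype=float)
    _check_finite(v, "v")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    a = np.abs(v)
    if a.sum() <= radius:
        return v.copy()
    u = np.sort(a)[::-1]
    css = np.cumsum(u)
    k = np.arange(1, u.size + 1)
    rho = k[u - (css - radius) / k > 0][-1]
    theta = (css[rho - 1] - radius) / rho
    w = np.sign(v) * np.maximum(a - theta, 0.0)
    # guard against floating-point cancellation at tiny radii: the result
    # must never leave the ball
    s = np.abs(w).sum()
    if s > radius:
        w *= radius / s
    return w


def _project_rows_l1(W: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Project each row of ``W`` onto the l1 ball of its own radius.

    Vectorized over rows; rows with radius <= 0 become exactly zero.
    """
    a = np.abs(W)
    norms = a.sum(axis=1)
    out = np.where(radii[:, None] > 0, W, 0.0).astype(float)
    need = (norms > radii) & (radii > 0)
    if not np.any(need):
        return out
    sub = a[need]
    r = radii[need]
    u = -np.sort(-sub, axis=1)
    css = np.cumsum(u, axis=1)
    k = np.arange(1, sub.shape[1] + 1)
    # the active set {j : u_j > (css_j - r)/j} is a prefix, so its size
    # equals the number of positive conditions
    rho = np.sum(u - (css - r[:, None]) / k > 0, axis=1)
    theta = (css[np.arange(sub.shape[0]), rho - 1] - r) / rho
    shrunk = np.sign(W[need]) * np.maximum(sub - theta[:, None], 0.0)
    # keep each row inside its budget despite floating-point cancellation
    sums = np.abs(shrunk).sum(axis=1)
    over = sums > r
    if np.any(over):
        shrunk[over] *= (r[over] / sums[over])[:, None]
    out[need] = shrunk
    return out


def project_l11_bilevel(W: np.ndarray, eta: float) -> np.ndarray:
    """Bilevel l1,1 projection of a feature-major weight matrix.

    Rows of ``W`` are the fan-out weights of individual input features
    (genes).  Stage 1 projects the vector of row l1 norms onto the l1 ball
    of radius ``eta``; stage 2 projects each row onto the l1 ball of its
    allocated budget.  The result satisfies ``sum_i ||W'_i||_1 <= eta`` and
    rows with zero budget are exactly zero (feature deselected).
    """
    W = np.asarray(W, dtype=float)
    _check_finite(W, "W")
    if eta <= 0:
        raise ValueError(f"eta must be positive, got {eta}")
    if W.ndim != 2:
        raise ValueError("W must be a 2-d matrix")
    t = np.abs(W).sum(axis=1)
    if t.sum() <= eta:
        return W.copy()
    t_star = project_l1_ball(t, eta)
    return _project_rows_l1(W, t_star)


def selected_feature_fraction(W: np.ndarray, tol: float = _ZERO_TOL) -> float:
    """Fraction of feature rows with nonzero l1 norm, in [0, 1]."""
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        return 0.0
    return float(np.mean(np.abs(W).sum(axis=1) > tol))
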