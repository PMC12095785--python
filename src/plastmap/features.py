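"""Node×node feature matrices: microstructure profile covariance (MPC) and
functional connectivity (FC).

MPC follows the standard intracortical-profile recipe: for each node pair, the
partial correlation of depth-wise MT intensity profiles controlling for the
cortex-wide mean profile, Fisher r-to-z transformed, negatives clipped to zero
(required for the non-negative affinity step downstream), diagonal zeroed.
FC is the plain Pearson correlation of node time series.
"""

from __future__ import annotations

import numpy as np

# keep arctanh finite for perfectly collinear (synthetic) profiles
_R_CAP = 1.0 - 1e-7


class DegenerateNodeError(ValueError):
    """A node with zero variance (constant profile / flat time series)."""


def build_mpc(profiles: np.ndarray, clip_negative: bool = True) -> np.ndarray:
    """MPC matrix from a nodes×depths profile stack.

    Parameters
    ----------
    profiles : (n_nodes, n_depths) array of MT intensities.
    clip_negative : clip negative edges to 0 after the Fisher transform
        (default on; exposed because the non-negativity requirement belongs to
        the affinity kernel, not to the covariance itself).
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[1] < 3:
        raise ValueError("profiles must be nodes×depths with >= 3 depths")
    if not np.isfinite(P).all():
        raise ValueError("profiles contain non-finite values")
    n = P.shape[0]
    mean_profile = P.mean(axis=0)
    # residualize every node profile on [1, mean_profile] across depths
    design = np.column_stack([np.ones_like(mean_profile), mean_profile])
    coef, *_ = np.linalg.lstsq(design, P.T, rcond=None)
    resid = P.T - design @ coef  # (depths, nodes)
    sd = resid.std(axis=0)
    if np.any(sd <= 1e-12):
        bad = np.flatnonzero(sd <= 1e-12)
        raise DegenerateNodeError(
            f"constant residual profile at node(s) {bad.tolist()}: "
            "zero depth variance after mean-profile control")
    R = np.corrcoef(resid.T)
    np.clip(R, -_R_CAP, _R_CAP, out=R)
    Z = np.arctanh(R)
    if clip_negative:
        np.clip(Z, 0.0, None, out=Z)
    np.fill_diagonal(Z, 0.0)
    return (Z + Z.T) / 2.0


def build_fc(timeseries: np.ndarray) -> np.ndarray:
    """Pearson-correlation FC matrix from nodes×timepoints series."""
    T = np.asarray(timeseries, dtype=float)
    if T.ndim != 2 or T.shape[1] < 3:
        raise ValueError("timeseries must be nodes×timepoints with >= 3 timepoints")
    if not np.isfinite(T).all():
        raise ValueError("timeseries contain non-finite values")
    sd = T.std(axis=1)
    if np.any(sd <= 1e-12):
        bad = np.flatnonzero(sd <= 1e-12)
        raise DegenerateNodeError(f"zero-variance time series at node(s) {bad.tolist()}")
    R = np.corrcoef(T)
    np.fill_diagonal(R, 1.0)
    return np.clip((R + R.T) / 2.0, -1.0, 1.0)


def change_map(post: np.ndarray, pre: np.ndarray) -> np.ndarray:
    """Elementwise post-minus-pre change, any matching shape."""
    post = np.asarray(post, dtype=float)
    pre = np.asarray(pre, dtype=float)
    if post.shape != pre.shape:
        raise ValueError(f"shape mismatch: {post.shape} vs {pre.shape}")
    return post - pre
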