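"""Transcriptomic association core: PLS of gene expression onto gradient-change
maps, with permutation significance, Procrustes-corrected bootstrap z-weights,
FIQT winner's-curse shrinkage, PCA denoising, and variogram-matching spatial
surrogates.

The PLS model is the standard two-block latent-variable decomposition

    X = T Pᵀ + E,    Y = U Qᵀ + F,

fit by NIPALS with deflation: components maximize the covariance between X- and
Y-scores. X is the nodes×genes expression block, Y the nodes×6 block of MPC and
FC gradient changes (G1–G3 each). Component significance is assessed by
permuting the rows of Y (jointly across columns, preserving inter-map
correlation) or by replacing Y with spatial-autocorrelation-preserving
surrogate maps; per-gene stability by bootstrap over nodes with Procrustes
correction for axis rotation/reflection across resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from statsmodels.stats.multitest import multipletests


def zscore(matrix: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Column-wise standardization (population-SD convention by default)."""
    M = np.asarray(matrix, dtype=float)
    sd = M.std(axis=0, ddof=ddof)
    if np.any(sd <= 1e-12):
        bad = np.flatnonzero(sd <= 1e-12)
        raise ValueError(f"zero-variance column(s) {bad.tolist()} cannot be z-scored")
    return (M - M.mean(axis=0)) / sd


def pca_denoise(X: np.ndarray) -> np.ndarray:
    """Regress the first principal-component score out of every gene column.

    Removes the dominant shared spatial mode (e.g. global overexpression in a
    lobe) before association analysis. Operates on column-centered data; the
    returned residuals keep the original column means removed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 nodes")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValueError("rank-0 input: no principal component to remove")
    pc1 = U[:, 0]  # unit-norm PC1 score vector over nodes
    return Xc - np.outer(pc1, pc1 @ Xc)


@dataclass
class PLSModel:
    """Fitted PLS decomposition with significance/stability annotations."""

    x_scores: np.ndarray      # T (n × l)
    y_scores: np.ndarray      # U (n × l)
    x_weights: np.ndarray     # W (m × l), the per-gene component weights
    x_loadings: np.ndarray    # P (m × l)
    y_loadings: np.ndarray    # Q (p × l)
    y_weights: np.ndarray     # C (p × l), regression weights for Y on T
    x_residual: np.ndarray    # E
    y_residual: np.ndarray    # F
    y_var_explained: np.ndarray  # per-component fraction of total Y variance
    perm_p: np.ndarray | None = None
    boot_z: np.ndarray | None = None      # (m × l)
    z_adjusted: np.ndarray | None = None  # (m × l), FIQT

    @property
    def n_components(self) -> int:
        return self.x_scores.shape[1]


def pls_fit(X: np.ndarray, Y: np.ndarray, l: int, max_iter: int = 500,
            tol: float = 1e-10) -> PLSModel:
    """NIPALS PLS regression (two-block, covariance-maximizing, with deflation).

    X and Y must be column-standardized. Per component: iterate weight/score
    updates to convergence, record scores and loadings, deflate both blocks by
    the X-score rank-1 contribution. The per-component fraction of total Y
    variance explained is ‖tᵢcᵢᵀ‖² / ‖Y‖². U and Q are defined so that
    Y = UQᵀ + F holds exactly (F is the residual of Y projected on the
    Y-scores); X = TPᵀ + E holds by deflation.
    """
    X0 = np.asarray(X, dtype=float)
    Y0 = np.asarray(Y, dtype=float)
    if Y0.ndim == 1:
        Y0 = Y0[:, None]
    if not (np.isfinite(X0).all() and np.isfinite(Y0).all()):
        raise ValueError("non-finite values in X or Y")
    n, m = X0.shape
    if Y0.shape[0] != n:
        raise ValueError("X and Y must have the same number of nodes")
    p = Y0.shape[1]
    max_rank = min(n - 1, m)
    if l < 1 or l > max_rank:
        raise ValueError(f"l={l} outside [1, min(n-1, m)={max_rank}]")

    Xd, Yd = X0.copy(), Y0.copy()
    ss_y = (Y0 ** 2).sum()
    T = np.empty((n, l)); Uc = np.empty((n, l))
    W = np.empty((m, l)); P = np.empty((m, l)); C = np.empty((p, l))
    varexp = np.empty(l)
    for comp in range(l):
        # start from the strongest remaining Y column
        u = Yd[:, np.argmax((Yd ** 2).sum(axis=0))].copy()
        if (u ** 2).sum() <= 1e-14 * max(1.0, ss_y):
            raise ValueError(f"Y block exhausted before component {comp + 1}: "
                             "l exceeds the effective rank")
        w = np.zeros(m)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            nw = np.linalg.norm(w_new)
            if nw <= 1e-14:
                raise ValueError(f"X block exhausted at component {comp + 1}")
            w_new /= nw
            t = Xd @ w_new
            c = Yd.T @ t / (t @ t)
            u = Yd @ c / (c @ c)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = Xd @ w
        tt = t @ t
        c = Yd.T @ t / tt
        p_load = Xd.T @ t / tt
        # deterministic sign: strongest gene weight positive
        if w[np.argmax(np.abs(w))] < 0:
            w, t, c, p_load, u = -w, -t, -c, -p_load, -u
        T[:, comp], Uc[:, comp] = t, u
        W[:, comp], P[:, comp], C[:, comp] = w, p_load, c
        varexp[comp] = tt * (c @ c) / ss_y
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, c)
    E = X0 - T @ P.T
    # Q: regression loadings of the original Y on the Y-scores, so Y = UQᵀ + F
    Q = np.linalg.lstsq(Uc, Y0, rcond=None)[0].T
    F = Y0 - Uc @ Q.T
    return PLSModel(x_scores=T, y_scores=Uc, x_weights=W, x_loadings=P,
                    y_loadings=Q, y_weights=C, x_residual=E, y_residual=F,
                    y_var_explained=varexp)


def pls_perm_test(X: np.ndarray, Y: np.ndarray, l: int, n_perm: int = 1000,
                  seed: int = 0, surrogates: np.ndarray | None = None) -> np.ndarray:
    """Per-component permutation p for Y-variance explained.

    Null draws permute the rows of Y jointly; if ``surrogates`` is given
    (shape (n_null, n_nodes, n_ycols), e.g. stacked variogram-matching
    surrogate maps), each null uses one surrogate response block instead.
    Add-one convention: p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    obs = pls_fit(X, Y, l).y_var_explained
    rng = np.random.default_rng(seed)
    if surrogates is not None:
        surrogates = np.asarray(surrogates, dtype=float)
        if surrogates.ndim != 3 or surrogates.shape[1:] != Y.shape:
            raise ValueError(
                f"surrogates must have shape (n_null, {Y.shape[0]}, {Y.shape[1]})")
        if surrogates.shape[0] < n_perm:
            raise ValueError("fewer surrogates than requested permutations")
    count = np.zeros(l)
    for i in range(n_perm):
        if surrogates is None:
            Ynull = Y[rng.permutation(Y.shape[0])]
        else:
            Ynull = zscore(surrogates[i])
        count += pls_fit(X, Ynull, l).y_var_explained >= obs
    return (1 + count) / (1 + n_perm)


def pls_bootstrap_z(X: np.ndarray, Y: np.ndarray, l: int, n_boot: int = 1000,
                    seed: int = 0, max_retries: int = 50,
                    procrustes: bool = True) -> np.ndarray:
    """Bootstrap z-scores of per-gene PLS weights, Procrustes-corrected.

    Nodes (rows) are resampled with replacement; each bootstrap refit's gene
    weight matrix is rotated/reflected onto the observed one before pooling,
    removing arbitrary axis flips and rotations across resamples (set
    ``procrustes=False`` to skip the correction). Returns
    z = observed weight / SD of rotated bootstrap weights, shape (genes, l).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    obs = pls_fit(X, Y, l)
    W_obs = obs.x_weights
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(W_obs)
    acc2 = np.zeros_like(W_obs)
    done = 0
    retries = 0
    while done < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            Wb = pls_fit(zscore(X[idx]), zscore(Y[idx]), l).x_weights
        except ValueError:
            retries += 1
            if retries > max_retries:
                raise ValueError("too many rank-deficient bootstrap samples")
            continue
        if procrustes:
            R, _ = orthogonal_procrustes(Wb, W_obs)
            Wr = Wb @ R
        else:
            Wr = Wb
        acc += Wr
        acc2 += Wr ** 2
        done += 1
    sd = np.sqrt(np.maximum(acc2 / n_boot - (acc / n_boot) ** 2, 0.0))
    return np.where(sd > 1e-12, W_obs / np.where(sd > 1e-12, sd, 1.0), 0.0)


def fiqt_adjust(z: np.ndarray) -> np.ndarray:
    """FDR inverse quantile transformation: shrink z-scores for winner's curse.

    Two-sided p-values from |z| are Benjamini–Hochberg adjusted and mapped back
    to the z scale with the original signs; |adjusted z| <= |z| always.
    """
    z = np.asarray(z, dtype=float)
    flat = z.ravel()
    if not np.isfinite(flat).all():
        raise ValueError("non-finite z-scores")
    p = 2.0 * stats.norm.sf(np.abs(flat))
    p_adj = multipletests(p, method="fdr_bh")[1]
    z_adj = np.sign(flat) * stats.norm.isf(np.minimum(p_adj, 1.0) / 2.0)
    z_adj = np.sign(flat) * np.minimum(np.abs(z_adj), np.abs(flat))
    return z_adj.reshape(z.shape)


def significant_genes(z_adjusted: np.ndarray, threshold: float = 1.96) -> np.ndarray:
    """Boolean mask of genes with |adjusted z| above threshold (per column)."""
    return np.abs(np.asarray(z_adjusted, dtype=float)) > threshold


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Spatial-autocorrelation-preserving null maps for one source map."""

    maps: np.ndarray  # (n_surrogates, n_nodes)
    source: np.ndarray
    metadata: dict = field(default_factory=dict)


def variogram(values: np.ndarray, coordinates: np.ndarray,
              n_bins: int = 10, max_frac: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Empirical semivariogram over quantile distance bins.

    Pairs farther apart than ``max_frac`` of the maximum distance are dropped
    (the usual geostatistical practice: the variogram is unreliable at ranges
    approaching the domain size). Returns (bin mean distance, gamma),
    gamma(h) = ½·mean[(xᵢ−xⱼ)²] per bin.
    """
    v = np.asarray(values, dtype=float)
    coords = np.asarray(coordinates, dtype=float)
    iu, ju = np.triu_indices(v.size, k=1)
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    if d.max() <= 0:
        raise ValueError("degenerate geometry: all nodes coincide")
    keep = d <= max_frac * d.max()
    iu, ju, d = iu[keep], ju[keep], d[keep]
    edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    sq = 0.5 * (v[iu] - v[ju]) ** 2
    counts = np.bincount(bin_idx, minlength=n_bins)
    gamma = np.bincount(bin_idx, weights=sq, minlength=n_bins) / np.maximum(counts, 1)
    h = np.bincount(bin_idx, weights=d, minlength=n_bins) / np.maximum(counts, 1)
    return h, gamma


def make_surrogates(source_map: np.ndarray, coordinates: np.ndarray, n: int,
                    seed: int = 0, n_bins: int = 10,
                    candidate_lengths: np.ndarray | None = None) -> SurrogateEnsemble:
    """Variogram-matching surrogate maps (geometry-agnostic spatial nulls).

    Each surrogate permutes the source values, smooths the permutation with a
    Gaussian distance kernel and re-injects a fraction of unsmoothed
    permutation noise; the (length scale, noise fraction) pair is chosen per
    surrogate from a candidate grid to best match the source variogram. The
    field is then rank-remapped onto the exact source value multiset —
    preserving the value histogram and, approximately, the spatial
    autocorrelation.
    """
    v = np.asarray(source_map, dtype=float)
    coords = np.asarray(coordinates, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if v.ndim != 1 or coords.shape[0] != v.size:
        raise ValueError("source map and coordinates must cover the same nodes")
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    dmax = D.max()
    if dmax <= 0:
        raise ValueError("degenerate geometry: all nodes coincide")
    if candidate_lengths is None:
        candidate_lengths = np.geomspace(0.02, 1.0, 10) * dmax
    noise_fracs = np.array([0.0, 0.05, 0.1, 0.15, 0.25, 0.4])
    kernels = [np.exp(-(D ** 2) / (2.0 * ell ** 2)) for ell in candidate_lengths]
    kernels = [K / K.sum(axis=1, keepdims=True) for K in kernels]

    # precompute pair/bin structure shared by every candidate variogram
    iu, ju = np.triu_indices(v.size, k=1)
    dpair = D[iu, ju]
    keep = dpair <= 0.5 * dmax
    iu, ju, dpair = iu[keep], ju[keep], dpair[keep]
    edges = np.quantile(dpair, np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges, dpair, side="right") - 1, 0, n_bins - 1)
    counts = np.maximum(np.bincount(bin_idx, minlength=n_bins), 1)

    def fast_gamma(fields: np.ndarray) -> np.ndarray:
        """Variograms for a (k, n_nodes) batch over the precomputed bins."""
        sq = 0.5 * (fields[:, iu] - fields[:, ju]) ** 2
        return np.stack([np.bincount(bin_idx, weights=row, minlength=n_bins)
                         for row in sq]) / counts

    gamma_src = fast_gamma(v[None, :])[0]
    src_sorted = np.sort(v)
    rng = np.random.default_rng(seed)
    out = np.empty((n, v.size))
    chosen = np.empty((n, 2))
    for i in range(n):
        perm = rng.permutation(v)
        permz = (perm - perm.mean()) / max(perm.std(), 1e-12)
        best, best_err, best_par = None, np.inf, (np.nan, np.nan)
        for ell, K in zip(candidate_lengths, kernels):
            smooth = K @ perm
            smoothz = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
            fields = ((1.0 - noise_fracs)[:, None] * smoothz[None, :]
                      + noise_fracs[:, None] * permz[None, :])
            cands = np.empty_like(fields)
            ranks = np.argsort(fields, axis=1, kind="stable")
            for r, cand_row in zip(ranks, cands):
                cand_row[r] = src_sorted  # rank remap onto the source multiset
            gammas = fast_gamma(cands)
            errs = np.nanmean(np.abs(gammas - gamma_src)
                              / np.maximum(gamma_src, 1e-12), axis=1)
            j = int(np.argmin(errs))
            if errs[j] < best_err:
                best, best_err, best_par = cands[j].copy(), errs[j], (ell, noise_fracs[j])
        out[i] = best
        chosen[i] = best_par
    return SurrogateEnsemble(
        maps=out, source=v.copy(),
        metadata={"method": "variogram-matching rank remap",
                  "n_bins": n_bins, "seed": seed,
                  "chosen_lengths": chosen[:, 0].tolist(),
                  "chosen_noise_fracs": chosen[:, 1].tolist()})
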