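"""Gradient embedding and network dispersion.

Feature matrices (MPC/FC) are sparsified row-wise, converted to a
normalized-angle affinity, and embedded with diffusion maps. Per-subject,
per-session embeddings are Procrustes-aligned to a group template built from
the grand-average feature matrix, so that dispersion statistics are comparable
across subjects and sessions.

Dispersion lives in the space of the first three gradients (G1–G3):
within-network dispersion is the *sum* of squared Euclidean distances of a
network's nodes to their centroid (a segregation measure that scales with
network size, by definition); between-network dispersion is the Euclidean
distance between two network centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

MEASURES = ("VN-within", "FPN-within", "VN-FPN-between")


@dataclass(frozen=True)
class GradientSet:
    """Low-dimensional embedding of a node similarity matrix."""

    components: np.ndarray  # (n_nodes, k), columns G1..Gk
    eigenvalues: np.ndarray  # (k,), nonincreasing
    aligned_to: str | None = None

    @property
    def k(self) -> int:
        return self.components.shape[1]


def build_affinity(feature: np.ndarray, sparsity_q: float = 0.9) -> np.ndarray:
    """Row-sparsified normalized-angle affinity.

    Each row keeps its top ``ceil((1 - sparsity_q) * n)`` entries (the top 10%
    at the default sparsity 0.9) and zeroes the rest; affinity between nodes i
    and j is 1 − θ/π with θ the angle between their thresholded rows. The
    result is symmetrized by averaging.
    """
    F = np.asarray(feature, dtype=float)
    if F.ndim != 2 or F.shape[0] != F.shape[1]:
        raise ValueError("feature matrix must be square")
    if not np.allclose(F, F.T, atol=1e-8):
        raise ValueError("feature matrix must be symmetric")
    if not 0.0 < sparsity_q < 1.0:
        raise ValueError("sparsity_q must be in (0, 1)")
    n = F.shape[0]
    keep = math.ceil((1.0 - sparsity_q) * n)
    thresh = np.zeros_like(F)
    order = np.argsort(F, axis=1, kind="stable")  # ascending
    rows = np.arange(n)[:, None]
    top = order[:, n - keep:]
    thresh[rows, top] = F[rows, top]
    norms = np.linalg.norm(thresh, axis=1)
    if np.any(norms <= 1e-12):
        bad = np.flatnonzero(norms <= 1e-12)
        raise ValueError(f"all-zero thresholded row(s) {bad.tolist()}: angle undefined")
    cos = (thresh @ thresh.T) / np.outer(norms, norms)
    np.clip(cos, -1.0, 1.0, out=cos)
    A = 1.0 - np.arccos(cos) / np.pi
    return (A + A.T) / 2.0


def diffusion_embed(affinity: np.ndarray, k: int = 10, alpha: float = 0.5,
                    t: float = 0.0) -> GradientSet:
    """Diffusion-map embedding of a nonnegative affinity matrix.

    Density normalization with exponent ``alpha`` (0.5 by default), then the
    spectral decomposition of the Markov transition matrix via its symmetric
    conjugate. The trivial constant eigenvector is dropped. Components are
    scaled by λ^t for diffusion time t > 0, or by λ/(1−λ) at t = 0 (the
    multiscale convention). Columns are ordered by nonincreasing eigenvalue.
    """
    W = np.asarray(affinity, dtype=float)
    n = W.shape[0]
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("affinity must be square")
    if np.any(W < 0):
        raise ValueError("affinity must be nonnegative")
    if k >= n:
        raise ValueError(f"k={k} must be < n_nodes={n}")
    n_comp, comp_labels = connected_components(W > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp_labels)
        raise ValueError(
            f"affinity graph is disconnected: {n_comp} components of sizes {sizes.tolist()}")
    d = W.sum(axis=1)
    if alpha != 0.0:
        inv_da = d ** (-alpha)
        W = W * np.outer(inv_da, inv_da)
        d = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    S = W * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)
    idx = np.argsort(evals)[::-1][: k + 1]
    evals, evecs = evals[idx], evecs[:, idx]
    psi = evecs * inv_sqrt[:, None]
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    lam = np.clip(evals[1:], None, 1.0 - 1e-12)  # drop the trivial λ=1
    comps = psi[:, 1:]
    scale = lam ** t if t > 0 else lam / (1.0 - lam)
    comps = comps * scale[None, :]
    # deterministic sign: largest-magnitude coordinate positive
    for j in range(comps.shape[1]):
        i = np.argmax(np.abs(comps[:, j]))
        if comps[i, j] < 0:
            comps[:, j] = -comps[:, j]
    return GradientSet(components=comps, eigenvalues=lam, aligned_to=None)


def procrustes_align(source: GradientSet, reference: GradientSet,
                     reference_id: str = "reference") -> GradientSet:
    """Rotate/reflect source components onto the reference (no scaling)."""
    if source.components.shape != reference.components.shape:
        raise ValueError(
            f"shape mismatch: source {source.components.shape} vs "
            f"reference {reference.components.shape}")
    Q, _ = orthogonal_procrustes(source.components, reference.components)
    return replace(source, components=source.components @ Q, aligned_to=reference_id)


def within_dispersion(grads: GradientSet, member_nodes: Sequence[int]) -> float:
    """Sum of squared distances of member nodes to their centroid in G1–G3."""
    members = np.asarray(member_nodes, dtype=int)
    if members.size < 2:
        raise ValueError("within-network dispersion needs >= 2 member nodes")
    if grads.k < 3:
        raise ValueError("dispersion space requires >= 3 gradients")
    pts = grads.components[members, :3]
    centroid = pts.mean(axis=0)
    return float(((pts - centroid) ** 2).sum())


def between_dispersion(grads: GradientSet, nodes_a: Sequence[int],
                       nodes_b: Sequence[int]) -> float:
    """Euclidean distance between two network centroids in G1–G3."""
    a = np.asarray(nodes_a, dtype=int)
    b = np.asarray(nodes_b, dtype=int)
    if a.size < 1 or b.size < 1:
        raise ValueError("between-network dispersion needs nonempty node sets")
    if grads.k < 3:
        raise ValueError("dispersion space requires >= 3 gradients")
    ca = grads.components[a, :3].mean(axis=0)
    cb = grads.components[b, :3].mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def normalize_to_control(values: np.ndarray, control_values: np.ndarray) -> np.ndarray:
    """Subtract the control-group mean from each value (sham normalization)."""
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    return np.asarray(values, dtype=float) - control.mean()


def _measure_values(grads: GradientSet, vn: np.ndarray, fpn: np.ndarray) -> dict[str, float]:
    return {
        "VN-within": within_dispersion(grads, vn),
        "FPN-within": within_dispersion(grads, fpn),
        "VN-FPN-between": between_dispersion(grads, vn, fpn),
    }


def dispersion_pipeline(
    feature_matrices: Mapping[tuple[int, str, str], np.ndarray],
    partition: Sequence[str],
    sparsity_q: float = 0.9,
    k: int = 10,
    alpha: float = 0.5,
    t: float = 0.0,
) -> tuple[pd.DataFrame, dict[tuple[int, str, str], GradientSet]]:
    """Dispersion statistics for every subject/session/modality.

    Parameters
    ----------
    feature_matrices : mapping (subject, session, modality) -> nodes×nodes
        feature matrix, modality in {"MPC", "FC"}.
    partition : per-node network labels (must contain "VN" and "FPN").

    Returns
    -------
    table : tidy DataFrame with columns (subject, session, modality, measure,
        value), including post−pre change rows (session "post-pre") and, when a
        baseline session is present, pre−baseline rows (session "pre-baseline").
    gradients : per-key aligned :class:`GradientSet` (plus group templates
        under subject −1, session "template").
    """
    labels = np.asarray(partition)
    vn = np.flatnonzero(labels == "VN")
    fpn = np.flatnonzero(labels == "FPN")
    if vn.size < 2 or fpn.size < 2:
        raise ValueError("partition must contain >= 2 VN and >= 2 FPN nodes")

    modalities = sorted({key[2] for key in feature_matrices})
    templates: dict[str, GradientSet] = {}
    for mod in modalities:
        mats = [m for key, m in feature_matrices.items() if key[2] == mod]
        grand = np.mean(mats, axis=0)
        templates[mod] = diffusion_embed(build_affinity(grand, sparsity_q), k, alpha, t)

    grads: dict[tuple[int, str, str], GradientSet] = {}
    rows = []
    for (subject, session, mod), mat in sorted(feature_matrices.items()):
        try:
            g = diffusion_embed(build_affinity(mat, sparsity_q), k, alpha, t)
            g = procrustes_align(g, templates[mod], reference_id=f"group-{mod}")
        except ValueError as err:
            raise ValueError(
                f"subject {subject}, session {session}, modality {mod}: {err}") from err
        grads[(subject, session, mod)] = g
        for meas, val in _measure_values(g, vn, fpn).items():
            rows.append((subject, session, mod, meas, val))
    for mod in modalities:
        grads[(-1, "template", mod)] = templates[mod]

    table = pd.DataFrame(rows, columns=["subject", "session", "modality", "measure", "value"])
    wide = table.pivot_table(index=["subject", "modality", "measure"],
                             columns="session", values="value")
    change_rows = []
    for (subject, mod, meas), r in wide.iterrows():
        if {"post", "pre"} <= set(r.index) and r[["post", "pre"]].notna().all():
            change_rows.append((subject, "post-pre", mod, meas, r["post"] - r["pre"]))
        if {"pre", "baseline"} <= set(r.index) and r[["pre", "baseline"]].notna().all():
            change_rows.append((subject, "pre-baseline", mod, meas, r["pre"] - r["baseline"]))
    if change_rows:
        table = pd.concat(
            [table, pd.DataFrame(change_rows, columns=table.columns)], ignore_index=True)
    return table, grads


def dispersion_wide(table: pd.DataFrame, session: str, modality: str) -> pd.DataFrame:
    """Subjects × measures slice of a dispersion table (sorted by subject)."""
    sub = table[(table.session == session) & (table.modality == modality)]
    wide = sub.pivot_table(index="subject", columns="measure", values="value")
    return wide[list(MEASURES)].sort_index()
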