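"""Synthetic data with the statistical structure the analysis assumes.

Generates every pipeline input — node geometry on a smooth cortical-sheet
surrogate, spatially autocorrelated gene-expression maps, depth-resolved
microstructure (MT) profiles, resting-state node time series, and log-curve
learning behavior — with *planted* ground truth: a set of driver genes tracking
a phenotype map, a post-training microstructural perturbation of the visual
(VN) and fronto-parietal (FPN) networks, a post-training widening of FPN
within-network functional covariance, and a behavior slope coupled to the same
per-subject effect. Every draw is a deterministic function of the config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io

NETWORKS = ("VN", "FPN", "other1", "other2", "other3", "other4", "other5")

#: sessions by count; >=3 gives an untrained baseline for specificity analyses
_SESSION_LABELS = {2: ("pre", "post"), 3: ("baseline", "pre", "post")}

# internal scale of planted brain effects per unit subject effect
_PROFILE_EFFECT_SCALE = 0.6
_FC_EFFECT_SCALE = 0.4
# baseline node-coherence heterogeneity that the planted effects modulate
_PROFILE_BASE_HETERO = 0.7
_FC_BASE_HETERO = 0.4
# FPN profile perturbation relative to VN (VN is the dominant MPC plant)
_PROFILE_FPN_FRACTION = 0.5


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named deterministic stream derived from the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate the multi-session training design: 20-ish subjects,
    three scan sessions (baseline / pre / post), 200 left-hemisphere nodes.
    ``n_genes`` defaults to the full atlas-scale 16651 but is reducible.
    """

    n_subjects: int = 20
    n_sessions: int = 3
    n_nodes: int = 200
    n_genes: int = 16651
    n_depths: int = 10
    n_timepoints: int = 250
    spatial_corr_length: float = 0.005
    planted_genes: tuple[int, ...] = ()
    planted_effect_size: float = 3.0
    dispersion_behavior_coupling: float = 1.2
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_sessions not in _SESSION_LABELS:
            raise ValueError("n_sessions must be 2 (pre/post) or 3 (baseline/pre/post)")
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if self.n_genes < max(1, len(self.planted_genes)):
            raise ValueError("n_genes must cover the planted gene set")
        if any(g < 0 or g >= self.n_genes for g in self.planted_genes):
            raise ValueError("planted gene index out of range")
        if self.n_depths < 3:
            raise ValueError("n_depths must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.spatial_corr_length <= 0:
            raise ValueError("spatial_corr_length must be positive")

    @property
    def sessions(self) -> tuple[str, ...]:
        return _SESSION_LABELS[self.n_sessions]


@dataclass(frozen=True)
class NodeGeometry:
    """Node centroids on a smooth 2-D sheet in 3-D plus a 7-network partition."""

    coordinates: np.ndarray  # (n_nodes, 3)
    network_labels: tuple[str, ...]  # one of NETWORKS per node

    def members(self, network: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.network_labels) == network)


def gen_geometry(cfg: SynthConfig) -> NodeGeometry:
    """Sample node centroids on a gently curved sheet; label 7 contiguous patches.

    Networks are angular wedges around the sheet center, so each patch is
    spatially contiguous; VN and FPN are placed in non-adjacent wedges.
    """
    if cfg.n_nodes < 3 * len(NETWORKS):
        raise ValueError(
            f"n_nodes={cfg.n_nodes} too small to allocate {len(NETWORKS)} networks "
            "with >= 3 nodes each")
    rng = _rng(cfg.seed, "geometry")
    uv = rng.uniform(0.0, 1.0, size=(cfg.n_nodes, 2))
    z = 0.15 * np.sin(np.pi * uv[:, 0]) * np.cos(np.pi * uv[:, 1])
    coords = np.column_stack([uv, z])

    theta = np.arctan2(uv[:, 1] - 0.5, uv[:, 0] - 0.5)
    order = np.argsort(theta, kind="stable")
    # near-equal contiguous arcs; VN and FPN separated by two wedges
    splits = np.array_split(order, len(NETWORKS))
    wedge_names = ("VN", "other1", "other2", "FPN", "other3", "other4", "other5")
    labels = np.empty(cfg.n_nodes, dtype=object)
    for wedge, idx in enumerate(splits):
        labels[idx] = wedge_names[wedge]
    return NodeGeometry(coordinates=coords, network_labels=tuple(labels))


def _sq_exp_cov(coords: np.ndarray, length: float) -> np.ndarray:
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * length ** 2))


def gen_expression(cfg: SynthConfig, geom: NodeGeometry,
                   phenotype_map: np.ndarray) -> np.ndarray:
    """nodes × genes matrix of smooth Gaussian random fields.

    Each gene is a draw from a zero-mean Gaussian process with a
    squared-exponential kernel over node coordinates (length scale
    ``spatial_corr_length``) plus iid noise; planted genes additionally carry
    ``planted_effect_size`` × standardized phenotype_map.
    """
    phenotype_map = np.asarray(phenotype_map, dtype=float)
    if phenotype_map.shape != (cfg.n_nodes,):
        raise ValueError("phenotype_map length must equal n_nodes")
    rng = _rng(cfg.seed, "expression")
    K = _sq_exp_cov(geom.coordinates, cfg.spatial_corr_length)
    L = np.linalg.cholesky(K + 1e-8 * np.eye(cfg.n_nodes))
    X = L @ rng.standard_normal((cfg.n_nodes, cfg.n_genes))
    X += cfg.noise_sd * rng.standard_normal(X.shape)
    if cfg.planted_genes:
        ph = phenotype_map - phenotype_map.mean()
        sd = ph.std()
        if sd > 0:
            ph = ph / sd
        X[:, list(cfg.planted_genes)] += cfg.planted_effect_size * ph[:, None]
    return X


def _depth_templates(cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Smooth per-network mean MT depth profile (arbitrary intensity units)."""
    rng = _rng(cfg.seed, "profile-templates")
    x = np.linspace(0.0, 1.0, cfg.n_depths)
    templates = {}
    for net in NETWORKS:
        a, b = rng.uniform(0.4, 1.4), rng.uniform(-0.8, 0.8)
        templates[net] = 1.5 + a * x + b * x ** 2
    return templates


def gen_profiles(cfg: SynthConfig, geom: NodeGeometry,
                 subject_effects: np.ndarray) -> dict[str, np.ndarray]:
    """Per-session stacks of MT depth profiles, shape (subjects, nodes, depths).

    Each node's multiplicative depth-shape perturbation mixes a shared
    network direction with a node-specific idiosyncratic direction in a
    4-function smooth depth basis; the mixing weight κ controls within-network
    profile coherence. VN/FPN nodes carry baseline heterogeneity κ = h·g_i
    (per-node gains g_i); in the post-training session the heterogeneity is
    shifted to (h + scale·effect_s)·g_i, so within-network decoherence — and
    hence downstream MPC gradient dispersion — is a monotone, deterministic
    function of the subject effect: the planted microstructural change. The
    FPN perturbation runs at half the VN gain, making VN the dominant
    microstructural plant.
    """
    subject_effects = np.asarray(subject_effects, dtype=float)
    if subject_effects.shape != (cfg.n_subjects,):
        raise ValueError("subject_effects must have one entry per subject")
    if cfg.n_sessions < 2:
        raise ValueError("need at least 2 sessions (pre/post)")
    rng = _rng(cfg.seed, "profiles")
    x = np.linspace(0.0, 1.0, cfg.n_depths)
    B = np.column_stack([x, x ** 2, np.sin(np.pi * x), np.sin(2 * np.pi * x)])
    templates = _depth_templates(cfg)
    labels = np.asarray(geom.network_labels)
    base = np.stack([templates[l] for l in labels])  # (nodes, depths)
    common = {}
    for net in NETWORKS:
        v = rng.standard_normal(B.shape[1])
        common[net] = v / np.linalg.norm(v)
    idio = rng.standard_normal((cfg.n_nodes, B.shape[1]))
    idio /= np.linalg.norm(idio, axis=1, keepdims=True)
    gains = rng.uniform(0.5, 1.0, cfg.n_nodes)
    gains[geom.members("FPN")] *= _PROFILE_FPN_FRACTION
    planted = np.isin(np.arange(cfg.n_nodes),
                      np.concatenate([geom.members("VN"), geom.members("FPN")]))
    C = np.stack([common[l] for l in labels])  # (nodes, basis)

    out: dict[str, np.ndarray] = {}
    h = _PROFILE_BASE_HETERO
    for sess in cfg.sessions:
        if sess == "post":
            kap = (h + np.clip(_PROFILE_EFFECT_SCALE * subject_effects,
                               -0.6, 2.5))[:, None] * gains[None, :]
            kap = np.where(planted[None, :], kap, h * gains[None, :])
        else:
            kap = np.broadcast_to(h * gains[None, :],
                                  (cfg.n_subjects, cfg.n_nodes)).copy()
        coefs = C[None, :, :] + kap[:, :, None] * idio[None, :, :]
        stack = base[None, :, :] * (1.0 + 0.25 * np.einsum("dk,snk->snd", B, coefs))
        stack = stack + cfg.noise_sd * 0.1 * rng.standard_normal(stack.shape)
        out[sess] = stack
    return out


def _session_correlation(cfg: SynthConfig, geom: NodeGeometry, effect: float,
                         fpn_gains: np.ndarray) -> np.ndarray:
    """Block correlation with node-coherence scaling of FPN nodes.

    VN/FPN have strong within-network correlation (0.5) so their structure
    dominates the leading gradients; other networks 0.25; between 0.10.
    FPN node i couples to everything through a coherence factor
    s_i = 1 − h·g_i with heterogeneity h = base + scale·effect: larger effect
    → more heterogeneous FPN → wider within-FPN covariance spread. The
    construction R_ij = s_i s_j S_ij (diag 1) is positive semidefinite for
    s ∈ [0, 1] by the factor-model identity R = DSD + (I − D²).
    """
    rho_b = 0.10
    labels = np.asarray(geom.network_labels)
    rho_net = np.where(np.isin(labels, ("VN", "FPN")), 0.5, 0.25)
    same_net = labels[:, None] == labels[None, :]
    S = np.where(same_net, np.minimum(rho_net[:, None], rho_net[None, :]), rho_b)
    h = float(np.clip(_FC_BASE_HETERO + _FC_EFFECT_SCALE * effect, 0.05, 0.95))
    s = np.ones(cfg.n_nodes)
    fpn = geom.members("FPN")
    s_fpn = 1.0 - h * fpn_gains
    # preserve the mean FPN coupling across effect levels so the planted
    # change widens the within-FPN spread without moving the FPN centroid
    base = 1.0 - _FC_BASE_HETERO * fpn_gains
    s[fpn] = np.minimum(s_fpn * (base.mean() / s_fpn.mean()), 1.0)
    R = np.outer(s, s) * S
    np.fill_diagonal(R, 1.0)
    return R


def _safe_cholesky(R: np.ndarray) -> np.ndarray:
    jitter = 1e-8
    for _ in range(12):
        try:
            return np.linalg.cholesky(R + jitter * np.eye(R.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError("covariance could not be made positive definite")


def gen_timeseries(cfg: SynthConfig, geom: NodeGeometry,
                   subject_effects: np.ndarray) -> dict[str, np.ndarray]:
    """Per-session resting time series, shape (subjects, nodes, timepoints).

    Multivariate Gaussian draws from a block correlation (within-network 0.5
    for VN/FPN, 0.25 elsewhere, 0.10 between networks). FPN nodes carry a
    fixed coherence heterogeneity; post-training it is increased in proportion
    to the subject effect, widening the within-FPN covariance spread (the
    planted FC-dispersion change, monotone in the effect).
    """
    subject_effects = np.asarray(subject_effects, dtype=float)
    if subject_effects.shape != (cfg.n_subjects,):
        raise ValueError("subject_effects must have one entry per subject")
    if cfg.n_timepoints <= cfg.n_nodes / 4:
        raise ValueError("n_timepoints must exceed n_nodes/4 for stable correlations")
    rng = _rng(cfg.seed, "timeseries")
    fpn = geom.members("FPN")
    fpn_gains = _rng(cfg.seed, "fc-gains").uniform(0.3, 1.0, size=fpn.size)
    out: dict[str, np.ndarray] = {}
    for sess in cfg.sessions:
        stack = np.empty((cfg.n_subjects, cfg.n_nodes, cfg.n_timepoints))
        for s in range(cfg.n_subjects):
            eff = subject_effects[s] if sess == "post" else 0.0
            L = _safe_cholesky(_session_correlation(cfg, geom, eff, fpn_gains))
            stack[s] = L @ rng.standard_normal((cfg.n_nodes, cfg.n_timepoints))
        out[sess] = stack
    return out


def gen_behavior(cfg: SynthConfig, subject_effects: np.ndarray,
                 n_training_sessions: int = 3,
                 intercept: float = 50.0, slope: float = 8.0,
                 noise_sd: float | None = None) -> np.ndarray:
    """Training accuracies (%), shape (subjects, training sessions).

    accuracy(t) = a_s + b_s·ln(t) + noise, clipped to [0, 100], with
    b_s = slope + dispersion_behavior_coupling × subject_effect_s.
    """
    subject_effects = np.asarray(subject_effects, dtype=float)
    if subject_effects.shape != (cfg.n_subjects,):
        raise ValueError("subject_effects must have one entry per subject")
    if n_training_sessions < 3:
        raise ValueError("need >= 3 training sessions to identify a log slope")
    if noise_sd is None:
        noise_sd = cfg.noise_sd
    rng = _rng(cfg.seed, "behavior")
    t = np.arange(1, n_training_sessions + 1)
    b = slope + cfg.dispersion_behavior_coupling * subject_effects
    acc = intercept + b[:, None] * np.log(t)[None, :]
    acc = acc + noise_sd * rng.standard_normal(acc.shape)
    return np.clip(acc, 0.0, 100.0)


def gen_subject_effects(cfg: SynthConfig) -> np.ndarray:
    """Standard-normal per-subject effect shared by brain and behavior plants."""
    return _rng(cfg.seed, "subject-effects").standard_normal(cfg.n_subjects)


def write_dataset(outdir: str | Path, cfg: SynthConfig, geom: NodeGeometry,
                  expression: np.ndarray, profiles: Mapping[str, np.ndarray],
                  timeseries: Mapping[str, np.ndarray], behavior: np.ndarray) -> None:
    """Dump all generated inputs as labeled TSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = [f"node_{i}" for i in range(cfg.n_nodes)]
    genes = [f"gene_{j}" for j in range(cfg.n_genes)]
    io.write_matrix_tsv(outdir / "expression.tsv", expression, nodes, genes)
    io.write_matrix_tsv(
        outdir / "geometry.tsv",
        np.column_stack([geom.coordinates,
                         [NETWORKS.index(l) for l in geom.network_labels]]),
        nodes, ["x", "y", "z", "network_index"])
    (outdir / "partition.tsv").write_text(
        "node_id\tnetwork_label\n"
        + "\n".join(f"{n}\t{l}" for n, l in zip(nodes, geom.network_labels)) + "\n")
    io.write_matrix_tsv(outdir / "behavior.tsv", behavior,
                        [f"sub_{s}" for s in range(cfg.n_subjects)],
                        [f"t{t}" for t in range(1, behavior.shape[1] + 1)])
    for sess, stack in profiles.items():
        for s in range(cfg.n_subjects):
            io.write_matrix_tsv(outdir / f"profiles_sub{s}_{sess}.tsv", stack[s],
                                nodes, [f"depth_{d}" for d in range(cfg.n_depths)])
    for sess, stack in timeseries.items():
        for s in range(cfg.n_subjects):
            io.write_matrix_tsv(outdir / f"timeseries_sub{s}_{sess}.tsv", stack[s],
                                nodes, [f"tp_{t}" for t in range(cfg.n_timepoints)])
    io.write_json(outdir / "manifest.json",
                  {"config": {k: (list(v) if isinstance(v, tuple) else v)
                              for k, v in vars(cfg).items()},
                   "sessions": list(cfg.sessions)})
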