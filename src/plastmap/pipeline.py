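"""End-to-end orchestration of the two study designs.

``run_multisession`` reproduces the multi-session training analysis on
synthetic data: features → gradients → dispersion changes → behavior
regressions (permutation, LOOCV, baseline/pre specificity) → PLS gene-map
association (raw and PCA-denoised expression, row-permutation and spatial-
surrogate nulls) → gene-set enrichment. ``run_intervention`` reproduces the
two-group (Anodal/Sham) single-session design: dispersion changes normalized
to the control group, summarized descriptively.

Every stage draws from a named seed stream derived from the run seed, so
reruns with the same config are bit-reproducible and stages can be rerun
independently.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import enrichment as enr
from . import features, genemap, gradients, io, synthgen
from .synthgen import SynthConfig, _rng


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run (one seed; per-stage streams derived)."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    mode: str = "multisession"
    sparsity_q: float = 0.9
    k: int = 10
    alpha: float = 0.5
    t: float = 0.0
    n_perm: int = 500
    n_boot: int = 200
    n_components: int = 3
    z_threshold: float = 1.96
    n_decoy_sets: int = 10
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("multisession", "intervention"):
            raise ValueError("mode must be 'multisession' or 'intervention'")
        if not 0.0 < self.sparsity_q < 1.0:
            raise ValueError("sparsity_q must be in (0, 1)")
        if self.n_perm < 99 or self.n_boot < 100:
            raise ValueError("n_perm >= 99 and n_boot >= 100 required")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        synth_kwargs = raw.pop("synth", {})
        if "planted_genes" in synth_kwargs:
            synth_kwargs["planted_genes"] = tuple(synth_kwargs["planted_genes"])
        seed = int(raw.get("seed", 0))
        synth_kwargs.setdefault("seed", seed)
        return cls(synth=SynthConfig(**synth_kwargs), **raw)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _feature_matrices(cfg: SynthConfig, profiles, timeseries):
    mats = {}
    for sess in cfg.sessions:
        for s in range(cfg.n_subjects):
            mats[(s, sess, "MPC")] = features.build_mpc(profiles[sess][s])
            mats[(s, sess, "FC")] = features.build_fc(timeseries[sess][s])
    return mats


def _regression_block(outcome, disp_table, modality, n_perm, seed,
                      baseline_available) -> dict:
    change = gradients.dispersion_wide(disp_table, "post-pre", modality)
    X = change.to_numpy()
    res = beh.regress(outcome, X)
    res.permutation_p = beh.permutation_regression_p(outcome, X, n_perm=n_perm, seed=seed)
    preds, r = beh.loocv(outcome, X)
    res.loocv_predictions, res.loocv_r = preds, r
    block = {
        "measures": list(change.columns),
        "betas": res.betas.tolist(),
        "t_values": res.t_values.tolist(),
        "coef_p": res.coef_p.tolist(),
        "F": res.f_stat, "df": [res.df_model, res.df_resid],
        "F_p": res.f_p, "R2": res.r2, "adj_R2": res.adj_r2,
        "n": res.n, "permutation_p": res.permutation_p,
        "loocv_r": res.loocv_r,
    }
    if baseline_available:
        base = gradients.dispersion_wide(disp_table, "baseline", modality)
        pre = gradients.dispersion_wide(disp_table, "pre", modality)
        frac, comp_p = beh.specificity_permutation(
            base, pre, outcome, n_iter=min(n_perm, 1000), seed=seed + 1)
        block["specificity_significant_fraction"] = frac
        block["specificity_p"] = comp_p
    return block


def _gene_sets(cfg: RunConfig, gene_ids: list[str]) -> dict[str, list[str]]:
    """Synthetic GMT collection: the planted set plus random decoy sets."""
    rng = _rng(cfg.seed, "gene-sets")
    sets = {}
    if cfg.synth.planted_genes:
        sets["planted_set"] = [gene_ids[g] for g in cfg.synth.planted_genes]
        size = max(len(cfg.synth.planted_genes), 5)
    else:
        size = 20
    for i in range(cfg.n_decoy_sets):
        pick = rng.choice(len(gene_ids), size=size, replace=False)
        sets[f"decoy_set_{i}"] = [gene_ids[g] for g in sorted(pick)]
    return sets


def _genemap_block(Xz, Y, cfg: RunConfig, coords, variant: str,
                   surrogates: np.ndarray | None = None) -> dict:
    l = cfg.n_components
    seed = int(_rng(cfg.seed, f"genemap-{variant}").integers(2 ** 31))
    model = genemap.pls_fit(Xz, Y, l)
    perm_p = genemap.pls_perm_test(Xz, Y, l, n_perm=cfg.n_perm, seed=seed,
                                   surrogates=surrogates)
    z = genemap.pls_bootstrap_z(Xz, Y, l, n_boot=cfg.n_boot, seed=seed + 1)
    z_adj = genemap.fiqt_adjust(z)
    sig = genemap.significant_genes(z_adj, cfg.z_threshold)
    model.perm_p, model.boot_z, model.z_adjusted = perm_p, z, z_adj
    return {
        "model": model,
        "summary": {
            "variance_explained": model.y_var_explained.tolist(),
            "permutation_p": perm_p.tolist(),
            "n_significant": sig.sum(axis=0).tolist(),
            "null": "surrogate maps" if surrogates is not None else "row permutation",
        },
        "significant": sig,
    }


def run_multisession(cfg: RunConfig) -> dict:
    """Full multi-session analysis on a synthetic cohort; returns a results bundle."""
    scfg = cfg.synth
    geom = synthgen.gen_geometry(scfg)
    effects = synthgen.gen_subject_effects(scfg)
    profiles = synthgen.gen_profiles(scfg, geom, effects)
    timeseries = synthgen.gen_timeseries(scfg, geom, effects)
    accuracy = synthgen.gen_behavior(scfg, effects)

    mats = _feature_matrices(scfg, profiles, timeseries)
    disp_table, grads = gradients.dispersion_pipeline(
        mats, geom.network_labels, sparsity_q=cfg.sparsity_q,
        k=cfg.k, alpha=cfg.alpha, t=cfg.t)

    rates = np.array([beh.fit_learning_rate(accuracy[s])[1]
                      for s in range(scfg.n_subjects)])
    improvement = accuracy[:, -1] - accuracy[:, 0]
    has_baseline = "baseline" in scfg.sessions
    beh_seed = int(_rng(cfg.seed, "behavior-perm").integers(2 ** 31))
    regressions = {
        f"{mod}_{name}": _regression_block(
            out, disp_table, mod, cfg.n_perm, beh_seed + off, has_baseline)
        for off, (mod, name, out) in enumerate(
            [("MPC", "learning_rate", rates), ("FC", "learning_rate", rates),
             ("MPC", "improvement", improvement), ("FC", "improvement", improvement)])
    }

    # group-mean aligned-gradient change maps: nodes × 6 (MPC G1–G3, FC G1–G3)
    ycols = []
    ynames = []
    for mod in ("MPC", "FC"):
        pre = np.mean([grads[(s, "pre", mod)].components[:, :3]
                       for s in range(scfg.n_subjects)], axis=0)
        post = np.mean([grads[(s, "post", mod)].components[:, :3]
                        for s in range(scfg.n_subjects)], axis=0)
        ycols.append(features.change_map(post, pre))
        ynames += [f"{mod}_G{i}_change" for i in (1, 2, 3)]
    Y_raw = np.hstack(ycols)
    Yz = genemap.zscore(Y_raw)

    # plant the gene association on the leading mode of the actual change maps
    u, s, _ = np.linalg.svd(Yz, full_matrices=False)
    phenotype = u[:, 0] * s[0]
    expression = synthgen.gen_expression(scfg, geom, phenotype)
    Xz = genemap.zscore(expression)

    surro_seed = int(_rng(cfg.seed, "surrogates").integers(2 ** 31))
    surr = np.stack([
        genemap.make_surrogates(Y_raw[:, j], geom.coordinates, cfg.n_perm,
                                seed=surro_seed + j).maps
        for j in range(Y_raw.shape[1])], axis=2)

    gm = {
        "raw": _genemap_block(Xz, Yz, cfg, geom.coordinates, "raw"),
        "denoised": _genemap_block(genemap.zscore(genemap.pca_denoise(expression)),
                                   Yz, cfg, geom.coordinates, "denoised"),
        "raw_surrogate": _genemap_block(Xz, Yz, cfg, geom.coordinates,
                                        "raw-surrogate", surrogates=surr),
    }

    gene_ids = [f"gene_{j}" for j in range(scfg.n_genes)]
    sets = _gene_sets(cfg, gene_ids)
    sig1 = gm["raw"]["significant"][:, 0]
    hits = [gene_ids[j] for j in np.flatnonzero(sig1)]
    enrich_table = (enr.enrich(hits, sets, gene_ids)
                    if hits else pd.DataFrame())

    report = {
        "pls1_significant": bool(gm["raw"]["summary"]["permutation_p"][0] < 0.05),
        "pls_permutation_p": gm["raw"]["summary"]["permutation_p"],
        "pls_variance_explained": gm["raw"]["summary"]["variance_explained"],
        "regression_significant": {
            key: bool(block["permutation_p"] < 0.05)
            for key, block in regressions.items()},
        "fpn_fc_beta_positive": bool(
            regressions["FC_learning_rate"]["betas"][
                regressions["FC_learning_rate"]["measures"].index("FPN-within")] > 0),
    }
    bundle = {
        "config": cfg,
        "geometry": geom,
        "subject_effects": effects,
        "behavior": {"accuracy": accuracy, "learning_rates": rates,
                     "improvement": improvement},
        "dispersion": disp_table,
        "gradients": grads,
        "response_maps": pd.DataFrame(Y_raw, columns=ynames),
        "expression": expression,
        "regressions": regressions,
        "genemap": gm,
        "enrichment": enrich_table,
        "report": report,
    }
    if cfg.outdir is not None:
        _write_bundle(bundle, Path(cfg.outdir))
    return bundle


def run_intervention(cfg: RunConfig) -> dict:
    """Two-group (Anodal/Sham) single-session design with control normalization.

    Both groups share the synthetic geometry; only the Anodal group carries
    the planted post-training effects. Dispersion changes are normalized to
    the Sham group mean and summarized descriptively.
    """
    scfg = cfg.synth
    base = {k: v for k, v in vars(scfg).items()}
    base["n_sessions"] = 2
    geom = synthgen.gen_geometry(SynthConfig(**base))
    effects = synthgen.gen_subject_effects(SynthConfig(**base))
    group_effects = {
        "Anodal": np.abs(effects) + 0.5,  # planted: positive FPN widening
        "Sham": np.zeros_like(effects),
    }
    summaries = []
    normalized = {}
    changes = {}
    for group, eff in group_effects.items():
        gcfg = SynthConfig(**{**base, "seed": scfg.seed + (0 if group == "Anodal" else 1)})
        profiles = synthgen.gen_profiles(gcfg, geom, eff)
        ts = synthgen.gen_timeseries(gcfg, geom, eff)
        mats = _feature_matrices(gcfg, profiles, ts)
        table, _ = gradients.dispersion_pipeline(
            mats, geom.network_labels, sparsity_q=cfg.sparsity_q,
            k=cfg.k, alpha=cfg.alpha, t=cfg.t)
        changes[group] = {
            (mod, meas): gradients.dispersion_wide(table, "post-pre", mod)[meas].to_numpy()
            for mod in ("MPC", "FC") for meas in gradients.MEASURES}
    for (mod, meas) in changes["Anodal"]:
        norm = gradients.normalize_to_control(changes["Anodal"][(mod, meas)],
                                              changes["Sham"][(mod, meas)])
        normalized[(mod, meas)] = norm
        summaries.append((mod, meas, norm.mean(), norm.std(ddof=1),
                          changes["Sham"][(mod, meas)].mean()))
    summary = pd.DataFrame(
        summaries, columns=["modality", "measure", "anodal_normalized_mean",
                            "anodal_normalized_sd", "sham_mean_change"])
    bundle = {"config": cfg, "summary": summary, "normalized": normalized,
              "report": {
                  "fpn_fc_normalized_change_positive": bool(
                      summary.query("modality == 'FC' and measure == 'FPN-within'")
                      ["anodal_normalized_mean"].iloc[0] > 0)}}
    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "intervention_summary.tsv", sep="\t", index=False)
        io.write_json(out / "report.json", bundle["report"])
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg: RunConfig = bundle["config"]
    bundle["dispersion"].to_csv(out / "dispersion.tsv", sep="\t", index=False)
    bundle["response_maps"].to_csv(out / "response_maps.tsv", sep="\t")
    io.write_json(out / "regressions.json", bundle["regressions"])
    gene_ids = [f"gene_{j}" for j in range(cfg.synth.n_genes)]
    for variant, block in bundle["genemap"].items():
        model: genemap.PLSModel = block["model"]
        rows = []
        for comp in range(model.n_components):
            for g in range(len(gene_ids)):
                rows.append((gene_ids[g], comp + 1, model.x_weights[g, comp],
                             model.boot_z[g, comp], model.z_adjusted[g, comp],
                             bool(block["significant"][g, comp])))
        pd.DataFrame(rows, columns=["gene", "component", "weight", "z", "z_adj",
                                    "significant"]).to_csv(
            out / f"pls_genes_{variant}.tsv", sep="\t", index=False)
        io.write_json(out / f"pls_summary_{variant}.json", block["summary"])
    if len(bundle["enrichment"]):
        bundle["enrichment"].to_csv(out / "enrichment.tsv", sep="\t", index=False)
    manifest = {
        "config": {**{k: v for k, v in asdict(cfg).items()
                      if k not in ("synth", "outdir")},
                   "synth": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in asdict(cfg.synth).items()}},
        "checksums": {
            "expression": _checksum(bundle["expression"]),
            "response_maps": _checksum(bundle["response_maps"].to_numpy()),
            "dispersion": _checksum(
                bundle["dispersion"]["value"].to_numpy()),
        },
        "report": bundle["report"],
    }
    io.write_json(out / "manifest.json", manifest)
    io.write_json(out / "report.json", bundle["report"])
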