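"""End-to-end orchestration: simulate or load data, build connectomes, map
hubs, residualize, cluster, embed, decode, and test -- with a
reproducibility manifest.

Every stochastic stage takes its seed from the config, and a rerun with the
same config is bit-identical. The shipped default config states every
analysis parameter explicitly (atlas threshold 0.35, resolution grid
0.1-6.0 in steps of 0.1, 250 runs per resolution, 10 000 spins, top 10%
decoding fraction); scaled-down grids are a config choice, not a hidden
default.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import communities as comm
from . import connectome as conn
from . import decode as dec
from . import dominance as dom
from . import gradients as grad
from . import nulls as nul
from . import residual as res
from . import simulate as sim
from .exceptions import ParameterError
from .parcellation import (
    read_parcellation,
    read_timeseries,
    write_annotation,
    write_matrix,
)

log = logging.getLogger("stemcortex")


@dataclass
class PipelineConfig:
    """Configuration of a full run; see the class-level defaults for the
    canonical parameter values."""

    # input: either a directory written by ``simulate`` ... or simulation pars
    data_dir: str | None = None
    simulate: bool = True
    sim_params: dict = field(default_factory=dict)
    # analysis parameters
    atlas_threshold: float = 0.35
    gamma_min: float = 0.1
    gamma_max: float = 6.0
    gamma_step: float = 0.1
    n_runs: int = 250
    n_spins: int = 10000
    sparsity: float = 0.9
    alpha: float = 0.5
    n_components: int = 5
    top_fraction: float = 0.10
    fdr_q: float = 0.05
    seed: int = 0
    outdir: str = "stemcortex_out"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def gamma_grid(self) -> np.ndarray:
        n = int(round((self.gamma_max - self.gamma_min) / self.gamma_step)) + 1
        return np.round(self.gamma_min + self.gamma_step * np.arange(n), 10)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict (also written
    to ``<outdir>/manifest.json``)."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "seeds": {}}

    # ---- stage: data -----------------------------------------------------
    stage_t = time.time()
    if config.simulate:
        model = sim.GenerativeModel(seed=config.seed, **config.sim_params)
        scheme = sim.make_scheme(model)
        subjects = sim.simulate_timeseries(model, scheme)
        truth = sim.ground_truth(model)
        receptors = [t.zscored() for t in sim.make_annotation_maps(model, "receptor")]
        terms = [t.zscored() for t in sim.make_annotation_maps(model, "term")]
        manifest["seeds"]["simulation"] = model.seed
    else:
        if config.data_dir is None:
            raise ParameterError("data_dir required when simulate is false")
        d = Path(config.data_dir)
        if not d.exists():
            raise ParameterError(f"data_dir {d} does not exist")
        scheme = read_parcellation(d / "parcellation.tsv")
        subjects = [read_timeseries(p, subject_id=p.stem)
                    for p in sorted(d.glob("timeseries_*.tsv"))]
        truth = None
        receptors = _load_maps(d / "receptor_maps")
        terms = _load_maps(d / "term_maps")
    labels = scheme.labels
    ctx_labels = labels[scheme.mask("cortex")]
    bst_labels = labels[scheme.mask("brainstem")]
    log.info("data stage: %d regions, %d subjects (%.1fs)", len(scheme),
             len(subjects), time.time() - stage_t)
    manifest["stages"]["data"] = {"n_regions": len(scheme),
                                  "n_subjects": len(subjects)}

    # ---- stage: connectome ----------------------------------------------
    stage_t = time.time()
    fcs = [conn.build_fc(ts, scheme) for ts in subjects]
    group = conn.group_average(fcs)
    write_matrix(group.matrix, labels, out / "fc_group.tsv")
    t_stat, t_p = conn.block_comparison_ttest(group)
    _, _, dist_r_ctx, _ = conn.fc_distance_profile(group, ("cortex", "cortex"))
    _, _, dist_r_bs, _ = conn.fc_distance_profile(group, ("brainstem", "brainstem"))
    _, _, dist_r_x, _ = conn.fc_distance_profile(group, ("brainstem", "cortex"))
    manifest["stages"]["connectome"] = {
        "welch_t": t_stat, "welch_p": t_p,
        "distance_fc_r": {"cortex": dist_r_ctx, "brainstem": dist_r_bs,
                          "cross": dist_r_x}}
    log.info("connectome stage (%.1fs)", time.time() - stage_t)

    # ---- stage: degree ---------------------------------------------------
    bs2ctx = conn.weighted_degree(group, "brainstem", "cortex")
    ctx2bs = conn.weighted_degree(group, "cortex", "brainstem")
    write_annotation(_ann(bs2ctx.values), bst_labels, out / "degree_brainstem.tsv")
    write_annotation(_ann(ctx2bs.values), ctx_labels, out / "degree_cortex.tsv")
    laminar = scheme.table.loc[scheme.mask("cortex"), "laminar_class"].to_numpy()
    cyto = scheme.table.loc[scheme.mask("cortex"), "cyto_class"].to_numpy()
    f_lam, p_lam = conn.class_anova(ctx2bs.values, laminar)
    f_cyt, p_cyt = conn.class_anova(ctx2bs.values, cyto)
    manifest["stages"]["degree"] = {"laminar_F": f_lam, "laminar_p": p_lam,
                                    "cyto_F": f_cyt, "cyto_p": p_cyt}

    # ---- stage: residual similarity -------------------------------------
    stage_t = time.time()
    profiles = res.regress_degree(group, bs2ctx)
    sim_bs = res.similarity(profiles, "brainstem_nuclei")
    sim_ctx = res.similarity(profiles, "cortical_regions")
    _, median_r = res.degree_profile_correlation(group, bs2ctx)
    write_matrix(sim_bs.matrix, bst_labels, out / "similarity_brainstem.tsv")
    write_matrix(sim_ctx.matrix, ctx_labels, out / "similarity_cortex.tsv")
    manifest["stages"]["residual"] = {"median_profile_r": median_r}
    log.info("residual stage (%.1fs)", time.time() - stage_t)

    # ---- stage: communities ----------------------------------------------
    stage_t = time.time()
    grid = config.gamma_grid()
    sweep = comm.gamma_sweep(sim_bs.matrix, grid, n_runs=config.n_runs,
                             seed=config.seed)
    sweep_df = pd.DataFrame(
        {"gamma": [c.gamma for c in sweep],
         "n_communities": [c.n_communities for c in sweep],
         "zrand_mean": [c.zrand_mean for c in sweep],
         "zrand_var": [c.zrand_var for c in sweep]})
    sweep_df.to_csv(out / "gamma_sweep.tsv", sep="\t", index=False)
    plateau = comm.stable_plateaus(sweep)[0]
    cons = plateau.representative
    pd.DataFrame({"label": bst_labels,
                  "community": cons.consensus.labels}).to_csv(
        out / "communities.tsv", sep="\t", index=False)
    manifest["seeds"]["communities"] = config.seed
    manifest["stages"]["communities"] = {
        "grid_size": int(len(grid)), "n_communities": cons.n_communities,
        "plateau_gamma_range": [plateau.gamma_min, plateau.gamma_max],
        "plateau_length": plateau.length,
        "zrand_mean": cons.zrand_mean, "zrand_var": cons.zrand_var}
    log.info("communities stage (%.1fs)", time.time() - stage_t)

    # ---- stage: nulls ----------------------------------------------------
    stage_t = time.time()
    spins = nul.generate_spins(scheme, n_reps=config.n_spins, seed=config.seed)
    manifest["seeds"]["spins"] = config.seed
    log.info("nulls stage: %d spins (%.1fs)", spins.n_reps, time.time() - stage_t)

    # ---- stage: decode + dominance per community -------------------------
    stage_t = time.time()
    cmaps = comm.community_degree_maps(group, cons.consensus)
    decode_rows = []
    dominance_out = {}
    for k, cmap in enumerate(cmaps):
        report = dec.correlate_battery(cmap, terms, spins=spins,
                                       q=config.fdr_q,
                                       map_name=f"community_{k}")
        retained = dec.top_fraction(report, config.top_fraction)
        retained.insert(0, "map", report.map_name)
        decode_rows.append(retained)
        dres = dom.dominance_analysis(cmap.values, receptors)
        dominance_out[f"community_{k}"] = {
            "r2_adj": dres.r2_adj_full,
            "percent": dict(zip(dres.predictors,
                                np.round(dres.percent_contribution, 4)))}
    pd.concat(decode_rows, ignore_index=True).to_csv(
        out / "decoding.tsv", sep="\t", index=False)
    (out / "dominance.json").write_text(json.dumps(dominance_out, indent=2))
    manifest["stages"]["decode"] = {"n_terms": len(terms),
                                    "retained_per_map": int(len(
                                        decode_rows[0])) if decode_rows else 0}
    manifest["stages"]["dominance"] = {
        k: v["r2_adj"] for k, v in dominance_out.items()}
    log.info("decode+dominance stage (%.1fs)", time.time() - stage_t)

    # ---- stage: gradients ------------------------------------------------
    stage_t = time.time()
    aff_bsctx = grad.build_affinity(sim_ctx.matrix, sparsity=config.sparsity)
    g_bsctx = grad.diffusion_embed(aff_bsctx, n_components=config.n_components,
                                   alpha=config.alpha)
    ctx_fc = group.block("cortex", "cortex").copy()
    np.fill_diagonal(ctx_fc, 0.0)
    aff_cc = grad.build_affinity(ctx_fc, sparsity=config.sparsity)
    g_cc = grad.diffusion_embed(aff_cc, n_components=config.n_components,
                                alpha=config.alpha)
    g1 = grad.align_sign(g_bsctx.first, g_cc.first)
    r_grad, p_grad = grad.compare_gradients(g1, g_cc.first, null=spins)
    pd.DataFrame({"label": ctx_labels, "g1_brainstem": g1,
                  "g1_cortex": g_cc.first}).to_csv(
        out / "gradients.tsv", sep="\t", index=False, float_format="%.10g")
    manifest["stages"]["gradients"] = {"r": r_grad, "p_spin": p_grad}
    log.info("gradients stage (%.1fs)", time.time() - stage_t)

    # ---- planted-truth recovery (synthetic runs only) --------------------
    if truth is not None:
        from scipy import stats as _st
        ari = comm.adjusted_rand_index(cons.consensus.labels,
                                       truth.community_labels)
        hub_r = float(_st.pearsonr(bs2ctx.values, truth.hub_weights)[0])
        grad_aligned = grad.align_sign(g_cc.first, truth.gradient_axis)
        grad_r = float(_st.pearsonr(grad_aligned, truth.gradient_axis)[0])
        manifest["stages"]["recovery"] = {
            "community_ari": ari, "hub_r": hub_r, "gradient_r": grad_r}

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    manifest["versions"] = _versions()
    for f in sorted(out.glob("*.tsv")):
        manifest.setdefault("digests", {})[f.name] = _digest(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=float))
    return manifest


def _ann(values):
    from .parcellation import AnnotationTable
    return AnnotationTable("map", values, scope="all")


def _load_maps(directory: Path):
    from .parcellation import read_annotation
    if not directory.exists():
        return []
    return [read_annotation(p, map_name=p.stem).zscored()
            for p in sorted(directory.glob("*.tsv"))]


def _versions() -> dict:
    import numpy, pandas, scipy  # noqa: PLC0415
    return {"numpy": numpy.__version__, "scipy": scipy.__version__,
            "pandas": pandas.__version__}
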