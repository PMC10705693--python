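"""Synthetic brainstem-cortex datasets with planted ground truth.

The generator emulates the structure the downstream analysis assumes:

* a parcellation of ``n_cortex`` cortical regions on a sphere plus
  ``n_brainstem`` brainstem nuclei in a compact cylinder below it
  (bilateral pairs mirrored in x, a few midline nuclei);
* a shared rank-one "dominant degree" component: every brainstem nucleus
  couples to a global latent signal with nucleus-specific hub weight, and
  every cortical region couples to the same signal with a constant loading,
  so summed brainstem-to-cortex connectivity recovers the hub weights;
* ``K`` brainstem communities, each with a distinct smooth cortical
  projection map, visible only after the dominant component is removed;
* a planted unimodal-transmodal cortical gradient carried by its own latent
  factor (and weakly coupled into the community projections so the
  cortex-to-brainstem similarity gradient aligns with it, as observed
  empirically in real data);
* distance-dependent cortico-cortical connectivity, built from many
  spatially localized bump factors;
* receptor / cognitive-term annotation maps constructed as known linear
  mixtures of the projection maps.

Time series follow a linear latent-factor model
``x_i(t) = baseline_i + lambda_i . z(t) + noise_sd * eps_i(t)`` with i.i.d.
standard-normal latents, so the expected Pearson correlation matrix is
available in closed form (:func:`expected_fc`) and every planted structure
is an exact property of the population connectome, not an artefact of one
noise draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .parcellation import (
    AnnotationTable,
    ParcellationScheme,
    TimeSeriesSet,
    write_annotation,
    write_parcellation,
    write_timeseries,
)

LAMINAR_CLASSES = ("plmb", "het", "uni", "idt")
CYTO_CLASSES = ("ins", "lim", "assoc1", "assoc2", "pss", "pm", "ps")


@dataclass
class GenerativeModel:
    """Parameters of the synthetic dataset.

    Defaults mirror the study conditions of the source data: 400 cortical
    regions, 58 brainstem nuclei (50 bilateral + 8 midline), 20 subjects,
    3 runs x 210 volumes at TR 2.5 s, 5 brainstem communities, 18 receptor
    maps and 123 term maps.
    """

    n_cortex: int = 400
    n_brainstem: int = 58
    n_midline: int = 8
    K: int = 5
    n_subjects: int = 20
    n_timepoints: int = 630
    n_runs: int = 3
    tr_seconds: float = 2.5
    noise_sd: float = 1.0
    brainstem_private_sd: float = 1.0   # extra idiosyncratic brainstem variance:
    # nuclei project mostly outside the brainstem, so within-brainstem FC is
    # weak relative to brainstem-cortex FC
    # loading strengths
    hub_strength: float = 0.7          # brainstem coupling to the global factor
    cortex_global_loading: float = 1.2  # constant cortical coupling to it
    community_strength: float = 0.5     # brainstem coupling to its community factor
    projection_strength: float = 0.8    # cortical coupling to community factors
    projection_offset: float = 0.4      # diffuse part of each ascending
    # projection: a uniform cortical loading on every community factor, so
    # brainstem-cortex FC exceeds within-brainstem FC on average
    gradient_strength: float = 1.4      # cortical coupling to the gradient factor
    distance_strength: float = 0.3      # amplitude of each distance bump factor
    n_distance_factors: int = 48
    bump_concentration: float = 12.0    # von Mises-Fisher kappa of bump factors
    projection_concentration: float = 12.0
    gradient_coupling: float = 0.4      # how strongly projections tilt along the gradient
    n_receptor_maps: int = 18
    n_term_maps: int = 123
    annotation_noise_sd: float = 0.4
    cortical_radius_mm: float = 67.0
    distance_decay_mm: float = 35.0     # descriptive scale of the planted decay
    baseline: float = 100.0             # percent-signal-change style offset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cortex < 4:
            raise ParameterError("n_cortex must be >= 4")
        if not 1 <= self.K <= self.n_brainstem:
            raise ParameterError(
                f"K={self.K} communities cannot exceed n_brainstem={self.n_brainstem}")
        if self.n_brainstem < 1 or self.n_midline > self.n_brainstem:
            raise ParameterError("invalid brainstem region counts")
        if (self.n_brainstem - self.n_midline) % 2:
            raise ParameterError("bilateral nuclei must come in pairs")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if self.n_brainstem < 2 * self.K:
            raise ParameterError("need at least 2 nuclei per community")


@dataclass
class GroundTruth:
    """Planted quantities the pipeline is expected to recover."""

    community_labels: np.ndarray
    hub_weights: np.ndarray
    gradient_axis: np.ndarray
    projection_maps: np.ndarray      # K x n_cortex
    receptor_mixing: np.ndarray      # K x n_receptor_maps
    term_mixing: np.ndarray          # K x n_term_maps

    def to_json(self) -> str:
        return json.dumps({k: np.asarray(v).tolist()
                           for k, v in asdict(self).items()})


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1 + 5 ** 0.5) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / phi
    r = np.sqrt(np.clip(1 - z ** 2, 0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_scheme(model: GenerativeModel) -> ParcellationScheme:
    """Build the synthetic parcellation.

    Cortical regions sit quasi-uniformly on a sphere of radius
    ``cortical_radius_mm``; brainstem nuclei occupy a narrow cylinder
    inferior to it. Hemisphere is the sign of x; bilateral brainstem pairs
    are mirrored. Laminar and cytoarchitectonic classes are binned along a
    noisy copy of the planted gradient so class structure is spatially
    meaningful.
    """
    rng = np.random.default_rng(model.seed)
    sphere = _fibonacci_sphere(model.n_cortex)
    cortex_xyz = sphere * model.cortical_radius_mm

    n_pairs = (model.n_brainstem - model.n_midline) // 2
    bs_x = np.concatenate([
        np.zeros(model.n_midline),
        *[[v, -v] for v in rng.uniform(2.0, 9.0, n_pairs)],
    ])
    bs_y = rng.uniform(-8.0, 8.0, model.n_brainstem)
    bs_z = rng.uniform(-95.0, -45.0, model.n_brainstem)
    # mirrored pairs share y and z
    for p in range(n_pairs):
        i = model.n_midline + 2 * p
        bs_y[i + 1] = bs_y[i]
        bs_z[i + 1] = bs_z[i]
    bs_xyz = np.column_stack([bs_x, bs_y, bs_z])

    grad = planted_gradient(model)
    lam = pd.qcut(grad + 0.6 * rng.standard_normal(model.n_cortex),
                  len(LAMINAR_CLASSES), labels=LAMINAR_CLASSES)
    cyto = pd.qcut(grad + 0.4 * rng.standard_normal(model.n_cortex),
                   len(CYTO_CLASSES), labels=CYTO_CLASSES)

    rows = []
    for j in range(model.n_cortex):
        hemi = "L" if cortex_xyz[j, 0] < 0 else "R"
        rows.append(dict(
            label=f"ctx_{hemi}_{j:04d}", structure="cortex", hemisphere=hemi,
            laminar_class=str(lam[j]), cyto_class=str(cyto[j]),
            x=cortex_xyz[j, 0], y=cortex_xyz[j, 1], z=cortex_xyz[j, 2],
            sx=sphere[j, 0], sy=sphere[j, 1], sz=sphere[j, 2],
            n_voxels=int(rng.integers(200, 1200))))
    for i in range(model.n_brainstem):
        if i < model.n_midline:
            hemi, tag = "midline", f"bs_m_{i:03d}"
        else:
            hemi = "L" if bs_xyz[i, 0] < 0 else "R"
            tag = f"bs_{hemi}_{i:03d}"
        rows.append(dict(
            label=tag, structure="brainstem", hemisphere=hemi,
            laminar_class="", cyto_class="",
            x=bs_xyz[i, 0], y=bs_xyz[i, 1], z=bs_xyz[i, 2],
            sx=np.nan, sy=np.nan, sz=np.nan,
            n_voxels=int(np.round(rng.lognormal(4.0, 0.8)) + 5)))
    return ParcellationScheme(pd.DataFrame(rows))


def planted_gradient(model: GenerativeModel) -> np.ndarray:
    """The planted unimodal-transmodal axis: a z-scored linear form on the
    sphere (first-degree spherical harmonic along a fixed oblique axis)."""
    sphere = _fibonacci_sphere(model.n_cortex)
    axis = np.array([0.25, 0.55, 0.8])
    axis /= np.linalg.norm(axis)
    g = sphere @ axis
    return (g - g.mean()) / g.std()


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def planted_structures(model: GenerativeModel):
    """Deterministic planted quantities: hub weights, community labels,
    projection maps, gradient axis. All derived from ``model.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 101]))
    hub = rng.lognormal(0.0, 0.5, model.n_brainstem)
    hub /= np.linalg.norm(hub)

    # communities: shuffled contiguous chunks, sizes as equal as possible
    sizes = np.full(model.K, model.n_brainstem // model.K)
    sizes[: model.n_brainstem % model.K] += 1
    labels = np.repeat(np.arange(model.K), sizes)
    rng.shuffle(labels)

    sphere = _fibonacci_sphere(model.n_cortex)
    centers = _fibonacci_sphere(max(model.K, 4))[: model.K]
    grad = planted_gradient(model)
    proj = np.empty((model.K, model.n_cortex))
    tilt = (np.linspace(-1, 1, model.K) * model.gradient_coupling
            if model.K > 1 else np.zeros(1))
    for k in range(model.K):
        bump = np.exp(model.projection_concentration * (sphere @ centers[k] - 1.0))
        proj[k] = _zscore(_zscore(bump) + tilt[k] * grad)
    return hub, labels, proj, grad


def build_loadings(model: GenerativeModel, scheme: ParcellationScheme) -> np.ndarray:
    """Latent-factor loading matrix Lambda, (n_regions, n_factors).

    Factor order: [global hub, gradient, K community factors,
    n_distance_factors bump factors].
    """
    hub, labels, proj, grad = planted_structures(model)
    n = len(scheme)
    ctx = scheme.indices("cortex")
    bst = scheme.indices("brainstem")
    n_fac = 2 + model.K + model.n_distance_factors
    lam = np.zeros((n, n_fac))

    lam[bst, 0] = model.hub_strength * hub * np.sqrt(model.n_brainstem)
    lam[ctx, 0] = model.cortex_global_loading
    lam[ctx, 1] = model.gradient_strength * grad
    for k in range(model.K):
        lam[bst[labels == k], 2 + k] = model.community_strength
        lam[ctx, 2 + k] = (model.projection_strength * proj[k]
                           + model.projection_offset)

    # spatially localized bump factors -> distance-dependent cortical FC
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 202]))
    sphere = _fibonacci_sphere(model.n_cortex)
    for d in range(model.n_distance_factors):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        bump = np.exp(model.bump_concentration * (sphere @ u - 1.0))
        lam[ctx, 2 + model.K + d] = model.distance_strength * _zscore(bump)
    return lam


def _noise_sd_vector(model: GenerativeModel, scheme: ParcellationScheme) -> np.ndarray:
    """Per-region innovation scale: brainstem nuclei carry extra private
    variance on top of the shared observation noise."""
    sd = np.full(len(scheme), float(model.noise_sd))
    sd[scheme.indices("brainstem")] = np.sqrt(
        model.noise_sd ** 2 + model.brainstem_private_sd ** 2)
    return sd


def expected_fc(model: GenerativeModel, scheme: ParcellationScheme) -> np.ndarray:
    """Closed-form population Pearson correlation of the latent-factor model."""
    lam = build_loadings(model, scheme)
    cov = lam @ lam.T + np.diag(_noise_sd_vector(model, scheme) ** 2)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def simulate_timeseries(model: GenerativeModel, scheme: ParcellationScheme,
                        n_subjects: int | None = None,
                        n_timepoints: int | None = None) -> list[TimeSeriesSet]:
    """Draw per-subject time series from the latent-factor model."""
    n_subjects = model.n_subjects if n_subjects is None else n_subjects
    n_timepoints = model.n_timepoints if n_timepoints is None else n_timepoints
    if n_timepoints < 50:
        raise ParameterError("n_timepoints must be >= 50")
    lam = build_loadings(model, scheme)
    noise_sd = _noise_sd_vector(model, scheme)[:, None]
    run_len = n_timepoints // model.n_runs
    boundaries = [r * run_len for r in range(model.n_runs)] if run_len >= 3 else [0]
    out = []
    for s in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([model.seed, 303, s]))
        z = rng.standard_normal((lam.shape[1], n_timepoints))
        eps = rng.standard_normal((len(scheme), n_timepoints))
        data = model.baseline + lam @ z + noise_sd * eps
        out.append(TimeSeriesSet(f"sub-{s:02d}", data, model.tr_seconds,
                                 list(boundaries)))
    return out


_KIND_SALT = {"receptor": 1, "term": 2, "power": 3}


def make_annotation_maps(model: GenerativeModel, kind: str) -> list[AnnotationTable]:
    """Receptor/term/power maps as known linear mixtures of projection maps.

    ``map_m = sum_k mixing[k, m] * projection_k + smooth noise``; the mixing
    matrix is recorded in the ground truth so decoding and dominance
    recovery can be checked against it.
    """
    counts = {"receptor": model.n_receptor_maps, "term": model.n_term_maps,
              "power": 7}
    if kind not in counts:
        raise ParameterError(f"unknown annotation kind {kind!r}")
    n_maps = counts[kind]
    mixing = _mixing_matrix(model, kind)
    _, _, proj, _ = planted_structures(model)
    rng = np.random.default_rng(
        np.random.SeedSequence([model.seed, 404, _KIND_SALT[kind]]))
    sphere = _fibonacci_sphere(model.n_cortex)
    maps = []
    for m in range(n_maps):
        v = mixing[:, m] @ proj
        if model.annotation_noise_sd > 0:
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            smooth = _zscore(np.exp(6.0 * (sphere @ u - 1.0)))
            v = v + model.annotation_noise_sd * smooth
        maps.append(AnnotationTable(f"{kind}_{m:03d}", v, scope="cortex"))
    return maps


def _mixing_matrix(model: GenerativeModel, kind: str) -> np.ndarray:
    counts = {"receptor": model.n_receptor_maps, "term": model.n_term_maps,
              "power": 7}
    rng = np.random.default_rng(
        np.random.SeedSequence([model.seed, 505, _KIND_SALT[kind]]))
    # each map dominated by one community, with smaller spillover weights
    n_maps = counts[kind]
    mixing = rng.uniform(0.0, 0.35, (model.K, n_maps))
    lead = rng.integers(0, model.K, n_maps)
    mixing[lead, np.arange(n_maps)] = rng.uniform(0.8, 1.2, n_maps)
    return mixing


def ground_truth(model: GenerativeModel) -> GroundTruth:
    hub, labels, proj, grad = planted_structures(model)
    return GroundTruth(
        community_labels=labels, hub_weights=hub, gradient_axis=grad,
        projection_maps=proj,
        receptor_mixing=_mixing_matrix(model, "receptor"),
        term_mixing=_mixing_matrix(model, "term"))


def write_dataset(model: GenerativeModel, outdir) -> dict:
    """Write the full fixture set (scheme, per-subject series, annotation
    maps, ground truth) as TSV/JSON; returns a small manifest dict."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = make_scheme(model)
    write_parcellation(scheme, outdir / "parcellation.tsv")
    labels = scheme.labels
    ctx_labels = labels[scheme.mask("cortex")]
    subjects = []
    for ts in simulate_timeseries(model, scheme):
        p = outdir / f"timeseries_{ts.subject_id}.tsv"
        write_timeseries(ts, labels, p)
        subjects.append(p.name)
    ann_files = {}
    for kind in ("receptor", "term"):
        kind_dir = outdir / f"{kind}_maps"
        kind_dir.mkdir(exist_ok=True)
        for table in make_annotation_maps(model, kind):
            write_annotation(table, ctx_labels, kind_dir / f"{table.map_name}.tsv")
        ann_files[kind] = kind_dir.name
    (outdir / "ground_truth.json").write_text(ground_truth(model).to_json())
    manifest = dict(seed=model.seed, n_regions=len(scheme),
                    subjects=subjects, annotations=ann_files)
    (outdir / "simulation_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
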