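# stemcortex

Functional-connectomics analysis of the human brainstem and its cortical
targets: hub detection, degree-residualized connectivity profiles,
consensus community detection, diffusion-map gradients, spatial null
models, and chemoarchitectural decoding — together with a synthetic data
generator with planted ground truth for end-to-end validation.

## The scientific problem

Resting-state fMRI studies of cortico-cortical organization are mature,
but the brainstem — the source of most ascending neuromodulatory systems —
is usually left out. When brainstem nuclei *are* included, their functional
connectivity to cortex is dominated by a single strong component: a few
hub nuclei couple broadly to the whole cortex, and this shared "degree"
signal swamps the finer structure. The analysis implemented here follows a
three-step logic:

1. **Hubs.** Compute each nucleus's weighted degree to cortex; this is the
   dominant axis of brainstem-cortex coupling.
2. **Residual profiles.** Regress the degree pattern out of every
   connectivity profile. What remains is the nucleus-specific part:
   which cortical territories a nucleus prefers *beyond* its overall
   coupling strength. Pairwise similarity of residual profiles defines
   two derived networks — nucleus-by-nucleus and cortex-by-cortex.
3. **Organization.** On the nucleus similarity network, run consensus
   community detection (signed Louvain across a resolution sweep, with
   z-Rand stability selection of the resolution). On connectivity and
   similarity matrices, compute diffusion-map embeddings and compare the
   resulting gradients. Statistical comparisons of cortical maps use
   spin-based spatial null models; contributions of receptor/transmitter
   maps are quantified by dominance analysis, and cortical patterns are
   decoded against a term-map battery.

Because no public dataset ships with this package, it includes a
generative model that plants each of these structures — hub weights, a
unimodal-transmodal gradient, community-specific projections, and
distance-dependent cortical FC — so every pipeline stage can be validated
against known ground truth.

## Worked example

Simulate the default study (20 subjects, 400 cortical regions, 58
brainstem nuclei, 5 planted communities), run the core analysis, and
check recovery against the planted ground truth:

```python
import numpy as np
from scipy import stats
from stemcortex import simulate as sim, connectome as conn, residual as res
from stemcortex import communities as comm, gradients as grad, nulls as nul

model = sim.GenerativeModel(seed=42)
scheme = sim.make_scheme(model)
truth = sim.ground_truth(model)

# group-average functional connectome
fcs = [conn.build_fc(ts, scheme) for ts in sim.simulate_timeseries(model, scheme)]
group = conn.group_average(fcs)

# 1. hubs: brainstem weighted degree to cortex
degree = conn.weighted_degree(group, "brainstem", "cortex")
print("hub recovery r =", round(stats.pearsonr(degree.values, truth.hub_weights)[0], 3))

# 2. residual profiles and nucleus similarity
profiles = res.regress_degree(group, degree)
sim_bs = res.similarity(profiles, "brainstem_nuclei")

# 3a. consensus communities across the resolution sweep
sweep = comm.gamma_sweep(sim_bs.matrix, comm.default_gamma_grid(),
                         n_runs=50, seed=0)
plateau = comm.stable_plateaus(sweep)[0]
labels = plateau.representative.consensus.labels
print("plateau: k =", plateau.n_communities,
      "over gamma", plateau.gamma_min, "-", plateau.gamma_max)
print("community recovery ARI =",
      round(comm.adjusted_rand_index(truth.community_labels, labels), 3))

# 3b. principal cortical gradient and a spin test against the planted axis
cc = group.block("cortex", "cortex").copy()
np.fill_diagonal(cc, 0.0)
emb = grad.diffusion_embed(grad.build_affinity(cc, sparsity=0.9), n_components=2)
planted = sim.planted_gradient(model)
spins = nul.generate_spins(scheme, n_reps=1000, seed=0)
r, p = nul.spin_pvalue(grad.align_sign(emb.first, planted), planted, spins)
print(f"FC gradient vs planted axis: r = {r:.3f}, p_spin = {p:.4f}")
```

Output (about 20 seconds on a laptop):

```
hub recovery r = 0.979
plateau: k = 5 over gamma 1.8 - 3.1
community recovery ARI = 0.956
FC gradient vs planted axis: r = 0.962, p_spin = 0.0160
```

The consensus sweep finds a stable plateau at exactly the planted five
communities, the degree map recovers the planted hub weights, and the
first diffusion gradient recovers the planted axis. Note the spin
p-value: even at r = 0.96 it is only 0.016, because the null preserves
spatial smoothness — a naive parametric p here would be astronomically
small and wrong.

## Command-line interface

The same pipeline is available as a CLI:

```bash
stemcortex simulate --seed 42 --out data/           # synthetic dataset + truth
stemcortex fc --data data/ --out results/           # group connectome
stemcortex run-all --config config.yaml             # everything, with manifest
```

`run-all` writes TSV/JSON artifacts plus a `manifest.json` recording
seeds, package versions, per-stage summaries, and SHA-256 digests of all
outputs, so two runs with the same config are verifiably identical.

## Package layout

| Module | Purpose |
| --- | --- |
| `parcellation` | Region tables, time series, annotations, TSV/volume I/O |
| `simulate` | Generative model with planted ground truth |
| `connectome` | FC construction, group averaging, weighted degree, block stats |
| `residual` | Degree residualization and profile-similarity matrices |
| `communities` | Signed Louvain, consensus clustering, resolution sweeps, plateaus |
| `gradients` | Affinity kernels and diffusion-map embedding |
| `nulls` | Spin tests, plain permutation, FDR |
| `dominance` | Dominance analysis over adjusted R² |
| `decode` | Term-battery decoding of cortical maps |
| `pipeline` | End-to-end orchestration with manifests |
| `cli` | `stemcortex` command-line entry point |

See `docs/methods.md` for the mathematical conventions and numerical
choices.
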