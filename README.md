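# nicheflow

**Indirect energy flow in niche-model food webs with Yodzis–Innes
bioenergetic dynamics.**

When energy moves from a prey species to its predator, part of it travels
directly along the feeding link and part arrives over *indirect paths*
through intermediate species (prey → omnivore's other prey → predator, or
around feeding loops). The fraction of prey-to-predator flow carried by
paths of length greater than one — the **flow indirectness (FI)** of an
interaction — measures how strongly a pairwise interaction is mediated by
the rest of the network. `nicheflow` is a simulation-and-analysis pipeline
that quantifies FI in synthetic food webs and asks which structural
features of a web predict it. It is aimed at food-web and ecosystem-network
ecologists who want a reproducible, fully scripted version of this
experiment, or who want its parts (niche-model generator, bioenergetic
integrator, dynamic environ approximation) as a library.

## The model chain

1. **Topology — the niche model.** Each of S species gets a niche value
   n_i ~ U(0,1), a feeding-range width r_i = n_i·b_i with
   b_i ~ Beta(1, (1−2C)/(2C)) so that E[r] = C, and a range center
   c_i ~ U(r_i/2, n_i); species i eats every species whose niche value
   falls inside its range (self-links allowed). Connectance is C = L/S².
   Candidate webs are rejected until they are a single connected component
   with at least one producer (component count = multiplicity of the zero
   Laplacian eigenvalue).

2. **Parametrization.** Trophic level TL_i is the mean of (a) 1 + shortest
   prey-path distance to a basal species and (b) the flow-based position
   TL_i = 1 + Σ_j TL_j p_ji with equal diet fractions. Body mass is
   m = 10^(TL−1); mass-specific metabolic rate x = 0.138 for producers and
   0.314·m^(−1/4) for consumers; maximum consumption y = 8; conversion
   efficiency e = 0.45 eating producers, 0.85 otherwise.

3. **Dynamics — Yodzis–Innes.** Producers grow logistically (r = K = 1);
   consumers pay metabolism and feed through a Holling type III response
   with predator interference,
   F_ij = B_j²/(B0² + c·B_i·B0² + Σ_{k∈prey(i)} B_k²) with q = c = 1,
   B0 = 0.5. Fixed-step RK4 (dt = 0.01) runs 1000 time units, species below
   10⁻⁶ are removed once, and the reduced web runs 1000 more units; only
   that second phase is analyzed.

4. **Dynamic environ approximation (DEA).** At each integer time the
   assimilated predation flows f_ij = x_i·y·B_i·F_ij form a conservative
   flow snapshot (producer growth enters as boundary input; unassimilated
   food and metabolic losses leave as boundary outputs). Normalizing by
   donor total outflow gives the flow-intensity matrix G (g_ii = 0). Over a
   window of m = 20 steps, the integral-flow matrix is
   N = I + G(t) + G(t)G(t+1) + … , and per-link indirectness is
   FI_ij = (N_ij − G_ij)/N_ij, averaged over realized predator–prey links.
   (The absolute indirect intensity N − G is recorded alongside; see
   `docs/methods.md` for why both definitions ship.)

5. **Statistics.** A scan over sizes × connectances × replicates yields one
   record per realization (~27 topological metrics + mean FI). A regression
   tree (split only if R² gains ≥ 0.01; 10-fold cross-validation pruning)
   identifies the structural predictors of FI, and a through-origin
   quadratic PathLen = b₁C + b₂C² summarizes the connectance–path-length
   relationship.

## Worked example

```python
import numpy as np
import nicheflow as nf

rng = np.random.default_rng(1)
web = nf.generate_web(15, 0.2, rng)
print("S =", web.S, " L =", web.L, " realized C =", round(web.connectance, 3))
pweb = nf.parametrize(web)
sim = nf.run_protocol(pweb, rng)
print("extinct:", sim.extinct_ids.size, " steady-state gap:", f"{sim.steady_state_gap:.2e}")
dea = nf.run_dea(sim)
print("mean FI (ratio):", round(dea.mean_FI, 4), " valid:", dea.valid)
print("mean FI (difference):", round(dea.mean_FI_difference, 4))
```

prints

```
S = 15  L = 48  realized C = 0.213
extinct: 0  steady-state gap: 1.11e-10
mean FI (ratio): 0.128  valid: True
mean FI (difference): 0.0235
```

This 15-species web reached a numerical steady state (max |dB/dt| ≈ 10⁻¹⁰)
with no extinctions; on average 12.8% of the integral flow on each feeding
link arrived over indirect paths, and the mean absolute indirect intensity
per link was 0.0235 units of flow per unit input.

The same pipeline is scriptable from the shell:

```sh
nicheflow generate --size 15 --connectance 0.2 --seed 1 --out web.tsv
nicheflow metrics --web web.tsv           # one-row CSV of the predictor suite
nicheflow dea --web web.tsv --seed 1 --out dea.json
nicheflow scan --config configs/small.ini --outdir out/   # records + analysis
```

## The analysis

Numbered drivers under `analysis/` rerun the study end to end and write
their tables to `results/`:

| script | what it does |
|---|---|
| `01_simulate_scan.py` | size × connectance × replicate scan → per-run records and a per-cell mean-FI grid |
| `02_pathlen_quadratic.py` | 2,460 generated topologies → through-origin quadratic of path length on connectance |
| `03_cart_predictors.py` | regression tree predicting mean FI from the metric suite |

## Layout

```
src/nicheflow/      library: nichemodel, trophic, dynamics, environ,
                    metrics, scan, analysis, io, cli
analysis/           numbered narrative drivers (see above)
scripts/            acceptance.py
tests/              pytest suite (unit, property and end-to-end checks)
docs/methods.md     modeling decisions, numerical choices, limitations
```
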