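# h12msm

Markov state model (MSM) analysis of helix-12 dynamics in a nuclear-receptor
ligand-binding domain, rebuilt as a tested, desk-scale pipeline.

The position of C-terminal helix 12 (H12) on the glucocorticoid receptor
ligand-binding domain encodes its signaling state: packed against the
activation-function-2 surface it recruits coactivators (agonist state), folded
into the coactivator groove it blocks them (the *passive antagonist* state).
Different ligand classes shift the conformational equilibrium and the folding
pathway of H12 between five metastable states S0–S4. This package implements
the full analysis chain used to quantify that picture from conformational
trajectories:

1. **Featurization** — Kabsch (least-squares) superposition, backbone-RMSD and
   H12 center-of-mass distance features, RMSD classification against a panel
   of crystal-like reference conformations, heavy-atom PCA.
2. **Free-energy landscapes** — `F(x, y) = -kT ln(p/p_max)` on the 2D feature
   plane, with basin detection.
3. **MSM estimation** — k-means microstate discretization, sliding-window
   transition counts at lag τ, ergodic trimming, reversible
   maximum-likelihood transition matrix `T` (detailed balance
   `π_i T_ij = π_j T_ji` enforced), conjugate Dirichlet posterior sampling for
   uncertainty.
4. **Validation** — implied timescales `t_i = -τ / ln|λ_{i+1}(T)|` as a
   function of lag, and the Chapman–Kolmogorov test `P(kτ) ≈ P(τ)^k` on
   metastable sets.
5. **Coarse-graining** — PCCA+ fuzzy memberships from the dominant
   eigenvectors, macrostate populations `χᵀπ` and lifetimes `τ/(1 - T_mm)`.
6. **Transition path theory** — forward/backward committors `q⁺, q⁻` from
   linear solves, reactive flux `f_ij = π_i q⁻_i T_ij q⁺_j`, and iterative
   maximum-bottleneck decomposition of the total A→B flux into ranked
   pathways with percentage contributions.

Because real microsecond MD ensembles are not shippable, a first-class
`generate` module plants analytically known kinetics: block-structured
reversible Markov chains, Brownian dynamics on five-well 2D potentials with
ligand presets (`apo`, `agonist`, `modulator`, `antagonist`), and a toy
swinging-helix coordinate trajectory with closed-form geometry. Every stage of
the pipeline is validated against these ground truths.

## Worked example

Recover a planted 5-macrostate chain end to end:

```python
import numpy as np, h12msm as h

chain  = h.make_metastable_chain(n_macro=5, micro_per_macro=10,
                                 intra_p=0.2, inter_p=0.002, seed=1)
dtrajs = h.sample_discrete_chain(chain, n_trajs=50, n_steps=20_000, seed=1)
msm    = h.MarkovStateModel(lag=1).fit(dtrajs)
print("slowest timescales (steps):", np.round(msm.timescales(4), 2))
print("planted analytic         :", np.round(chain.implied_timescales(4), 2))
macro  = h.pcca_coarse_grain(msm.model_, 5)
print("macrostate populations   :", np.round(np.sort(macro.macro_populations)[::-1], 3))
print("planted macro mass       :", np.round(np.sort(chain.macro_stationary_mass())[::-1], 3))
```

prints

```
slowest timescales (steps): [21.53 20.35 19.37 18.06]
planted analytic         : [21.32 20.13 19.35 18.17]
macrostate populations   : [0.212 0.206 0.206 0.197 0.179]
planted macro mass       : [0.214 0.205 0.205 0.195 0.181]
```

i.e. the four slow relaxation times and the five stationary macrostate masses
are recovered to within sampling error, and (not shown) the PCCA+ crisp
assignment reproduces the planted blocks exactly.

The same workflow from the shell, on the antagonist ligand preset:

```bash
h12msm run --preset antagonist --seed 7 --out-dir out_antagonist
h12msm report --out-dir out_antagonist
```

The pathway table (`out_antagonist/pathways.tsv`) then reads

```
pathway	percent_of_total_flux
S0→S2→S3→S4	63.6
S0→S1→S3→S4	28.6
S0→S1→S2→S3→S4	7.8
```

the S0→S4 folding flux routes dominantly through the S2 corridor and
terminates in the passive-antagonist-like basin S4, whose stationary
population (~0.24) is several-fold larger than under the `agonist` preset —
the qualitative signature of an antagonist-stabilized passive state. Under
the `agonist` preset the dominant pathway switches to the S1 corridor and S4
nearly empties.

## Layout

```
src/h12msm/
  generate.py    synthetic chains, Brownian dynamics, ligand presets, toy helix
  trajectory.py  containers + PDB/XYZ/TSV text formats
  featurize.py   Kabsch, RMSD/COM features, reference panel, heavy-atom PCA
  landscape.py   2D free-energy surfaces and basin detection
  msm.py         k-means discretizer, counting, reversible MLE, Bayesian MSM
  validate.py    implied-timescale scan, Chapman–Kolmogorov test
  kinetics.py    PCCA+, committors, reactive flux, pathway decomposition
  pipeline.py    end-to-end orchestration, reporting, provenance
  cli.py         `h12msm` command-line interface
```

See `docs/methods.md` for the models, parameter choices and limitations.
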