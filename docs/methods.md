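# Methods

This note documents the models implemented in `h12msm`, the defaults that
matter, what the synthetic generators do and do not emulate, and the numerical
choices made where the design was open.

## Markov state model

Conformational dynamics are modeled as a Markov jump process on microstates
obtained by k-means clustering of a 2D feature vector per frame: the Kabsch
RMSD of a backbone selection to a reference structure, and the center-of-mass
distance between helix 12 and an anchor residue. Features are z-scored per
column before clustering because the two axes differ by an order of magnitude
in scale (Å vs tens of Å); cluster centers are reported in original units.

Transitions are counted with a sliding window at lag τ (windows advance by
one frame; trajectories are never concatenated, so no artificial transitions
cross file boundaries). Counts are trimmed to the largest strongly connected
component of the count graph (ties toward the component containing the
smallest state index), and the transition matrix is estimated under detailed
balance by the standard self-consistent iteration on symmetrized count
variables,

    x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j),   T_ij = x_ij / Σ_j x_ij,

iterated to a 1e-12 change in the normalized variables. The stationary
distribution π comes jointly from the fixed point, so
`π_i T_ij = π_j T_ji` holds to machine precision by construction.

Uncertainty uses the conjugate Dirichlet posterior per row,
Dir(C_i1 + α, …, C_iK + α), sampled via gamma variates (α = 0 by default, so
structurally zero counts stay zero). The posterior samples are
non-reversible; they serve only for credible bands on scalar functionals
(timescales, CK cells), while the headline estimate is the reversible MLE.
This mirrors common practice where a full reversible sampler is not needed
for band-level decisions.

For implied-timescale bands, the Dirichlet concentration uses the *effective*
count matrix C/τ. Sliding windows at lag τ overlap τ-fold, so raw counts
overstate the information content by roughly that factor and the posterior
would narrow by ~√τ too much; C/τ is the standard correction.

### Validation

* Implied timescales `t_i = -τ/ln|λ_{i+1}|` are scanned over a lag list;
  eigenvalues with modulus within 1e-12 of 1 beyond the Perron root are
  reported infinite (disconnected or periodic dynamics). Non-reversible
  models may have complex eigenvalues; the modulus is used and flagged.
* The Chapman–Kolmogorov test compares the set-projected k-th power of the
  base model against a model re-estimated at lag kτ. Projection weights
  microstates by the stationary distribution within each set. Binomial
  standard errors `√(p(1-p)/N_source)` accompany each estimated cell, with
  `N_source` the transitions counted out of the source set at that lag.
  Both diagnostics accept `reversible=False` because detailed-balance
  estimation deliberately destroys unit-modulus cycle eigenvalues that the
  diagnostics are meant to expose.

## PCCA+ coarse-graining

Metastable macrostates come from PCCA+ on the top-m right eigenvectors of the
reversible T (computed via the symmetrized matrix `D^{1/2} T D^{-1/2}` for
numerical stability). Spectral-simplex vertices are located with the
inner-simplex algorithm (iterative Gram–Schmidt selection of the most
independent rows); memberships are `χ = X A` with `A = X[vertices]^{-1}`,
clipped to non-negative and row-renormalized. The subsequent feasibility
optimization of full PCCA+ is omitted: on metastable inputs the ISA
memberships are already crisp to numerical precision, and every recovery test
(planted blocks, brute-force partition oracle) passes exactly. Macrostate
populations are `χᵀπ`, the coarse matrix is the π-weighted projection
`(χᵀ diag(π) T χ)` row-normalized, and lifetimes use the mean geometric
holding time `τ/(1 - T_mm)`.

## Transition path theory

The forward committor solves the linear system `q⁺_i = Σ_j T_ij q⁺_j` on
intermediate states with `q⁺ = 0` on A and `1` on B; the backward committor
is the forward committor of the time-reversed chain
`T̃_ij = π_j T_ji / π_i` toward A (equal to `1 - q⁺` for reversible models,
which is verified rather than assumed). Gross reactive flux is
`f_ij = π_i q⁻_i T_ij q⁺_j` (zero diagonal), net flux is the pairwise
positive part, and the total flux is the net flow out of A. Conservation
(node balance at intermediates, outflow(A) = inflow(B)) is checked to 1e-10.

Pathways are extracted by iterative maximum-bottleneck decomposition:
repeatedly find the widest A→B path in the net-flux graph, subtract its
bottleneck flux along the path, and record it, until the residual drops below
1e-12 of the total. Bottleneck ties resolve to the path with fewer hops,
then the lexicographically smallest state sequence. The search is two-phase —
a widest-path Dijkstra for the optimal bottleneck W*, then a best-first
search on (hops, sequence) restricted to edges carrying at least W* — because
committing to the widest route *to each intermediate* can violate the
tie-break rules when a later edge limits the bottleneck. Coarse-grained
fluxes sum microstate gross fluxes between distinct macrostates; source and
target sets must each lie within a single macrostate.

## Synthetic generators

The generators provide planted ground truth, not molecular realism; they
contain no force field, solvent or thermostat.

* **Metastable chains** — raw weights uniform on (0,1], symmetrized, scaled
  by `intra_p` (within-block) and `inter_p` (between blocks), row-normalized.
  Symmetrization makes the planted chain reversible (π ∝ row sums of the
  weight matrix), matching the detailed balance of physical kinetics; without
  it the reversible estimator converges to the chain's reversibilization and
  entrywise recovery is meaningless. `inter_p > 0` guarantees irreducibility.
  Reference conditions throughout: 5 macrostates × 10 microstates,
  `intra_p = 0.2`, `inter_p = 0.002`, sampled as 50 trajectories × 20 000
  steps (slowest planted timescales ≈ 18–21 steps).
* **Brownian dynamics** — Euler–Maruyama integration of
  `x ← x - (D·dt/kT)∇U + √(2D·dt)·g` on a sum-of-Gaussian-wells potential,
  optionally plus a flat-bottomed quartic confinement and/or a harmonic term.
  The confinement reflects that RMSD and distance observables are bounded;
  without it trajectories leak into the flat background and the slow spectrum
  reflects fringe diffusion instead of well hopping. The harmonic term exists
  because a Gaussian well is only locally quadratic, so equilibrium-variance
  checks of the integrator need a true `½kr²` potential. 10% of steps are
  discarded as burn-in by default.
* **Ligand presets** — five wells on the (RMSD-like, distance-like) plane:
  source S0 at the bottom, two symmetric intermediate corridors S1 (left)
  and S2 (right), the active-like basin S3, and the passive-antagonist-like
  basin S4 (width 1.4, kT = 1, D = 1, dt = 0.05, confinement centered on the
  well region). Only depths differ between presets (in kT, S0…S4):
  apo (3.0, 2.8, 1.0, 2.0, 2.2), agonist (3.0, 3.2, 0.8, 4.5, 2.5),
  modulator (2.8, 1.0, 3.0, 2.0, 4.0), antagonist (3.0, 0.8, 3.2, 1.5, 4.5).
  The depths are illustrative constants calibrated once so that the presets
  differ qualitatively — the agonist preset routes the dominant S0→S4 flux
  through S1 and stabilizes S3, the antagonist/modulator presets route it
  through S2 and stabilize S4 — and were verified robust across seeds. The
  tests assert these *properties*, never particular percentages.
* **Toy helix** — a 20-atom body and an 11-atom arm on regular lattices with
  a zero-mean zigzag in z (so frames are never collinear and superposition is
  well-posed), hinged at the origin; the arm swings in the x–y plane. Segment
  centroids stay in the swing plane, so the arm–anchor distance has the
  closed form `d² = a² + r² + 2ar·cosθ + z₀²`.

What passing tests show, and what they do not: the pipeline provably recovers
planted kinetics of the right structure (metastability, five basins,
corridor-dependent flux) at desk scale. They say nothing about force-field
accuracy, sampling convergence of real MD, or the quantitative pathway
percentages of any real receptor ensemble.

## Defaults and scales

| Parameter | Default | Why |
| --- | --- | --- |
| landscape bins | 80×80, 2% range padding | resolves five wells at the default data volume |
| kT (landscape) | 1 | surfaces in kT units |
| microstates k | 100 | ~20 per basin at desk scale (1000 available via config for large data) |
| lag τ | 5 steps | inside the converged region of the default ITS scan {1,2,5,10,20} |
| CK factors | {1,2,3,4} | multiples of the validated base lag |
| macrostates | 5 | the five planted basins |
| Bayesian samples | 50 (pipeline), 100 (diagnostics) | band stability vs runtime |
| synthetic scale | 50 trajectories × 20 000 steps | keeps every stage's estimation error inside the tested bounds while the full pipeline runs in ~1–2 minutes on one CPU |

The reference-panel classifier uses a 2.0 Å default cutoff; population
fractions from real data depend strongly on this unstated choice, so
cutoff-sensitive populations are only tested on synthetic constructions.

## Numerical choices and edge cases

* Kabsch superposition uses SVD with the determinant correction, so the
  returned rotation is always proper, including for reflection-related
  inputs; fewer than three non-collinear selected atoms is an error.
* PCA alignment is single-pass onto frame 0 over heavy atoms (no iterative
  mean-structure refinement), keeping the covariance oracle exact.
* Empty landscape bins get `F = ∞` and are excluded from basin search; the
  minimum finite cell is exactly 0 by construction.
* k-means uses scikit-learn's k-means++ with an explicit seed and `n_init=1`
  for determinism; empty clusters are relocated internally.
* A lag at or beyond every trajectory length yields an all-zero count matrix
  plus a warning, not an exception; scans flag such lags and continue.
* The pipeline refuses to estimate at a lag absent from the configured scan
  unless forced, and derives all stage seeds from the single config seed, so
  a fixed config reproduces numeric tables byte-for-byte.

## Known limitations

* No TICA/VAMP featurization, hidden Markov models, milestoning,
  mean-first-passage-time matrices, or rate-matrix estimation.
* The Bayesian sampler is non-reversible; credible bands near the
  reversible MLE are approximate (adequate for lag selection and CK bands,
  not for posterior inference on π).
* Coordinate I/O covers multi-model PDB and XYZ text only; binary MD formats
  are out of scope (use an external converter).
* PCCA+ without the feasibility optimization can produce slightly negative
  memberships before clipping on weakly metastable inputs; crispness is only
  guaranteed when a spectral gap exists.
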