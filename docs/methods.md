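# Methods

## The model

Each gene's nascent (unspliced, `u`) and mature (spliced, `s`) mRNA follow
the two-stage splicing kinetics

    du/dt = α − βu,        ds/dt = βu − γs = v,

with transcription rate α, splicing rate β, degradation rate γ, and a
binary transcriptional state: during induction α is active; at the switch
time α drops to 0 and the system relaxes from the switch-time state. The
closed-form solutions and the time-independent phase-portrait curve s(u)
are implemented in `kappavelo.kinetics`. Because sequencing undercounts
nascent reads, measured unspliced abundance is modelled as the true one
divided by a gene-specific upscale factor m; internally every formula
operates on m·u.

The central difficulty is scale invariance: multiplying (α, β, γ) by any
κ > 0 and dividing time by κ leaves the phase portrait unchanged, so a
gene's portrait fixes its rates only up to its time scale κ. Velocity
*components* are therefore incomparable across genes until the κ's are
pinned down, which is the package's core contribution: κ is recovered from
cell densities along the trajectory, after which the correctly scaled
parameters (A, B, Γ) = κ·(α, β, γ) and M = m give the high-dimensional
velocity V_i = B∘M∘U_i − Γ∘S_i.

## Per-gene fitting

`kappavelo.fit` fits the β = 1 family member of each gene's portrait. Free
parameters: α, γ, m and the switch position (stored as the fraction
q_switch of the induction asymptote reached before shutdown). Latent
variables: each cell's branch k (1 induction, 0 repression) and position τ
along it. The fit is a hard-assignment EM on orthogonal distances:

* E-step: project every cell onto the nearest point of the current curve
  (dense τ grid per branch, followed by a vectorised golden-section
  refinement of each projection), assigning (k, τ). Distances are taken
  after standardising u and s to unit variance, so neither axis dominates
  and the resulting likelihood is invariant to gene-wide rescaling.
* M-step: Levenberg–Marquardt update of the parameters at fixed
  projections, accepted only when it lowers the profiled objective, so the
  objective is monotone non-increasing by construction.

Because this alternation converges slowly along the curve's flat
directions, the winning start is polished by a direct Nelder–Mead
minimisation of the profiled objective (cells re-projected at every
evaluation). Five starts are used in total: a deterministic initialisation
(m₀ = sd(s)/sd(u), α₀ = 1.05·max(m₀u), γ₀ from the inverse slope of s on
m₀u over the extreme-abundance cells, switch at the largest observed u)
plus four log-normal jitters, skipped when an earlier start already fits
to numerical precision.

Two model-selection safeguards matter in practice. First, an
induction-only model (no switch) always competes with the switch model,
and the switch is kept only when it improves the mean squared distance by
a clear relative margin (default 5%): without this, measurement noise
around a single branch's plateau is absorbed into a spurious switch, which
corrupts downstream time statistics. Second, fits whose data span only a
sliver of the fitted curve are flagged `unidentifiable` (a cloud parked at
a fixed point carries no kinetic information).

The per-gene score is the mean per-cell Gaussian log-likelihood under the
fitted residual variance (floored at 1e-12). Genes are filtered by a
likelihood quantile (default: keep the upper half) and, optionally, by a
cluster-order prior: a gene is dropped when the Spearman correlation
between a user-supplied cell-type ordering and the mean fitted curve
position per cluster is negative.

## Recovering κ from cell density

For two cells i before j in the same transcriptional phase, inverting the
β = 1 unspliced solution gives f(i,j) = log((mu_i − α)/(mu_j − α)), which
equals κ·Δt_ij on the true time axis. The elapsed time is proxied by the
number of cells observed between the two states, d(i,j): in snapshot data
the chance of catching a cell in a region is proportional to the time
spent there. Plotting f against d yields points under a line of slope κ
(in cells-between units); dwell at a plateau inflates d without advancing
f, pushing points strictly below the line. The slope is extracted by a
parallelogram fit: among candidate slopes (log-spaced around a robust
quantile initialisation, then refined), choose the one whose residual band
of fixed coverage (default 95%) is narrowest — minimum parallelogram area
at fixed d-range. Fewer than 50 usable pairs triggers a quantile-slope
fallback with a warning.

Design choices that proved load-bearing:

* Pair endpoints are restricted to cells in the transient window of their
  branch (fitted m·u between 10% and 90% of the branch amplitude): the
  log-ratio is noise-dominated near the asymptote and time-degenerate at
  the pre-activation plateau.
* The in-between count d uses **all** cells in the expression interval,
  regardless of their branch assignment; thinning the count to one phase
  corrupts the density clock whenever some cells of a single-branch gene
  are assigned to the other branch.
* The estimate is taken from the phase holding the most transient cells
  (the model is single-branch at any expression level); the other phase is
  a fallback.
* κ estimates carry one unknown global unit (cells per time). This cancels
  in velocity directions; all recovery claims are "up to one global
  constant".

A second estimator inverts the spliced solution instead (numerically, on
the fitted branch curve) and serves as a cross-check; it depends on γ as
well as α and is therefore the more error-prone route.

## The heuristic (MNN) route

Fixing the observation interval of gene g at Δt_g = 1/γ_g and linearising,
s_g(t + Δt_g) = (β_g/γ_g)·u_g(t): a cell's unspliced profile is
proportional to its own future spliced profile. If β and γ are shared
across genes, future states can be found directly by matching each cell's
U-vector against other cells' S-vectors: j is a mutual nearest neighbour
of i when s_j is among the k nearest spliced neighbours of u_i *and* u_i
is among the k nearest unspliced queries of s_j (k = 5 by default; not
every cell has mutual neighbours). The arrow points from the cell's
embedding position toward the mean position of its mutual neighbours,
shrunk by a global display factor (default 0.5). A cell may be its own
mutual neighbour; by default self is excluded from the arrow target so
steady cells get zero arrows. Preparation follows standard cross-modal
matching: log1p, per-modality size normalisation, per-cell L2
normalisation (Euclidean distance then orders like cosine).

`future_state_check` quantifies the shared-rate assumption: it evaluates
the Euler-step future state with the true per-gene rates against the
prediction from one pooled rate pair, so it passes exactly when rates are
homogeneous — the regime in which the heuristic is valid — and reports
per-gene errors otherwise (the method's documented failure mode).

## Processing

The detailed pipeline: variable genes by the variance of analytic Pearson
residuals of the spliced counts (overdispersion θ = 100, residuals clipped
at ±√n_cells); low-count gene filter by detection fraction (defaults 5% in
U, 10% in S); joint size normalisation with one factor per cell,
target/(Σu + Σs), which preserves every within-cell u:s ratio — the
property whose violation by per-modality normalisation distorts phase
portraits whenever cell types differ in total-u:total-s; kNN imputation
(default k = 30, PCA with 30 components on z-scaled spliced counts,
neighbourhood includes the cell itself, ties broken by cell index). A
state tag enforces the order raw → normalised → imputed, and every filter
appends a JSON record (rule, n_before, n_after) to the processing log.

## Visualisation

PCA projection is exactly linear: arrow = projection of S + V·Δt minus
projection of S (Δt = 1), the only representation where the drawn arrow is
the high-dimensional vector. For nonlinear embeddings, endpoints are
placed by Nyström out-of-sample projection: a Gaussian transition kernel
P′(i,j) ∝ exp(−‖x_i − x_j‖²/2σ_i²) from each endpoint to the training
points, row-normalised, then Y_test = P′·Y_train — a convex combination,
so endpoints stay inside the hull of the embedding. Bandwidths are
adaptive (distance to the 15th nearest training point) unless the
embedding supplies its own kernel width. Validity requires endpoints near
the sampled manifold: all velocities share one downscale factor chosen so
the longest arrow does not exceed the median nearest-neighbour distance in
feature space, and endpoints with vanishing kernel mass (< 1e-12) are
flagged out-of-distribution with a uniform-over-k-nearest fallback.

The correlation-kernel baselines of earlier tools are implemented
faithfully for comparison, including their documented defects (velocity
magnitude is invisible to a correlation/cosine kernel). An optional
display-only smoothing operator averages arrows over 30 spliced-space
neighbours and is never applied to stored velocities.

## The simulator

`kappavelo.simulate` draws per-gene base rates log-normally (log-mean 0,
log-sd 0.5 — a modest spread keeping noiseless fits identifiable; the
exact generating distribution of the original study is not published, so
these are this package's own defaults) and scales each gene's triple by
κ ~ U[1, 15]. Cells are uniform snapshots on one branch; each gene's
active window is window_constant/(κβ) (default 3 splicing time constants,
~95% of the induction asymptote), so activation is inversely proportional
to speed, fast genes switch on last, and the mature all-genes-steady state
is never sampled — late cells point outside the observed cloud. Noise is
additive Gaussian per entry with sd proportional to the gene's
steady-state amplitude (default 5%), truncated at zero. Options share the
base β across genes (so overall speed is set by κ alone) or both β and γ
(the heuristic's regime). What it does not emulate: UMI depth/dropout,
capture-efficiency variation, branching lineages, bursting, cell
birth/death — so passing tests show correctness of the inference under
the model's own assumptions, not robustness to every artefact of real
data.

Three conventions for the recovery experiments follow from what the
simulator generates: m is fixed at 1 during fitting (no unspliced
undercount is simulated, and on induction-only arcs (α, m) form a
near-degenerate ridge); recovered-vs-true-κ comparisons use the shared-β
option (otherwise recovery is proportional to κβ and a per-gene β would
confound the comparison); and noisy counts pass through the pipeline's
kNN-imputation step before fitting — the log-ratio time statistic is
noise-dominated near the asymptote, and denoising is exactly what the
imputation stage is for — with the neighbourhood scaled to the dataset
(k = 10 at 500 cells, ~2% of cells, matching the ~1% the default k = 30
represents at real-dataset scale). Size normalisation is skipped on
simulated abundances, which carry no library-size variation. Noiseless
data are fitted raw: averaging is pure bias when there is no noise to
remove.

## Numerical choices

* γ = 1 and β = γ singularities use analytic-limit branches selected when
  the denominator is below 1e-8.
* Curve grids are uniform in approach fraction q (τ = −log(1−q)/min(1,γ),
  q up to 0.99995), dense near activation where curvature is highest.
* EM: grid 250/branch, golden-section refinement 10 iterations, max 10
  alternations (the polish does the precision work), polish budget 300
  evaluations, parameter tolerance 1e-6.
* Pair sampling: 2000 seeded pairs per gene by default, exhaustive when
  fewer exist.
* Problem sizes used by the validation suite and `scripts/acceptance.py`:
  50 genes × 500 cells for κ recovery and velocity fidelity (noiseless and
  5% noise), 30 × 300 for projection comparisons, 30 × 500 for the
  heuristic — the scale at which the statistical properties of interest
  are already stable.

## Known limitations

* The density clock assumes uniform capture along the trajectory;
  heterogeneous proliferation/death or enrichment sorting breaks the
  proportionality between cell counts and time.
* κ recovery degrades for the fastest genes: a gene active for a fraction
  w of the sampled window contributes ~n·w transient cells, and no
  estimator can beat the resulting counting noise; expect increased spread
  at high κ rather than failure.
* The per-gene EM fits a single switch; genes with multiple rate regimes
  are meant to be filtered (likelihood and cluster-order filters), not
  modelled.
* Nyström projection cannot extrapolate: arrows at the boundary of the
  manifold, where true velocities point outside the sampled cloud, are the
  least reliable (flagged, not fixed).
* loom input is not supported (h5ad and MatrixMarket pairs are).
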