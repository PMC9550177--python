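# kappavelo

RNA velocity estimation with per-gene time scales, for single-cell
transcriptomics.

RNA velocity infers the direction and speed of cell-state change from the
balance of nascent (unspliced, `u`) and mature (spliced, `s`) mRNA, under
the two-stage kinetics

$$\frac{du}{dt} = \alpha - \beta u, \qquad \frac{ds}{dt} = \beta u - \gamma s = v.$$

A gene's u–s phase portrait determines its rates only up to a joint
rescaling: if $(\alpha, \beta, \gamma)$ fits the portrait, so does
$(\kappa\alpha, \kappa\beta, \kappa\gamma)$ for any $\kappa > 0$. Summing
gene-wise velocity components without knowing each gene's $\kappa$
therefore points the high-dimensional velocity vector in the wrong
direction. This package implements two estimators that confront that
scale-invariance problem directly:

* **the detailed route** fits each gene's $\beta = 1$ phase portrait by EM
  (parameters $\alpha, \gamma$, switch point, unspliced upscale $m$), then
  recovers $\kappa$ from cell density along the trajectory: for two cells
  in the same transcriptional phase, $f(i,j) = \log\frac{mu_i - \alpha}{mu_j - \alpha}$
  equals $\kappa\,\Delta t_{ij}$, and the number of cells observed between
  the two states is a proxy for $\Delta t_{ij}$. The slope of the upper
  boundary of the $(d, f)$ cloud — a parallelogram fit, since dwell at
  steady state only pushes points below the line — recovers $\kappa$ up to
  one global constant. Velocities
  $V_i = B{\circ}M{\circ}U_i - \Gamma{\circ}S_i$ with
  $(A, B, \Gamma) = \kappa(\alpha, \beta, \gamma)$ are then visualised by
  exact PCA projection or by Nyström out-of-sample projection onto any
  existing embedding, which preserves arrow lengths that
  correlation-kernel projections discard.
* **the economical route** skips rate fitting: over the interval
  $1/\gamma$, a cell's unspliced profile is proportional to its own future
  spliced profile, so future states are found by mutual nearest neighbours
  between each cell's U-vector and other cells' S-vectors. Valid when
  $\beta$ and $\gamma$ are roughly shared across genes; a diagnostic
  quantifies how badly that assumption is violated.

A splicing-kinetics simulator with known rates, time scales, true times
and true velocities makes every stage testable end to end.

## Worked example

`examples/kappa_recovery.py` simulates 20 genes (time scales
$\kappa \sim U[1, 15]$, one shared base splicing rate) at 500 cells,
fits every gene and recovers the time scales from cell density:

```
gene   true kappa   recovered/global-constant
gene_0      1.10       1.16
gene_1     10.04      10.59
gene_2     11.08      11.08
gene_3     12.70      12.92
gene_4      4.95       4.78
...
R^2 of recovered vs true kappa (line through origin): 0.9962
```

Each recovered value sits on the diagonal after dividing by one global
constant — the cells-per-time unit of the density clock, which is shared
by all genes and therefore does not affect velocity directions. The other
scripts in `examples/` walk through simulation, single-gene fitting, the
full detailed workflow, the mutual-nearest-neighbour route and the
projection comparison, each printing the quantities it computes.

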