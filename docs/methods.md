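# Methods

## Model

`sinucell` assumes a population of cells progressing through a periodic
process acts additively on log-scale expression: gene g in cell n carries a
component `A_g cos(x_n − φ_g)` on top of its non-periodic program and
noise, where `x_n ∈ [0, 2π)` is the cell's position in the cycle. After
per-gene standardization this is exactly the family of functions a
one-circular-bottleneck autoencoder with a cosine/sine decoder can
represent, so the maximum-fidelity reconstruction forces the encoder to
order cells around the circle.

The encoder is a two-hidden-layer tanh perceptron (default widths 30 and
20) ending in one unbounded scalar; the decoder applies cos and sin to that
scalar and mixes them linearly per gene (`V_circ`, G × 2). Optional linear
embedding components (`n_linear`, default 0) pass through untransformed and
model non-periodic structure. The objective is the summed squared
reconstruction error with L2 penalties on all weight matrices
(`α = 1e-3` per encoder matrix, `β = 1e-4` on the decoder), optionally with
per-gene weights in the residual to emphasize prior-knowledge genes.

### Identifiability

The reconstruction is invariant to a global rotation of the circle and to
reflection (`x → −x` with the matching rotation of the decoder rows), so
pseudo-times are meaningful only up to these transforms. Amplitudes `A_g`
are invariant; phases `φ_g` shift by the global offset. All accuracy
metrics first align inferred to reference angles with
`circular_alignment_score`, which maximizes the centered complex
correlation of the unit-circle embeddings over rotations in closed form and
tries both orientations. The score is reported in [0, 1]; independent
angle vectors score near `N^{-1/2}`.

### Training

Adam on analytic gradients (the gradient implementation is tested against
central finite differences at relative 1e-4). Defaults: 500 epochs,
minibatch `min(N, 128)`, learning rate 5e-3 decaying exponentially to 5% of
its initial value across the scheduled epochs, early stop when the relative
epoch-loss change stays below 1e-6 over 50 epochs, weight init uniform
`±1/√fan_in`, seed 0. The constant-step regime of Adam leaves parameters
jittering at a noise floor; the decay is what lets clean fixtures reach
near-exact reconstruction. The loss surface has local optima (circle
traversed more than once, or collapsed to an arc); `n_restarts` refits from
consecutive seeds and keeps the lowest final loss. On the fixtures used
here a single restart suffices.

### Decoder has no intercept

`ŷ = V[cos x; sin x; x_lin]` contains no constant term. Standardization
forces every gene column to mean zero over the *sample*, but the fitted
values `a cos x_n + b sin x_n` generally do not have zero sample mean, so a
finite random sample of angles leaves a small unremovable offset per gene
(order `A/√N`). This is invisible in pseudo-time accuracy but caps
per-entry reconstruction precision (~0.1 at N = 100). The simulator's
`pseudotime_distribution="grid"` option places cells at exactly evenly
spaced angles, where the empirical cos/sin means vanish and a perfect
reconstruction exists; reconstruction-precision tests use it.

## Preprocessing

Counts or TPM are transformed as `log2(x + 1)` (the pseudocount is a
parameter; 1 is the conventional choice) and each gene is z-scored with the
population (divisor-N) standard deviation so all genes enter the loss on
the same scale. Constant genes become zero columns rather than being
dropped — genes are never filtered, since poorly fitting genes receive
near-zero decoder amplitude and silence themselves. Cell QC (total-signal
and mitochondrial-fraction thresholds) is available for droplet data and
removes only cells. The per-gene means/sds are retained so corrected data
can be mapped back to the log scale.

## Dimensionality selection

`scan_dimensionality` fits one circular plus (k−1) linear components for
k = 1..k_max and records the per-entry reconstruction MSE next to rank-k
PCA. k* is the largest k whose relative MSE drop from k−1 exceeds a
threshold (default 5%; the elbow criterion is inherently heuristic and the
threshold is exposed). Two caveats discovered while validating: the scan
needs a well-converged fit (more epochs, lighter regularization than the
training defaults) or residual circular signal masquerades as a linear
component; and on data whose periodic structure is weak relative to noise,
single noise PCs can approach the threshold. A circle needs two linear
dimensions but only one circular one, so on circular data the model beats
PCA at k = 1.

## Correction

`remove_circular` subtracts the circular addend of the reconstruction,
exactly: corrected + circular component equals the input to machine
precision. Linear embedding components are deliberately not subtracted
(they model non-periodic structure to be preserved). The operation consumes
a fitted model and never refits — applying it twice subtracts twice. Output
stays on the standardized scale by default (`scale="corrected"`); a flag
de-standardizes back to log scale. `remove_pcs` provides the linear
baseline: subtract the reconstruction built from designated principal
components. Downstream embeddings (t-SNE) run on the corrected matrix
without re-standardization.

## Marker genes and condition comparison

Amplitude and phase derive from the decoder rows by
`a cos x + b sin x = A cos(x − φ)`. Genes are ranked by amplitude
(descending, ties broken lexicographically for determinism); because the
model is trained on standardized data, amplitude is scale-free and
comparable across separately fitted datasets. `compare_conditions`
intersects two gene universes and reports `ΔA` and the signed phase
difference wrapped to (−π, π]; phase differences presume the two fits have
been rotationally aligned, amplitude differences do not. No significance
threshold ships — there is no natural null for the amplitude, so the output
is a ranking.

## Simulator

`simulate_circular` draws angles (uniform, a von Mises mixture, or an even
grid), gives each periodic gene an amplitude from U(0.5, 2) and a uniform
phase, adds Gaussian noise (sd 0.3 by default), and labels cells by
contiguous stage arcs — default widths (π, π/2, π/2) mimicking G0/G1, S,
G2/M occupancy. Values are treated as already log-scale. The generator
reproduces the geometry the model targets (a noisy circle with a gene-wise
sinusoidal parameterization) and none of the distributional pathologies of
real scRNA-seq: no dropout/zero inflation, no library-size variation, no
correlated noise, and sinusoidal kinetics exactly matching the decoder
family. Passing recovery tests therefore demonstrates correctness of the
machinery, not performance on real droplet data.

`make_virtual_tumor` mirrors the confounding construction used to evaluate
cycle-effect removal: clone 1 is a base population unchanged; clone 2
resamples its cells and multiplies a chosen gene set by a fold change
(default 2 — implemented as +log2(fold change) on log values, i.e. the
doubling is on the linear scale; defaults of 288 cells and 600 cell-cycle
plus 1000 other perturbed genes reproduce the reference construction). The
packaged `synthetic_cell_cycle_gene_ids` list is a synthetic positional
stand-in; real analyses should supply a curated list.

## Evaluation

* **Stage accuracy** — a Gaussian mixture on the raw 1-D pseudo-time, with
  components matched to truth labels by the best bijection (exhaustive to
  5 labels, Hungarian beyond; both exact). When the reference process
  occupies the circle near-uniformly, the mixture boundaries are weakly
  identified — the likelihood is almost flat in them — so assignments vary
  by initialization. Restarts use distinct seeds with data-point
  initialization; following the usual convention for stochastic
  clusterings, the best accuracy over restarts (default 5) is reported when
  truth is supplied, the best likelihood otherwise. Expect residual
  seed-to-seed spread (~0.65–0.98 best-of-5 on the reference fixture; the
  wrap-around stage can also split between components).
* **Subclone separability** — best two-component GMM accuracy of clone
  identity on a seeded 2-D t-SNE (perplexity 30 by default; both recorded,
  as the score depends on them).
* **Cycling fraction** — a von Mises KDE (bandwidth 0.3 rad → concentration
  ≈ 11) on the circle; arcs with density below 0.2× the circular mean are
  gaps (missing stages), cells outside the most-occupied dense arc count as
  cycling, and a gapless density reports 1.0. Both parameters are heuristic
  and exposed; the KDE widens the dense arc beyond the raw point spread, so
  fractions read slightly low for very tight resting populations.
* **Gene-set program scores** — per-cell mean over the intersected gene
  set.

## Reference study conditions

The acceptance script and the end-to-end tests use: 500 cells × 200 genes
(150 periodic, amplitudes U(0.5, 2), noise sd 0.3, uniform angles) for
recovery; 300 × 100 standard Gaussian with a 3-component linear-only model
for the PCA-equivalence check; two 250-cell clones sharing one circular
program with 100 periodic genes doubled in clone 2 for the separability
check; and a 288-cell base with 2500 genes for the virtual-tumor recipe
(600 + 1000 genes doubled). These sizes keep a full run around ten seconds
on one CPU while leaving each measured effect far from its decision
boundary.

## Known limitations

* One circular dimension; processes with several interleaved periodic
  programs are out of scope.
* The decoder is strictly sinusoidal — one harmonic. Sharp, pulse-like
  kinetics are approximated by their fundamental and lose amplitude.
* No intercept in the decoder (see above).
* Quiescent (non-cycling) cells are not modeled explicitly; they compress
  onto an arc, and the cycling-fraction heuristic quantifies this only
  coarsely.
* Amplitude ranking has no significance calibration.
* The numpy trainer is single-threaded per step; datasets of ~10⁴ cells ×
  ~10⁴ genes fit comfortably, but very large atlases will be slow compared
  to GPU-backed implementations.
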