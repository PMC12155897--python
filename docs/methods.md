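# Methods

## Design construction and coding

`design.build_bbd` supports exactly the 3-factor Box–Behnken design: the
12 edge midpoints (each factor pair at (±1, ±1), third factor at 0)
followed by the centre replicates. Runs are emitted deterministically —
factor pairs in lexicographic order, signs in the order (−,−), (+,−),
(−,+), (+,+), centres last. Experimental run randomization is a wet-lab
concern; every computation downstream is invariant to row order, so the
constructor favours determinism. The packaged 17-run table keeps its
original (randomized) row order.

Coding uses half-range scaling, (actual − centre)/((high − low)/2), which
is the only linear map consistent with equispaced three-level factors.
`FactorSpec` enforces equispacing at 1e-9 relative tolerance. Responses
are stored as percent (13.36 means 13.36% of dry mass).

## Quadratic fit and ANOVA

The 10-term model is solved by `numpy.linalg.lstsq` (QR/SVD-based), not
the raw normal equations; the inverse normal matrix is still formed for
the per-term partial SS, which is numerically harmless at n = 17 with
coded columns of order 1. Per-term sums of squares are partial (Type-III),
bⱼ²/cⱼⱼ: on a BBD the linear and interaction columns are mutually
orthogonal, but the pure-quadratic columns are not orthogonal to the
intercept, and the partial convention is the one that matches standard
DoE software output on this design. Sequential (Type-I) SS is available
via `anova(..., sequential=True)`.

Pure error comes from replicate groups defined by exact equality of the
coded level vector; lack of fit is the remainder of the residual. The
lack-of-fit F uses the pure-error mean square; all other F ratios use the
residual mean square. p-values are upper-tail F probabilities with no
multiplicity adjustment. With no replicates the two rows are omitted with
a warning. On a perfect fit (zero residual mean square) F is reported as
+∞ with p = 0 rather than failing.

Summary statistics: R² = SS_model/SS_total, adj-R² = 1 − (1−R²)(n−1)/df_res,
CV% = 100·√MS_res / ȳ.

The independent oracle used in the tests is the closed-form BBD contrast
set: the intercept equals the centre-run mean, each linear coefficient is
an 8-denominator contrast of the runs at ±1, each interaction a
4-denominator four-point contrast. The least-squares path must agree with
these to 1e-10 on random response vectors.

## Surface optimization

The stationary point solves 2Bx = −b with B the quadratic-form matrix
(pure quadratics on the diagonal, half the interactions off it); the
nature is read off the eigenvalues of B, with |λ| ≤ 1e-10 treated as a
ridge (reported as saddle with a warning). The box-constrained maximum
runs projected gradient ascent with the Lipschitz-safe step 1/(2·max|λ|)
from the 20 best seeds of a 21³ grid, and by construction never returns
less than the grid maximum. A perfectly flat surface returns the box
centre, for determinism. Both views are reported side by side in the CLI
because published optimization tables rarely state which one the vendor
software used; on the packaged data they coincide (the stationary point is
interior).

## Network surrogate

Architecture 3-H-1 with tansig (= tanh) hidden units and a linear output.
Default H = 7: in our neuron sweeps on the 17-run table, as in the study
this package reproduces, the validation MSE minimum sits at H = 7 even
though larger H also fits. Inputs and the response are min–max normalized
to [−1, 1] using the bounds of **all** runs (not the training subset), so
a trained network's forward pass does not depend on how the data were
split.

Levenberg–Marquardt training: full-batch Jacobian by closed-form
backpropagation (36 parameters at H = 7), step (JᵀJ + μI)⁻¹Jᵀe, μ divided
by 10 on an accepted step and multiplied by 10 otherwise, starting at
μ = 1e-3 (exposed as `--mu-init`; a plain gradient-descent learning rate
has no slot in LM, so a nominal "learning rate" setting from other
toolchains is not mapped onto μ). Stopping: 1000-epoch cap, training-MSE
goal 1e-5 (normalized scale), gradient-infinity-norm floor 1e-6, μ
overflow at 1e10, or 6 consecutive validation-MSE increases (max-fail);
the returned parameters are from the best-validation epoch. Weights are
initialized uniform(−0.5, 0.5); an initialization-scale sweep showed the
fit quality is insensitive to this choice on the packaged data.

With 17 samples split 12/3/2, single runs are high-variance: the
validation set has three points and early stopping often triggers within
ten epochs. The whole-data fit quality of the *best* restart is therefore
the meaningful quantity, and the package default restart budget for that
property is 1200 (a few seconds of CPU); the best restart then reaches
all-17-run R² ≥ 0.98 reliably. `split_data` sizes are round(n·f) with the
test subset absorbing the rounding remainder (17 → 12/3/2).

## Genetic algorithm

Real-coded, searching in actual units (the reported optima are in actual
units) with clipping to the box. Tournament-2 selection, BLX-0.5 blend
crossover on a 0.8 fraction of offspring, per-gene Gaussian mutation with
probability 0.1 and σ = 10% of the gene range, 2 elites, population 100,
300 generations. Selection and mutation operators are conventional
defaults; they are not prescribed by the study being reproduced and are
exposed in `GAConfig`. Elitism makes the best-fitness trace non-decreasing,
which the tests assert for every seed. The fitness is maximized directly
(no sign-flip convention).

## Comparison metrics

R², MSE (denominator n), RMSE = √MSE, and two absolute-deviation
statistics: `aad_relative_percent` = (100/n)Σ|err|/|actual| and `mad` =
(1/n)Σ|err|. Both are reported because comparison tables in this
literature often print the unnormalized mean absolute deviation under the
label "AAD"; on the packaged data the quadratic model gives MAD 0.1641
versus relative AAD 1.17%.

## Assay arithmetic

Total phenolics: Y% = 100·C·V·r/W; the calibration line is fitted with
`scipy.stats.linregress`. ORAC uses the plain ratio-sum AUC
1 + Σ fᵢ/f₀ — no trapezoid correction, matching the assay convention this
package reproduces — so the AUC depends only on fluorescence ratios and is
invariant to detector gain. Net AUC subtracts the AAPH-containing blank
(a flagless alternative subtraction was considered and rejected: the
standards are netted the same way, so any consistent choice cancels in
the calibration). Trolox equivalence comes from the net-AUC-vs-
concentration line as the primary path, with the single-point ratio
(net_sample/net_trolox)·[Trolox] as a secondary path; negative TE is
clamped to zero with a warning. The wet-lab scale factor (μmol TE per g
dry weight per μM in the well) enters only through `mass_basis`.

## Synthetic data

`gen_surface` draws y = quadratic(truth) + N(0, σ) on any design; with
the fitted 17-run coefficients as truth and σ = 0.1 (the replicate
pure-error SD of the packaged data is ≈0.08, so 0.1 is a realistic bench
noise level) the linear-coefficient RMS error must match the BBD contrast
standard error σ/√8 within 20% sampling slack over 500 replicates.
`gen_plate` builds geometric-decay curves whose ratio-sum AUC is planted
analytically (the AUC sees only ratios, so the decay shape is a free
choice), with Trolox standards at 6.25–50 μM placed exactly on the
generating line; `gen_calibration` is a plain noisy line. All generators
are pure functions of (parameters, seed).

What the synthetic data do not emulate: heteroscedastic or correlated
assay noise, plate edge effects, fluorescence drift, factor measurement
error, or any chemistry (solvent viscosity, cavitation). Passing the
recovery tests shows the estimators are correct under the assumed
homoscedastic Gaussian model, not that real extractions satisfy it.

## Known limitations

- Only the 3-factor BBD is constructed; other response-surface designs
  must be supplied as CSV.
- The published network weights for this system were never printed, so a
  retrained surrogate (and hence the GA optimum) can only reproduce the
  *regime* of the published fit, not its exact numbers; the surface near
  the optimum is flat, and materially different conditions can score
  nearly identical predicted yields.
- Type-III SS uses the explicit inverse normal matrix; for designs far
  larger or worse-conditioned than desk-scale DoE tables a pivoted
  orthogonal approach would be preferable.
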