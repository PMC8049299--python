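# Methods

## Model and assumptions

The analysis treats promoter-proximal histone-modification (HM) level as
a sparse linear function of binned transcription-factor (TF) occupancy.
For each gene the response is the mean HM ChIP-seq signal on the window
[TSS−500, TSS+500) and the features are mean TF signals in k = 10
consecutive 100-bp bins of that window, both log-transformed and min-max
scaled to [0, 1] per column. The fitted objective is

    ‖y − β₀ − Xβ‖² + λ₁‖β‖₁ + λ₂ Σ_{(i,j)∈E} |βᵢ − βⱼ|

with E the chain of adjacent bins within each TF. The quadratic term
carries no 1/2 and no 1/n factor; all closed forms used in validation
(the KKT bound 2‖Xᵀ(y−ȳ)‖∞ for the all-zero solution, the orthonormal
soft-threshold solution at λ₁/2) follow this scaling. The model is
deliberately linear: coefficients are interpreted as signed association
strengths, not causal effects, and nonlinear relationships are out of
scope.

Assumptions worth keeping in mind: signal columns are comparable after
log-unit normalization (motivated by right-skewed, positive raw
coverage); associations are class-homogeneous (one model per CpG class);
and residual noise is roughly i.i.d. Gaussian, which the F-test inherits.

## Promoter geometry

Coordinates are 0-based half-open throughout; GTF input (1-based closed)
is converted on read. Bin 0 is the most upstream bin in gene orientation,
so minus-strand windows are bin-reversed relative to genome coordinates —
"early bins" then mean the same promoter position for every gene. When a
gene has several transcripts its most 5′ TSS (in gene orientation) is
used, a deterministic and annotation-robust choice. Windows extending
below coordinate 0 are clipped and the gene flagged for exclusion.

## Normalization

x ↦ log(x + 1), then min-max per column. Natural log and pseudocount 1
are defaults (both config-exposed); the pseudocount guards log(0) and is
negligible against typical coverage values. Columns are normalized
*within each CpG class* (and on the union for the all-genes model): each
model's feature space is self-contained, matching the per-set training
design. Constant columns map to all-zeros — they carry no information and
keeping the [0, 1] contract avoids NaNs downstream. By default the
response is normalized the same way; `normalize_response=False` keeps raw
window means, which is what the synthetic recovery studies use since
their planted truth is linear on the response scale.

## Solver

Accelerated proximal gradient (FISTA) with adaptive restarts on objective
increase. Because the fusion graph is a disjoint union of chains, the
proximal operator of the combined penalty is exact and cheap: 1-D
total-variation denoising (a taut-string forward scan, linear time per
chain, numba-compiled) followed by elementwise soft-thresholding. The
step is 1/L with L = 2σ²max(X_centered). The intercept stays unpenalized
by centering y and the columns of X during optimization and restoring β₀
afterwards. Convergence is declared after three consecutive iterations
with relative objective change below `tol` (default 1e-9); momentum
phases can stall for a single iteration without being at the optimum,
hence the patience. Hitting `max_iter` flags the result rather than
failing. The solver is validated against a generic convex minimizer (QP
reformulation of the objective) to 1e-6 in objective value, with KKT
subgradient certificates checked by bounded least squares.

A full solution-path algorithm is intentionally not implemented: the
penalty search only needs solutions at grid points, and grid solutions
from a prox-based solver are directly verifiable against an oracle.

Block structure and degrees of freedom: within each chain, maximal runs
of coefficients equal within 1e-6 relative to max|β| form blocks; df
counts blocks whose value is nonzero at the same tolerance. A relative
tolerance is needed because proximal solutions fuse only to solver
precision, unlike path solutions.

## Penalty selection

γ = λ₁/λ₂ is searched over {0} ∪ {10^i | i = −5..5} (γ = 0 is fusion
only); λ₂ over a geometric grid of 30 values spanning 5 decades downward
from λ₂,max, the smallest power-of-two λ₂ (found by doubling search,
λ₁ = 0) that fuses every chain flat — at that point the fit equals OLS on
per-TF mean features. Grid sizes are config-exposed; the cheaper studies
below use coarser grids. Nested CV uses 5 outer and 3 inner folds, folds
drawn deterministically from the run seed; the (γ, λ₂) pair minimizing
mean inner-fold RSS wins, with ties going to the larger λ₂ then larger γ
(parsimony). Outer folds record test RSS plus Pearson and Spearman
correlation; Pearson is the headline performance number. The final model
is refitted on all data at penalties selected by one more inner-style CV
on the full data (the per-fold selections need not agree, so a single
well-defined selection rule is applied to the union).

## Association inference

The F-statistic compares the full fit against the same coefficient
vector with one TF's k coefficients zeroed — no refit, which makes the
test cheap but approximate: the zeroed model is not the optimal reduced
model, so RSS₀ is an upper bound and the test tends to be
anti-conservative for TFs the penalty kept small. The df difference is
taken as df(M_full) − df(M₀), the conventional positive orientation. N is
the number of genes in the class used for the final refit. p-values come
from the F survival function; no multiple-testing correction is applied
across TFs — the fixed α = 0.005 plus ten-lowest-p-values rule is the
selection scheme, and in practice far more than ten TFs reach α, so the
*ranking* carries the information. A TF whose coefficients are entirely
zero in the full model is reported untested (F = 0, p = 1).

## CpG partition

CpG dinucleotides are counted on the ±500 bp window (a CG straddling a
profile-bin boundary belongs to the bin of its C). A two-component
Gaussian mixture is fitted to the raw per-gene totals by EM (k-means
initialization, 10 restarts, fixed seed) — fitting the totals avoids the
arbitrary histogram-bin parameter. The class threshold is the root of
w₁N(x; μ₁, σ₁²) = w₂N(x; μ₂, σ₂²) inside (μ₁, μ₂), found by bracketed
root-finding; genes below it are CpG-poor. Degenerate fits (vanishing
component, collapsed modes, no interior root) raise with a diagnostic
rather than returning a silent split.

## Partial correlations

For each unordered HM pair, both marks are residualized by OLS (with
intercept) on all remaining marks, and the Pearson correlation of the
residuals is tested by permuting one residual vector (default n = 10000).
The default test is two-sided on |ρ| with the add-one estimator
(1 + #exceed)/(n + 1): strongly negative correlations are then testable
and the p-value is never exactly zero. The literal one-sided
count-over-n estimator sits behind flags. Bonferroni correction is over
the C(n_hm, 2) pairs within one class at α = 0.01.

## Performance comparison

Rich-vs-poor model performance per HM is compared by the unpaired exact
Wilcoxon rank-sum test on the five outer-fold Pearson values — fold test
sets contain different genes in the two classes, so a paired test is
undefined. Benjamini-Hochberg correction is applied across the HMs of one
run at α = 0.05. An all-genes model is trained alongside to expose
training-set-size effects.

## Synthetic data

The generator emulates exactly the structure the analysis assumes: CpG
counts from a two-Gaussian mixture (defaults: weights 0.27/0.73, modes
20 ± 5 and 60 ± 10 counts, mirroring the ~27/73 poor/rich split of real
promoter sets with clearly separated modes); log-normal raw TF bin
signals (log-scale location 0, scale 1); HM responses as planted sparse
block-constant linear combinations of the class-normalized TF bins plus
Gaussian noise, shifted to a nonnegative minimum. Planted coefficients
act on the *normalized* feature space so recovery compares like with
like. One seed drives three documented sub-streams (counts, TF matrix,
noise), making every part bit-reproducible. What it does *not* emulate:
read-level noise, peak shapes, replicate structure, correlated TF
occupancy, or any nonlinearity — so passing recovery tests demonstrates
correctness of the machinery under the model's own assumptions, not
performance on real ChIP-seq data.

The benchmark recovery design uses 2000 genes, 50 TFs, 10 bins, five
planted TFs per class with block-constant coefficients (magnitudes
1.2–2.0), one TF flipping sign between classes, and one class-exclusive
TF per class. Noise is calibrated per replicate so the planted signal
explains 80% of within-class response variance. Penalties for the
benchmark fits are selected once by 3-fold CV on an independent tuning
replicate and reused across the 20 evaluation replicates — tuning and
evaluation data stay disjoint while keeping the study at one fit per
class per replicate. The class-exclusivity metric is per exclusive TF:
detected in its home class's top-10 and absent from the other class's.
Because the zero-out F-test is anti-conservative, roughly 15–20 of 50
TFs reach α = 0.005 per model and the non-planted top-10 slots are
filled by near-chance ranking among nulls; a specific null TF therefore
lands in a given top-10 about 11% of the time, which bounds attainable
exclusivity around 0.9.

## Numerical choices and degenerate inputs

- Constant predictions (fully penalized fits) get correlation 0, not NaN;
  constancy is checked bitwise since the standard deviation of a
  bitwise-constant float array can round to ~1e-17.
- Ties in inner-fold RSS: larger λ₂, then larger γ.
- Rank-deficient conditioning sets in residualization fall back to
  minimum-norm least squares with a logged warning.
- Residual variance below 1e-20 of the target's total variance is treated
  as exact collinearity and rejected.
- Non-finite inputs to the solver raise immediately; unconverged fits are
  flagged, and association scoring refuses flagged fits.

## Problem sizes in bundled studies

The test suite and the acceptance script size their simulations to a few
minutes on one CPU: 50 oracle instances (≤ 30 genes, ≤ 12 features), 20
benchmark replicates at 2000 × 500, mixture fits at n = 10⁴–2·10⁴, 500
permutation-calibration replicates at n_perm = 999, 20 sign-flip
replicates at 300 genes per class, and a 200-gene, 3-HM pipeline run for
determinism checks. These sizes are the package's validation conditions;
larger runs only change runtime.

## Known limitations

- The zero-out F-test's null calibration is not characterized; only
  relative ranking of planted vs null TFs is asserted and interpreted.
- Linear, class-homogeneous associations only.
- The all-genes model mixes class-specific normalizations, so it is a
  size control, not a pooled estimate of class models.
- λ₂ grids approximate the solution-path knots; extremely fine penalty
  structure between grid points is not resolved.
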