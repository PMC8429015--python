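# Methods

## Model

The package addresses prediction of conversion from mild cognitive
impairment (MCI) to Alzheimer's disease (AD) from two morphological
"views" of structural MRI — regional cortical thickness and regional
cortical volume (d regions per view, d = 78 by default). Rather than
classifying MCI subjects in the raw feature space, the method learns a
pair of linear projections into the c-dimensional class-indicator
("label") subspace using *auxiliary* subjects — AD patients and normal
controls (NC) — whose class separation is much stronger than that of
progressive (pMCI) versus stable (sMCI) MCI subjects. Using auxiliary
subjects also avoids double-dipping: the target subjects never
influence the representation they are later classified in.

With X_CT, X_CV ∈ R^{d×n} the aligned auxiliary feature blocks and
Y ∈ {0,1}^{n×c} the one-hot class matrix, the projections
U, V ∈ R^{d×c} minimize

Q(U,V) = λ(‖Y − X_CTᵀU‖²_F + ‖Y − X_CVᵀV‖²_F)
       + (1−λ)‖X_CTᵀU − X_CVᵀV‖²_F
       + α(tr(UᵀX_CT L_CT X_CTᵀU) + tr(VᵀX_CV L_CV X_CVᵀV))
       + β(‖U‖²_F + ‖V‖²_F),

i.e. a label regression per view, a cross-view consistency term (both
views of a subject should land at the same point in the label
subspace), a graph-Laplacian penalty preserving each view's
neighbourhood structure, and a ridge term. L = D − W is the
unnormalized Laplacian of a k-nearest-neighbour graph with heat-kernel
weights w_ij = exp(−‖x_i−x_j‖²/(2σ²)).

Held-out (MCI) subjects are mapped through the fitted model,
Fea_CT = Z_CTᵀU and Fea_CV = Z_CVᵀV, and fused into the final
biomarker by a self-weighted convex combination

Fea = η·|Fea_CT|⊙|Fea_CT| + (1−η)·|Fea_CV|⊙|Fea_CV|,

an elementwise weighted square that amplifies confidently-placed
coordinates. Fea is nonnegative, quadratically homogeneous in the
projected features, and affine in η.

## Optimization

Q is convex in each block with the other fixed. Starting from
U = V = 0, the solver alternates the exact minimizers

U ← (X_CT X_CTᵀ + α X_CT L_CT X_CTᵀ + βI)⁻¹ (λ X_CT Y + (1−λ) X_CT X_CVᵀ V)

and its mirror image for V. Each system matrix is symmetric positive
definite for β > 0 and is solved by Cholesky factorization, never by
explicit inversion. Exact block minimization makes the objective trace
nonincreasing; the implementation raises if it ever increases beyond
1e−9 relative. Convergence is declared when
|Q_t − Q_{t−1}| / max(1, Q_{t−1}) < tol (default 1e−8, max 200
iterations). A caveat discovered in testing: an objective tolerance of
1e−10 can still leave the iterate ~1e−6 away from the exact fixed
point in parameter space on ill-conditioned instances, so
self-consistency checks run the solver at 1e−13.

## Scaling and the intercept question

The label regression Xᵀ U has no intercept. Raw morphometric features
are large and positive (thickness in mm, volume in mm³), and it is
precisely this common positive baseline that lets a linear map reach
the constant part of the 0-1 indicator targets. Centering the features
removes that component: the fitted subspace coordinates then become
sign-symmetric across classes (≈ ±s instead of ≈ 1/0), and the
magnitude-based fusion |x|·|x| erases the class information entirely —
measured as chance accuracy on an otherwise cleanly separable cohort.

The default preprocessing is therefore **scale-only** standardization:
each feature is divided by its auxiliary-set standard deviation (to
reconcile the mm vs mm³ unit gap) but not centered. The same transform
fit on the learning set is applied to target subjects. Full z-scoring
(`standardize="zscore"`) and no rescaling (`"off"`) remain available;
the z-score mode is appropriate only if the downstream representation
is used with a sign-aware classifier rather than the squared fusion.

## Graph construction choices

The neighbourhood rule as written is directed (x_i ∈ N_k(x_j)); the
graph is declared undirected, so the weight matrix is symmetrized by
elementwise maximum (union-kNN), which preserves every stated nonzero.
Consequences: every node has degree ≥ k, and the total number of
nonzero entries is ≤ 2nk, but an individual hub node may exceed 2k
incident edges. Neighbour ties break toward the lowest subject index.
The bandwidth σ defaults to the median Euclidean distance over the
retained directed kNN pairs (median heuristic), with a fixed-σ
override; if all retained pairs coincide the bandwidth falls back
to 1.

## Hyperparameters

Defaults are the selected combination from the reference evaluation:
λ = 0.1 (label terms get little weight relative to cross-view
consistency), α = 0.1, β = 10 (strong ridge — the biomarker needs a
stable direction, not a tight fit), k_CT = 11, k_CV = 3, η = 0.03
(the volume view dominates the fusion). The grid-search ranges are
λ ∈ {0.1,…,0.9}, α ∈ {10⁻³,…,10¹}, β ∈ {10⁻¹,10⁰,10¹},
k ∈ {3,5,…,15} per view, η ∈ {q·10⁻², q·10⁻¹ : q = 1..9} — 119,070
combinations; the search runs at a reduced repeat count (5) for
screening, and its top row is explicitly a selection-on-evaluation
quantity.

## Evaluation protocol

Stratified 10-fold cross-validation repeated 20 times; folds are dealt
round-robin per class after a seeded shuffle, so per-fold class counts
differ by at most one (a class smaller than the fold count triggers a
warning). Metrics — accuracy, sensitivity (pMCI = positive),
specificity, and rank-based (Mann–Whitney, ties = ½) AUC — are
computed per repeat from the pooled out-of-fold predictions, which
avoids undefined sensitivity/specificity on tiny folds; an undefined
metric is reported as NaN, never silently zero. Classifier scores for
AUC are the signed decision-function values for SVMs and the leaf
class-probability for decision trees. Paired two-sided t-tests compare
per-repeat accuracies of two runs that share fold seeds; identical
zero-variance differences give p = 1 by convention, nonzero constant
differences are flagged as p = 0.

Two learning protocols are implemented. Under `auxiliary`, the
projections and scaler are learned once on the full AD/NC set and
cross-validation trains only the classifier — legitimate because no
target information enters the representation. Under `self`, the
projections are relearned inside every fold on the target training
subjects only; the fold-fitting routine slices training columns before
computing any statistic, so the leakage audit (perturbing held-out
columns and asserting an unchanged fit) holds by construction and is
asserted in tests.

## Synthetic cohorts

The generator emulates the structure the method assumes, not ADNI
itself. Each subject draws a latent signal per view as
μ_g + (ρ·e_shared + (1−ρ)·e_private)/√(ρ² + (1−ρ)²) with i.i.d.
standard-normal e, keeping within-class signal spread at exactly unit
sd for every cross-view coupling ρ; independent N(0, noise_sd²) noise
is added. Only the first `n_informative` features (default 10 of 78)
carry class signal: AD and NC deviate by ±δ/2 around a common positive
baseline (default 10, playing the role of the raw-morphometry offset
discussed above), and pMCI/sMCI sit at the mix-weighted combination
(default mix = 0.25, so pMCI = 0.75·AD + 0.25·NC in mean) — the
qualitative premise that pMCI resembles AD and sMCI resembles NC, not
a calibrated quantity. One seeded generator per call; identical specs
give bit-identical cohorts.

What the generator does **not** emulate: realistic inter-regional
covariance, site/scanner effects, age and sex confounds, non-Gaussian
tails, or any spatial structure of the AAL parcellation. Passing tests
therefore demonstrate the correctness and internal soundness of the
pipeline and its protocol, not clinical performance on real cohorts.

Study conditions used by the simulation-level checks (chosen once):

- recovery: δ = 3, noise_sd = 1, ρ = 0.7, 100 per target group,
  150 per auxiliary group, linear SVM, 20 repeats;
- chance-level null: δ = 0, 50 per target group, averaged over 6
  independent cohorts per classifier family — a single finite cohort
  carries chance label–feature correlation of order ±0.05 that
  repeat-level standard errors cannot represent, so the null check
  compares the across-cohort mean against the across-cohort standard
  error;
- auxiliary-vs-self: δ = 2, ρ = 0.7, small target (40/group) against
  a large auxiliary pool (150/group), where transfer should help most;
- size sweep: δ = 1.5 (moderate difficulty so auxiliary size matters),
  balanced subsets of 50/150/250, 10 resamples, 5 CV repeats per
  resample.

## Numerical and degenerate-input conventions

β > 0 is required (positive definiteness of the block systems);
λ ∈ (0, 1], with λ = 1 the supported boundary that switches the
cross-view term off (used by the ridge-limit identity). Constant
features receive unit scale in the standardizer. A class present in
`class_order` but absent from the data is accepted with a warning (the
optimization remains well-posed and the case is useful in testing);
an unknown label is an error. k is clipped to n − 1 when a training
fold is smaller than the configured neighbour count. Feature tables
are written with 17 significant digits and read with round-trip float
parsing, so write→read is exact.

## Known limitations

- Exactly two views; no kernelization, no more-than-two-view fusion.
- The unnormalized Laplacian only; no alternative affinities.
- Grid search evaluates on the same data it ranks on; the ranked table
  is for exploration, and the top row is an optimistic estimate.
- The fusion step discards the sign of the subspace coordinates by
  design; it presumes the projection targets are reachable (see the
  scaling discussion), which is the uncentered regime.
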