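# Methods

## Problem setting

A sensory neuron is modelled as a linear-nonlinear-Poisson (LNP) cascade:
the stimulus `s` (a flattened image patch or a time-embedded flicker
segment, dimension `D`) is projected onto a small number `K` of feature
vectors, a static nonlinearity maps the projections to a firing rate, and
spikes are generated by a Poisson process.  The estimation problem is to
recover the `K`-dimensional feature subspace from a stimulus matrix
(`N x D`) and a per-bin spike train, for stimulus distributions that are
*not* Gaussian — the regime where classical spike-triggered covariance
(STC) is biased by higher-order stimulus correlations.

All estimators in this package work on the binarised response
`r = min(counts, 1)`; multi-spike bins are rare at the operating points
simulated here (mean spike probability 0.15) and binarisation keeps every
likelihood Bernoulli.

## The second-order minimal model

The minimal (maximum-noise-entropy) model constrained by the observed
mean spike probability, the spike-triggered average `⟨r s⟩`, and the
spike-triggered second moment `⟨r s sᵀ⟩` is the logistic model

    P(spike | s) = 1 / (1 + exp(a + h·s + sᵀJs)),

with `1 + D + D(D+1)/2` free parameters (`J` symmetric).  It is the
least-biased model consistent with those moments: it maximises the noise
entropy, equivalently minimises the stimulus/response mutual information
given the constraints.  Imposing the moment constraints is equivalent to
maximising the Bernoulli log-likelihood, which is concave in `(a, h, J)`,
so any sensible ascent reaches the global optimum; we use L-BFGS (a
quasi-Newton ascent with line search — interchangeable with nonlinear
conjugate gradients here precisely because the problem is concave, which
the test suite verifies by checking initialisation independence to 1e-6
relative).  The likelihood gradient components are the (model − empirical)
moment mismatches, so at full convergence the defining constraints hold to
numerical tolerance; `check_constraints` reports them directly.

Sign convention: a more negative polynomial argument means a higher spike
probability, so *negative* eigenvalues of `J` mark excitatory (variance-
expanding) directions and positive eigenvalues suppressive ones.  All
eigen-analysis ranks by `|eigenvalue|`, which makes the convention
immaterial downstream.

Overfitting control: the data is split into four *contiguous* quarters
(preserving any temporal structure); each fit trains on three quarters
while the held-out quarter's likelihood is evaluated at every iteration;
the parameters at the held-out maximum are returned, and the four
parameter vectors (the full `(a, h, J)` triplet) are averaged before
diagonalisation.  `folds=1` disables early stopping and trains to full
convergence — the mode used when exact moment matching is wanted.

Stimuli are standardised before fitting: per-dimension zero mean and a
single *global* scale giving unit average variance.  Using one global
scale (not per-dimension) means feature directions are identical in
standardised and raw units; `to_raw_units` converts `(a, h, J)` exactly
using the stored record.

## Nonlinear MID

The per-spike information carried by a projection `x = v·s` is the
Kullback-Leibler divergence between the spike-conditional and prior
distributions of `x`.  Linear MID maximises this over one or two
directions; the histogram estimator makes more than two dimensions
impractical (curse of dimensionality), so the package refuses `n_dims > 2`.

Nonlinear MID lifts the stimulus to
`y(s) = (s, upper-triangle of s sᵀ)` with off-diagonal products doubled,
so `v·y(s) = h·s + sᵀJs` for `v = (h, triu(J))`: one direction in the
expanded space encodes a full quadratic form, and the search stays
one-dimensional no matter how many features `J` contains.  The expansion
is handled implicitly — projections and gradients are computed from the
raw `N x D` matrix, so the `N x (D + D(D+1)/2)` matrix is never built and
image patches up to at least 8x8 (`D = 64`, 2144 expanded dimensions)
stay cheap in memory.

### Estimator and surrogate gradient

`info_per_spike` uses quantile bins of the prior projection distribution:
16 bins for one dimension, 12x12 for two.  Quantile binning makes the
estimate exactly invariant to strictly monotone transforms of the
projection (a property the tests assert).  An even 1-d bin count is
deliberate: it places the median on a bin edge, so the analytic oracle
"spike iff the projection exceeds its median → exactly 1 bit" holds
exactly; with an odd count the oracle value would be `(B-1)/B` bits.  Bin
counts are exposed in every fitting function.

The hard-binned objective is piecewise constant in `v`, so it has no
useful gradient.  The optimiser therefore ascends a smoothed surrogate:
Gaussian soft-bin memberships centred on the projection quantiles
(bandwidth 0.9x the median centre spacing, centres treated as constants
within an iteration).  The surrogate is differentiable and its analytic
per-sample gradient is verified against central finite differences in the
tests.  All accept/reject decisions, early stopping and reported numbers
use the *hard* estimator; the surrogate only proposes search directions.

### Search

Stochastic gradient ascent on re-randomised minibatches (default 70% of
the training bins) with simulated annealing: a proposal that lowers the
hard training information is still accepted with probability
`exp(ΔI / T_k)`, `T_k = T0 · decay^k` (defaults `T0 = 0.02`,
`decay = 0.9`).  The step size adapts (x1.1 on accept, x0.6 on reject)
and directions are renormalised every step — the objective depends on the
direction only, not the scale.  Early stopping and four-fold averaging
mirror the minimal-model protocol; fold directions are Procrustes-aligned
(sign for 1-d, an orthogonal 2x2 rotation for 2-d) before averaging,
since the objective is invariant to those symmetries.  nMID starts from
the minimal-model estimate, which both cuts runtime and, because the
initial point is in the trace, guarantees the returned training
information never falls below the initialisation's.

## STC baseline

`C_spike` is the covariance of the spike-triggered ensemble centred on
the spike-triggered mean (standard STC practice); `ΔC = C_spike −
C_prior` is diagonalised and each eigenvector is multiplied by
`(C_prior + λI)^{-1}` to undo stimulus correlations, then renormalised.
The ridge term `λ` tames noise amplification along poorly sampled
directions.  `scan_ridge` picks the `λ` maximising the overlap with
*known ground truth* — only possible in simulation, and deliberately
generous to STC, since the cross-validated estimators get no analogous
tuning.  Equal-magnitude eigenvalue ties are broken by ascending index.

## Eigenvalue significance

500 Gaussian random symmetric matrices are drawn with independent
elements matched in variance to the empirical elements of `J` (upper
triangle mirrored); their pooled eigenvalues give one global pair of
2.5th/97.5th-percentile thresholds (linear interpolation), and eigenvalues
of `J` outside them are flagged.  On null kernels the false-positive rate
calibrates to the nominal 5% (tested at D=20 over 200 replicates).

Small-D caveat: the null's element variance is matched to `J` itself, so
a strong signal inflates its own null.  The null eigenvalue spread is
roughly `±2·sd·√D` with `sd² ≈ Σλ²/D²`; at `D = 8` with three comparable
planted eigenvalues the detection edge exceeds each individual
`|λ|`, and typically only the largest one or two are flagged even when
all three are recovered almost perfectly by the eigenvectors.  The flagged
features still lie inside the true subspace (the subspace-projection
measure evaluates containment when ranks differ), but users working at
small `D` should read the flag count conservatively.  At `D = 50+` with a
few strong features — the regime the procedure is meant for — the edge
sits far below the signal.

The linear kernel `h` can carry one extra feature: its projection onto the
significant eigenvectors is subtracted, leaving an orthogonal residual
whose Euclidean norm is reported next to the eigenvalue magnitudes.  The
two scales are not strictly commensurate (curvature vs slope of the
log-odds); both raw numbers are reported and no unit conversion is
attempted.

## Subspace projection

Recovery is scored by the product of the cosines of the principal angles
between the recovered and true subspaces: orthonormalise each basis by
SVD, take the singular values of `Q_a Q_bᵀ`, multiply.  This is the
normalised intersection of spanned volumes — 1 iff the spans coincide, 0
iff some direction of the smaller span is orthogonal to the other — and is
invariant to any invertible recombination or rescaling of either basis
(asserted to 1e-10 in the tests).  For bases of unequal rank the
`min(K, K')` principal angles are used, so a low-rank basis contained in
a higher-rank one scores 1.

## Simulated cells and stimuli

* **Energy cell** — two unit-norm quadrature Gabor features (90° phase
  difference), spike probability `min(1, c·[(e₁·s)² + (e₂·s)²])`:
  phase-invariant, the classic V1 complex-cell model.
* **Divisive cell** — the energy numerator divided by one plus the summed
  squared projections onto four suppressive features: a quadrature pair
  at the orthogonal orientation in the receptive-field centre and a
  parallel-orientation pair in the surround annulus.  Six genuinely
  independent ground-truth dimensions (rank asserted).
* **Quadratic-logistic cell** — a neuron inside the minimal-model class,
  with explicit `(a, h, J)`.

Gabor parameter defaults (frequency 0.3 cycles/pixel, envelope ~2 px on an
8x8 grid, centre radius 2.4 px, surround to 5.5 px) are package choices
tuned to give well-conditioned, visually Gabor-like features at small
patch sizes; all are exposed.

Calibration sets the mean spike probability over the stimulus ensemble to
a target (default 0.15) by deterministic bisection — on the multiplicative
scale for energy/divisive cells, on the bias `a` for quadratic-logistic
cells (the only monotone free parameter there).  Spike counts are Poisson
with intensity `−ln(1 − p)`, so that `P(count ≥ 1) = p` exactly: the
binarised response then has precisely the calibrated mean, while
multi-spike bins still occur with their natural Poisson frequency.

Synthetic naturalistic patches are Gaussian random fields shaped in the
frequency domain to a `1/f^exponent` power spectrum (default exponent 2),
passed through a pointwise exponential (`exp(0.45 g)`, giving lognormal
marginals with positive excess kurtosis ~4) and mean-subtracted.  This
reproduces the two statistics that break STC — spatial correlations and
heavy tails — but *not* the structured content of photographic databases
(edges, occlusions, phase alignment across scales).  Recovery gaps between
STC and the information-theoretic methods are therefore smaller here than
on real photographic patches; passing tests demonstrate the ordering and
the estimators' correctness, not the magnitude of the advantage on real
imagery.  `load_image_patches` can crop real database images when a
directory of them is available.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run desk-scale versions of the
recovery experiments: 8x8 patches (`D = 64`), `N = 5·10⁴` bins at spike
probability 0.15 (~7.5k spikes) for the naturalistic experiments,
`N = 10⁵` for the white-noise concordance check, `D = 8`, `N = 5·10⁴` for
within-class parameter recovery.  Minimal-model fits cap L-BFGS at
50–200 iterations under early stopping (the held-out maximum is reached
well before) and 3000 iterations at `tol = 1e-12` for full-convergence
moment matching.  nMID runs 25–40 annealing iterations from the
minimal-model start.

Degenerate inputs: constant ensembles cannot be standardised (error); a
training split without spikes raises an error naming the fold; a zero
kernel makes the significance test warn and flag nothing; `C_prior + λI`
condition numbers above 1e12 raise an error advising a larger ridge.

## Known limitations

* Binary-response likelihood only; no Poisson-count minimal model.
* Linear MID is limited to two dimensions by construction.
* The minimal model is second order; neurons with strong higher-order
  structure are captured only through the quadratic projection that nMID
  shares, not through higher powers.
* Fold averaging assumes the four fold solutions sit in the same basin up
  to the handled symmetries; for nMID this is enforced by the shared
  minimal-model start.
* The pooled-null significance test's small-D conservatism described
  above.
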