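# Methods

## The model

Each group's nine scores (15T, 15R, DSB, FLU, STR, TMT, FAP, FID, FEF)
are treated as a multivariate Gaussian vector; the object of interest is
the conditional-dependence graph, i.e. the pattern and magnitude of
partial correlations

    rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj),

where Theta is the precision (inverse covariance) matrix. The precision
matrix is estimated per group by the graphical lasso,

    max_Theta  log det(Theta) - tr(S Theta) - lambda * sum_{i != j} |Theta_ij|,

with S the group's Pearson correlation matrix. The L1 penalty is applied
to off-diagonal entries only: penalizing the diagonal would shrink
precision variances and thereby distort the rescaled partial
correlations, and the dominant convention in psychometric network tools
penalizes off-diagonals only. Estimating on the correlation (rather than
covariance) matrix makes the penalty scale-free, so the resulting
network is invariant to affine rescaling of any score column.

The penalty strength is chosen by minimizing the extended BIC over a
descending log-spaced grid of 100 values from `lambda_max = max_{i!=j}
|S_ij|` (where the network is empty) down to `0.01 * lambda_max`:

    EBIC(lambda) = -2 l(Theta) + E ln(n) + 4 gamma E ln(p),
    l = (n/2) (log det Theta - tr(S Theta)),

with E the number of nonzero upper-triangle off-diagonal entries and
`gamma = 0` by default (plain BIC). Ties within 1e-9 are broken toward
the larger penalty (sparser model) for determinism.

### Solver

The solver is Friedman-style block coordinate descent on the covariance
side: each column update is a lasso problem solved by coordinate
descent, with the diagonal of the working covariance fixed at `diag(S)`
(the unpenalized-diagonal convention). The precision matrix is recovered
from the converged column coefficients; an off-diagonal entry is an
exact zero iff both of its column problems produce a zero coefficient.
Convergence is declared when the largest change of the working
covariance in a sweep falls below 1e-6. At `lambda = 0` the exact
maximizer is `S^-1` and is computed directly (coordinate descent
converges too slowly on ill-conditioned matrices to meet the same
accuracy). The inner loop is numba-compiled because the bootstrap
re-fits the full penalty path thousands of times. Solutions are verified
in the test suite by the KKT stationarity conditions of the stated
objective (subgradient violation below 1e-6) and by the matrix-inversion
oracle at `lambda = 0`.

## Bootstrap inference

Uncertainty is quantified by the nonparametric bootstrap of the *whole*
pipeline: each of B = 1000 (default) replicates resamples subjects with
replacement (n out of n), re-selects the penalty by BIC, re-estimates
the network, and re-detects communities. 95% confidence intervals are
the empirical 2.5th/97.5th percentiles (linear interpolation between
order statistics) of the bootstrap distributions — for every edge weight
and every node strength. Nonoverlap of two groups' closed intervals is
reported as evidence of a group difference; touching endpoints count as
overlap. Percentile intervals for centrality indices are known to be
imperfectly calibrated; no correction is applied, and the coverage study
below quantifies the behavior for edge weights. Per-bootstrap RNG
streams are spawned deterministically from `(seed, bootstrap index)`, so
ensembles are reproducible and order-independent. A resample with a
constant column is redrawn (counted, with a hard error past 5% of B).

## Centrality and communities

Centrality is node strength: the sum of absolute incident partial
correlations. Communities are found by maximizing modularity with the
Louvain heuristic; because the networks carry negative edges, the
quality function is the asymmetric signed modularity

    Q = Q+ - (s- / (s+ + s-)) Q-,

with Q+/Q- the Newman weighted modularity of the positive /
absolute-negative subnetworks and s+/s- their total weights. Positive
weight dominates the partition; negative weight discourages
co-assignment; with no negative edges the formula reduces exactly to
Newman's Q. Both the objective and the Louvain move gains are expressed
through a single modularity matrix M with `Q = sum_ij M_ij
delta(c_i, c_j)`, which makes the greedy gains exact for the signed
objective. An absolute-weight fallback (`modularity: absolute`) treats
|W| as a positive graph. The resolution parameter is fixed at 1.

Louvain is restarted 100 times (shuffled node orders from per-restart
seeds) and the maximum-Q solution kept, with exact ties broken by the
lexicographically smallest canonical membership vector. Community ids
are canonicalized by first appearance in label order so outputs are
diff-stable. On graphs of <= 6 nodes the test suite compares best-of-100
Louvain against exhaustive enumeration of all set partitions
(Bell(6) = 203).

Community stability is summarized by the co-assignment matrix: P_ij is
the fraction of bootstrap partitions placing nodes i and j in the same
community. It is invariant to community relabeling within each
replicate.

## Synthetic cohorts

Real score data for this design are not publicly available, so the
generator plants the truth instead: each group is a multivariate
Gaussian whose standardized precision matrix encodes a block structure —
every within-block pair gets a chosen partial correlation, cross-block
pairs are conditionally independent, and individual pairs can be pinned
to other values. If the requested pattern is not positive definite, the
matrix is diagonally loaded (add eps*I, doubling eps until the smallest
eigenvalue exceeds 1e-8) and re-standardized; loading shrinks the
achieved partial correlations, and all ground-truth comparisons use the
loaded model's actual values. Note the feasibility bound: a complete
block of k nodes at equal partial correlation r requires r < 1/(k-1),
so e.g. a 5-node block at 0.30 is loaded down to ~0.24.

The study fixture has three groups of n = 67 / 66 / 61 with identical
means and SDs on plausible raw-score scales (e.g. 15T ~ N(45, 10); the
scales are conventional, since per-group score moments are not public,
and are irrelevant to estimation, which standardizes). All groups share
a strong verbal-memory edge (15T-15R at 0.6) and a DSB-FLU edge (0.4).
The frontal model merges {15T, 15R, DSB, FLU} into one block (within
0.15, the largest value keeping the block comfortably positive definite
next to the 0.6 and 0.4 pins); the control and non-frontal models keep
the memory pair separate from {DSB, FLU} (within 0.3). All models carry
an executive-speed block {STR, TMT} and a behavioral block {FAP, FID,
FEF}.

What the generator does *not* emulate: nonnormal margins (real time
scores are skewed; TMT is therefore routed to a rank-based test, but the
generator is Gaussian by contract), test-wise missingness patterns,
demographic covariates, and any mean differences between groups.
Passing tests therefore certify the estimation machinery under
Gaussian, complete-case, equal-means conditions — not robustness to
violations of them.

## Validation studies and problem sizes

`cognet.benchmarks` (driven by `scripts/acceptance.py` and the
acceptance tests) measures, at sizes chosen to keep a single-CPU run in
minutes:

- oracle agreement of unpenalized partial correlations with the
  regression-residual definition (n = 10,000; agreement ~1e-15);
- best-of-100 Louvain vs exhaustive partition search on 100 random
  signed graphs of 4-6 nodes;
- planted-structure recovery at n = 5,000 (50 replicates);
- bootstrap CI coverage for planted edges at n = 500, B = 200
  (25 outer replicates, pooled over the 16 true edges);
- co-assignment separation of the two planted blocks at n = 2,000,
  B = 200 (within-block proportions vs between-block);
- null calibration on 9 independent Gaussians at n = 65 (the study's
  group scale): how often the selected network is empty;
- type-I calibration of the ANOVA stage on the equal-means fixture
  (500 replicates, pooled over the nine variables);
- bit-level reproducibility of two identically-seeded pipeline runs.

## Known limitations

- **BIC overselection at large n.** With strong true edges, the
  likelihood cost of the lasso shrinkage bias grows with n faster than
  the `ln(n)` penalty of admitting tiny spurious edges, so the BIC
  minimum migrates toward the small-lambda end of the path and the
  selected network carries a tail of near-zero false edges (measured
  false-edge rate ~0.15 per absent edge at n = 5,000, with sensitivity
  1.0 and false edges typically |w| < 0.01). This anti-sparsistency of
  BIC-selected graphical lasso is a property of the criterion, not of
  the solver (which satisfies the KKT conditions to ~1e-8). EBIC with
  `gamma > 0` (available via config) is markedly more conservative. At
  the study's own n ~ 65 the selection is conservative rather than
  liberal (empty-network rate 0.9 under the null).
- Percentile CIs inherit the estimator's shrinkage bias; measured edge
  coverage at n = 500 is ~0.94, within but below the nominal corridor's
  center.
- Listwise deletion is the only missing-data rule; the bootstrap
  requires a single n per group.
- Gaussian generator only; no nonparanormal transform is offered.
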