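# Methods

## Model

All analyses fit the single-kernel linear mixed model

    y = 1 mu + g + e,   g ~ N(0, K sigma_g^2),   e ~ N(0, I sigma_e^2),

with `y` a vector of entry means (LSMs) for n entries, so the residual
variance is on an entry-mean basis and `V = K sigma_g^2 + I sigma_e^2`.
The only fixed effect is the intercept; covariates, multiple kernels, and
heteroscedastic residuals are out of scope.

## Relationship matrices

Let `Z` be the n x m dosage matrix (counts in {0, 1, 2} of an arbitrary
designated allele), `Zbar` its column-mean-centered version (identical to
`P Z` with `P = I - 11'/n`, computed by column subtraction in O(nm)),
`Kbar = Zbar Zbar'`, and `p_j` the observed counted-allele frequency
(half the column mean; frequencies are deliberately not folded to MAF —
folding changes no centered quantity).

- **ASV**: `K_ASV = Kbar / ((n-1)^-1 tr(Kbar))`.  Exact identities, tested
  to 1e-10: `tr(K_ASV) = n - 1`, zero row sums, mean diagonal `(n-1)/n`,
  unit trace-scaling factor.
- **Normalized (GN)**: `Kbar / (n^-1 tr(Kbar))`; `tr = n` and
  `K_ASV = K_GN (n-1)/n`.  REML compensates matrix scale, so the two give
  identical ASV heritabilities and raw ratios differing at O(1/n).
- **VanRaden (VR)**: `(Z - 2p)(Z - 2p)' / (2 sum p_j(1-p_j))`.  With
  observed frequencies this is an exact positive multiple of `K_ASV`;
  the divisor is calibrated only under HWE.
- **Endelman–Jannink (EJ)**: the marker covariance
  `S = m^-1 Zbar Zbar' - zbar zbar'` (with `zbar` the mean centered
  column) shrunk toward `<S_ii> I` with intensity
  `delta = min(1, (n/m) / CV^2)`, where `CV^2` is the squared coefficient
  of variation of the eigenvalues of `S` excluding the structural null
  eigenvalue forced by centering (`S 1 = 0`); the mean outer product is
  re-added and the whole normalized by `2 <p_j(1-p_j)>`.  `delta = 0`
  reproduces VR to round-off.  Note that on *unstructured* (i.i.d.)
  genotypes the eigenvalue dispersion of `S` is pure Marchenko–Pastur
  noise with `CV^2 ≈ n/m`, so `delta` saturates at 1 and the matrix
  collapses toward the identity; `delta` is therefore always reported,
  and `force_delta=0` is available (and used in the simulation-protocol
  invariance experiment, where the shrunk matrix is uninformative by
  construction).
- **Yang (GCTA)** and **Astle–Balding (AB)**: per-marker standardization
  by `2 p_j (1 - p_j)`; AB averages standardized cross-products, Yang
  additionally replaces the diagonal by
  `1 + m^-1 sum_j (z^2 - (1 + 2p_j) z + 2 p_j^2) / (2 p_j (1-p_j))`.
  Their off-diagonals coincide exactly.  Monomorphic markers would divide
  by zero and are excluded with a warning (they are retained, contributing
  zeros, in the centered constructions).  Yang's modified diagonal can
  make the matrix indefinite; only symmetry is guaranteed for Yang and EJ.
- **IBS**: `(2m)^-1 sum_j (z_j - 1)(z_j - 1)' + 1/2` on the {0,1,2}
  coding; the only construction free of allele frequencies, and the only
  one that is not shift-invariant.

Missing genotype calls are mean-imputed per marker at ingestion, with the
imputation count recorded.

## ASV estimators

The ASV (half the average pairwise variance of differences between
entries, equivalently the expected sample variance) of the genetic values
is `theta_g = (n-1)^-1 tr(K P) sigma_g^2`; the residual ASV is
`sigma_e^2` unchanged, and `theta_y = theta_g + theta_e` exactly.  The
trace factor uses `tr(K P) = tr(K) - (mean row sum)`, not `tr(K)`, so
additive constants in uncentered GRMs (the +1/2 of IBS) cancel.  The ASV
heritability is `theta_g / theta_y`.  Two equivalent routes:

1. fit with `K_ASV` (factor 1, raw ratio already calibrated), or
2. fit with any GRM and multiply the fitted `sigma_g^2` by the factor.

The equivalence is exact in the intercept-orthogonal contrast space: for
GN/VR the kernels are exact scalar multiples of `K_ASV`, and for IBS the
non-proportional parts are rank-one terms involving the ones vector that
the contrast projection annihilates.  The dual-path property is verified
numerically to 1e-4 over 50 simulated datasets (observed agreement is
~1e-8, limited only by optimizer tolerance).  Raw and ASV heritabilities
are always reported side by side so the scaling bias is visible.  No
standard errors are attached to single-fit h2 estimates; replicate SDs
come from the simulation driver.

## REML

REML is evaluated on orthonormal Helmert contrasts `A` (`A1 = 0`,
`AA' = I`), where the restricted likelihood is the exact Gaussian
log-density of `Ay ~ N(0, A V A')`.  Fitting profiles the likelihood in
the ratio `lambda = sigma_g^2 / sigma_e^2` after one eigendecomposition
of `A K A'`: for eigenvalues `d_i` and rotated data `ỹ_i`,

    sigma_e^2(lambda) = (n-1)^-1 sum ỹ_i^2 / (lambda d_i + 1),

and the profile criterion is maximized over `log10 lambda` in [-10, 10]
by a 201-point scan followed by bounded scalar minimization to 1e-10 in
log-lambda; the scan endpoints are always compared and a `boundary` flag
is set when the optimum sits at the edge.  Numerical choices:

- variance floor `1e-10 x var(y)` prevents log(0); a constant phenotype
  returns floored components with a warning;
- kernels indefinite beyond `-1e-8 x` largest eigenvalue receive a
  diagonal jitter of `1e-8 x` mean diagonal (warning), then negative
  eigenvalues are clipped at zero;
- a kernel that is numerically a multiple of the identity triggers a
  non-identifiability warning (the two components are then separable only
  through the intercept projection).

GBLUP uses the GLS intercept and `g_hat = sigma_g^2 K V^-1 (y - 1 mu)`;
PEV is the mixed-model conditional variance `diag(G - G P_V G)` including
fixed-effect uncertainty, and selection reliability `1 - PEV/sigma_g^2`
is attached.  Held-out entries are predicted as
`sigma_g^2 K[test,train] V_train^-1 (y_train - 1 mu)`.

## Simulator

Genotypes are i.i.d. per cell with genotype probabilities
`((1-H)/2, H, (1-H)/2)` for dosages (0, 1, 2).  This holds the
counted-allele frequency at 1/2 and controls heterozygosity directly:
H = 0.5 is HWE at p = 1/2 (f = 0), H = 0 is complete inbreeding (f = 1),
via `f = (0.5 - H)/0.5`.  H = 1 is rejected (centered genotypes would be
degenerate).  An alternative law (`hwe_uniform`) draws per-marker
`p_j ~ U(0.1, 0.9)` with binomial dosages for robustness checks.

Traits are fully polygenic: every marker is causal with effect
`u_j ~ N(0, 1)`; genetic values are `g = Z u` on the raw dosages (the
centering difference is a constant absorbed by the intercept); residuals
are drawn with variance `sigma_e^2 = s_g^2 (1 - h2) / h2`, where
`s_g^2` is the realized sample variance of `g`, so the target
heritability refers to the realized genetic values of each replicate.
(The dimensionally consistent form of the residual-variance rule is used;
the Monte-Carlo tests confirm the realized heritability concentrates on
the target.)

What the simulator does *not* emulate: population structure and
admixture, realistic allele-frequency spectra and rare alleles, and
linkage disequilibrium along chromosomes.  Passing tests therefore
demonstrate calibration of the estimators under exchangeable, unlinked
genotypes — the regime in which the bias patterns of GRM scaling are
cleanly isolated — not robustness to structured real-world populations.

Replicate seeding is additive (`base_seed + rep` for genotypes, plus a
fixed offset of 10^6 for the trait stream) and recorded per row, so any
single replicate is re-runnable in isolation.

## Cross-validation

Entries are split 80:20 (train size = round(0.8 n)); variance components
are re-estimated within each training fold to avoid leakage from test
phenotypes; predictive ability is the Pearson correlation between
held-out predictions and test-set entry means; prediction accuracy
divides by `sqrt(h2)` — the standard upper-limit scaling — using the
fold's ASV-corrected estimate (the literal `r / h2` variant is exposed as
a config switch for comparison with reports that use it).  Predictive
ability is invariant across proportional kernels to ~1e-10 and across all
seven constructions to <1e-3 at realistic marker densities (the Yang/AB
diagonal deviations scale like 1/sqrt(m)).

## Problem sizes

The simulation grid is exposed at two scales: the full 36-cell design
(n in {250, 500, 1000}, m = 5000, 1000 replicates) reachable through the
`experiment` command with a design file, and a reduced desk scale
(n = 250, m = 1000, 200 replicates per cell) used by the test suite and
the acceptance script.  At the reduced scale one replicate (simulate,
build GRM, eigendecompose, fit) costs ~25 ms, a 12-cell grid about a
minute.  The package reports Monte-Carlo standard errors alongside cell
means; at the reduced scale the 2-SE band on a cell mean is ~±0.03.

## Known limitations

- The EJ shrinkage intensity follows the approximation
  `delta = (n/m)/CV^2`; on unstructured genotypes it saturates at 1 (see
  above), which is statistically defensible but makes the shrunk matrix
  unsuitable for prediction when the trait was generated from the
  genotyped markers themselves.
- Yang's matrix can be indefinite; fits then rely on the documented
  jitter and may warn.
- No dominance/epistasis kernels, pedigree matrices, MAF-binned or
  LD-weighted GRMs, and no multi-environment models.
- Heritability point estimates carry no analytic standard errors;
  uncertainty is quantified only by replicate SDs in simulation output.
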