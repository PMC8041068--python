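# Methods

## Model and estimation

The genetic model is y = Wα + Zγ + u + ε with polygenic effects
u ~ MVN(0, σ_g²K), i.i.d. marker effects γ_k ~ N(0, φ²), and residuals
ε ~ MVN(0, σ²I). All marker effects are random; only the intercept (and
optional covariates) are fixed. Three stages keep the computation at one
n × n eigendecomposition plus one n × n × m matrix product per analysis.

### Stage 1 — polygenic whitening

The ratio λ_g = σ_g²/σ² is estimated by REML on the reduced model
y = Wα + u + ε. The restricted log-likelihood is profiled over α and σ²
in the eigenbasis of K, leaving a one-dimensional maximization over λ_g:
a 121-point geometric grid on [1e-6, 1e6] brackets the optimum and Brent's
method refines it inside the best bracket; the returned optimum always
dominates the grid. Estimates that collapse to the lower bound are
reported as exactly 0 (no detectable polygenic variance); hitting the
upper bound sets a warning flag. λ̂_g is frozen for all later stages —
nothing downstream re-estimates it per marker.

The whitening operator is C = QΛ^(−1/2)Qᵀ from B = λ̂_g K + I = QΛQᵀ.
Eigenvalues of B are floored at 1e-8 before the inverse square root; in
exact arithmetic they are ≥ 1, so the floor only guards accumulated
round-off. C is symmetric, positive definite, and satisfies CBCᵀ = I to
1e-8 in the max norm (tested).

The kinship matrix is the centered cross-product K = X_cX_cᵀ/s with
s = trace(X_cX_cᵀ)/n, i.e. scaled to mean diagonal exactly 1, computed
from all markers (causal ones included). Any symmetric PSD matrix can be
supplied instead through the `kinship` argument or a TSV file.

### Stage 2 — correlation screening

Whitened markers are tested against the whitened phenotype with the
standard Pearson correlation t-test (t = r√((n−2)/(1−r²)) on n − 2 df,
two-sided). Markers with p strictly below the threshold (default 0.01)
form the candidate set. The loose default deliberately admits ~1% of null
markers so that slight correlations — minor-effect loci — survive to the
multi-locus stage. Zero-variance markers get p = 1 and are never
selected; |r| = 1 yields p = 0. The scan chunks over marker blocks for
multi-worker execution; each column is reduced with fixed-shape float64
kernels, so results are bit-identical for every block size and worker
count.

### Stage 3 — deshrinking ridge regression

The q candidates enter y = Wα + Zγ + ε with a single shared prior
variance φ² ("only two variance components"). Per the published
formulation, stage 3 uses the untransformed phenotype and genotypes: the
polygenic background already did its work selecting candidates
(`stage3_on_whitened=True` is available for sensitivity analysis).

With λ = φ²/σ² and H = λZZᵀ + I:

- γ̂ᴼᴿᴿ = λZᵀH⁻¹(y − Wα̂) = λZᵀPy, where α̂ is the GLS estimate and
  P = H⁻¹ − H⁻¹W(WᵀH⁻¹W)⁻¹WᵀH⁻¹;
- d_k = λZ_kᵀPZ_k = 1 − var(γ̂_k|y)/φ², the well-measurement factor;
- γ̂ᴰᴿᴿ_k = γ̂ᴼᴿᴿ_k/d_k, var(γ̂ᴰᴿᴿ_k) = var(γ̂ᴼᴿᴿ_k|y)/d_k;
- W_k = (γ̂ᴰᴿᴿ_k)²/var(γ̂ᴰᴿᴿ_k) ~ χ²₁ under γ_k = 0.

Using the fixed-effects-absorbed projection P (rather than bare H⁻¹) in
d_k is a deliberate choice: it propagates the uncertainty of α̂ into the
posterior variance, and it makes the method's defining identity exact —
for q = 1 with an intercept, γ̂ᴰᴿᴿ equals the ordinary least-squares slope
for *every* λ > 0, not only asymptotically. All the algebra runs through
the thin SVD of Z, which is simultaneously the n × n and the Woodbury
q × q form of H and remains cheap whether q < n or q > n.

**Choosing φ².** By default (`ridge_prior="stage1_prior"`) the prior
variance of a marker effect is carried over from the genome-wide fit:
σ_g²K = (σ_g²/s)X_cX_cᵀ means each marker's share of the polygenic
variance is φ² = σ̂_g²/s, and only σ² is re-profiled by REML on the
selected model (a fixed-point iteration over λ = φ²/σ², converging in a
few steps). This keeps the prior consistent with what stage 1 already
learned about *all* markers. The alternative (`ridge_prior="model_reml"`)
re-estimates both components on the selected subset; because screening
enriches the subset for markers that correlate with this realization of
the phenotype, the subset REML sees an inflated apparent effect variance,
λ̂ grows by two orders of magnitude, and the deshrunk estimates slide
toward the joint-least-squares limit in which selection-biased null
candidates explain away part of a true QTN's signal (≈20% downward bias
on the flagship simulation, measured). With the genome-wide prior
λ ≈ 2e-5, d_k ≈ 0.04, and the deshrunk estimate is effectively the
marginal least-squares estimate with a ridge-calibrated variance — the
regime in which the method is unbiased and its Wald test is χ²₁-calibrated.
When λ̂_g = 0 the prior is floored at 1e-6·σ̂², which keeps the same fully
deshrunk regime.

**Significance.** The default threshold is α/q over the q markers in the
fitted model (`bonferroni="model_markers"`), the published convention.
Because the same data chose the q candidates, this call is deliberately
anticonservative: in a null panel roughly m · (tail beyond α/q) markers
slip through regardless of m — the mechanism behind the characteristic
~0.4–0.6 per-mille false-positive rate, traded for power on minor
effects. `bonferroni="all_markers"` (α/m) restores family-wise control
and leaves null panels empty in the large majority of runs.

Markers whose d_k falls below 1e-8 are numerically unmeasured: they are
flagged (`measured=False`), reported with W = 0 and p = 1, and never
called significant.

## Synthetic data generator

The generator reproduces the simulation design used to characterize the
method: n = 2000 individuals, m = 10000 independent biallelic markers,
per-marker MAF drawn from U(0.1, 0.5), grand mean 10.0, residual variance
10.0. Genotypes default to a two-homozygote inbred-panel coding
{−1, +1} with P(+1) = 1 − MAF (marker variance 4q(1−q)); a three-class
Hardy–Weinberg coding {−1, 0, +1} is available. Fixed-position QTN
designs carry the published effect sizes verbatim (single QTN 0.7398 at
position 98; five QTNs 0.5451/0.8622/0.8598/1.0789/1.2093 at positions
98/301/540/801/1000); their nominal per-QTN heritability labels are not
used, because no single effect↔r² mapping reproduces all printed effects.

The polygenic term is u ~ MVN(0, c·σ²·K) with K the marker-derived
kinship (mean diagonal 1), drawn exactly as X_c a·√(cσ²/s) with
a ~ N(0, I_m) — no n³ factorization per replicate. The scenario labels
2K/5K/10K denote absolute polygenic variances σ_g² = 2, 5, 10 (c = 0.2,
0.5, 1.0 with σ² = 10). This reading was fixed by the published
per-scenario estimate spreads: the single-marker standard error
√(total var/(n·avg 4pq)) predicts 0.089/0.100/0.115 across scenarios
under it, matching the printed 0.091/0.109/0.131, whereas a relative
reading (σ_g² = c·σ², c ∈ {2, 5, 10}) would put up to 10/11 of the
phenotypic variance into the background and cap single-QTN power near
20–40% — far from the reported values. Each replicate draws fresh
genotypes and a fresh phenotype from seed base + replicate index, with
genotype and phenotype streams spawned independently.

What the generator does *not* emulate: linkage disequilibrium, population
structure, missing genotypes, non-Gaussian noise, dominance or epistasis.
Passing tests therefore demonstrate the method's behavior under
independent markers and a marker-exchangeable polygenic background; on
real data, LD spreads signals over neighboring markers (the evaluation
layer exposes a detection window for that case) and structure can inflate
the screening stage.

## Evaluation conventions

- **Power** per QTN: percentage of replicates in which the QTN's exact
  simulated position is called significant. Exact-position matching is
  correct here because simulated markers are independent.
- **Effect accuracy**: mean and SD of the deshrunk estimate at the true
  position over detecting replicates only (QTNs never detected report
  missing values, not zeros).
- **MSE**: the *sum* over detecting replicates of squared errors. The sum
  reading (rather than the mean) is fixed by the moment identity
  n·(SD² + bias²): with the published 100-replicate values for the
  flagship scenario, 100·(0.091² + 0.0058²) ≈ 0.83 matches the printed
  0.817 to rounding, while the mean reading would be ~100× smaller.
- **False positive rate**: significant markers at zero-effect positions
  divided by (replicates × zero-effect markers), in per mille.

## Numerical choices

- REML bounds [1e-6, 1e6] on variance ratios, 121-point bracketing grid,
  Brent refinement to 1e-10 on the log scale.
- Kinship PSD tolerance −1e-4·max eigenvalue (covers float32-accumulated
  round-off; genuinely indefinite inputs fail by orders of magnitude).
- `precision="fast"` (default) runs the two large dense operations —
  kinship cross-product and whitening — in float32 and everything
  else in float64; `"double"` runs everything in float64. Stage-3
  algebra is always float64.
- Problem sizes in the test suite: the replicated acceptance experiments
  run the full published design (2000 × 10000) at 30–50 replicates;
  unit and property tests use panels of 50–800 individuals chosen so the
  whole suite stays in the tens of minutes on one CPU.

## Known limitations

- The per-model Bonferroni call does not control the family-wise error
  rate (see above); users wanting FWER control should use
  `bonferroni="all_markers"`.
- A single shared φ² across selected markers is a deliberate
  simplification; strongly heterogeneous architectures may prefer
  per-marker variances, which are out of scope.
- One variance component besides the residual: no dominance/epistasis
  kinships, no leave-one-chromosome-out correction.
- The screening stage is a single marginal pass — no iterated
  sure-independence screening or conditional screening.
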