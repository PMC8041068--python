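# fastrr — fast multi-locus ridge regression for GWAS

`fastrr` implements a three-stage multi-locus mixed-linear-model method for
genome-wide association studies of quantitative traits, aimed at panels
where the number of markers far exceeds the number of individuals and where
both large- and minor-effect quantitative trait nucleotides (QTNs) must be
detected against a polygenic background.

## The model

For phenotypes **y** (n × 1), fixed effects **α** with design **W**, marker
genotypes **Z**, marker effects γ, polygenic effects **u** and residuals ε:

    y = Wα + Zγ + u + ε,
    γ_k ~ N(0, φ²),   u ~ MVN(0, σ_g² K),   ε ~ MVN(0, σ² I_n),

with **K** the marker-derived relatedness matrix. The algorithm runs in
three stages:

1. **Whitening.** λ_g = σ_g²/σ² is estimated once by REML on the reduced
   model (no marker term) via a single eigendecomposition of **K**. With
   B = λ̂_g K + I = QΛQᵀ, the operator C = QΛ^(−1/2)Qᵀ satisfies CBCᵀ = I,
   so the transformed data y_c = Cy, Z_c = CZ have homoscedastic,
   uncorrelated noise.
2. **Screening.** Each whitened marker is tested for Pearson correlation
   with the whitened phenotype (t-test on n − 2 df); markers with
   p < 0.01 form the candidate set of size q.
3. **Deshrinking ridge regression (DRR).** The q candidates enter a
   multi-locus ridge model with a single shared effect variance φ². With
   λ = φ²/σ² and H = λZZᵀ + I, the ridge BLUP is γ̂ᴼᴿᴿ = λZᵀH⁻¹(y − Wα̂);
   each effect's well-measurement factor d_k = 1 − var(γ̂_k|y)/φ² measures
   how much of the prior uncertainty the data resolved. Deshrinking
   divides effect and variance by d_k, and W_k = (γ̂ᴰᴿᴿ_k)²/var(γ̂ᴰᴿᴿ_k)
   is referred to χ²₁. Significance uses a Bonferroni threshold
   α / q over the markers in the fitted model.

The package also ships the Monte-Carlo machinery used to characterize the
method: a synthetic-data generator (independent biallelic markers,
MAF ~ U(0.1, 0.5), marker-derived polygenic term, fixed-position QTNs) and
an evaluation layer computing per-QTN power, effect accuracy and the
false-positive rate.

## Worked example

```python
from fastrr import preset_config, generate_genotypes, generate_phenotype, run_fastrr, FastrrConfig

cfg = preset_config("single-qtn-2k", n_individuals=400, n_markers=1500)
geno = generate_genotypes(cfg, seed=11)
y, truth = generate_phenotype(geno, None, cfg, seed=12)

res = run_fastrr(geno, y, config=FastrrConfig(bonferroni="all_markers"))
print(f"lambda_g = {res.lambda_g:.3f}, candidates q = {res.n_selected}, threshold = {res.threshold:.2e}")
print(res.table[res.table.significant][["position", "gamma_drr", "se_drr", "p_value"]].to_string(index=False))
```

prints (seed-exact):

```
lambda_g = 0.283, candidates q = 12, threshold = 3.33e-05
 position  gamma_drr  se_drr  p_value
       98   0.791273 0.18368 0.000016
```

The single simulated QTN sits at position 98 with true effect 0.7398; the
pipeline screens 12 candidates out of 1500 markers and recovers it with a
deshrunk estimate of 0.79 ± 0.18 at p ≈ 1.6e-5. At this reduced panel size
the standard error is roughly twice that of the full 2000 × 10000 design.
The example uses the conservative genome-wide Bonferroni call (α/m); the
default per-model call (α/q, the published convention) trades a controlled
false-positive rate — a few tenths per mille of the null markers — for
extra power on minor effects.

The same pipeline runs from the shell:

```bash
fastrr simulate --preset single-qtn-2k --seed 7 --out-prefix sim
fastrr run --geno sim.geno.tsv --pheno sim.pheno.tsv --out result.tsv
fastrr evaluate --preset single-qtn-2k --reps 30 --seed 1 --out summary.tsv
```

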