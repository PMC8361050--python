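# grntopo

Signed gene-regulatory-network inference and topological comparison of
expression cohorts: maximum-entropy Gaussian coupling estimation via a
from-scratch graphical lasso, structural-balance energetics of the signed
network, and persistent homology of its weighted clique complex.

## The problem

Given a genes × samples expression matrix (e.g. RPKM-normalized RNA-seq for a
tumor and a matched normal cohort), we want a *global*, threshold-free
description of how the gene–gene interaction structure differs between
conditions. Pairwise correlations conflate direct and indirect effects, and
hard-thresholding a correlation network makes every downstream statistic a
function of an arbitrary cutoff. This package instead:

1. **Infers couplings.** The maximum-entropy distribution over continuous
   expression levels S that matches the observed first and second moments is
   the multivariate Gaussian

   P(S) = exp[ −½ (S − ⟨S⟩)ᵀ C⁻¹ (S − ⟨S⟩) ] / ( (2π)^{L/2} det(C)^{1/2} ),

   so the coupling between genes i and j is read off the precision matrix:
   J_ij = −(C⁻¹)_ij. Because the sample inverse covariance is dense, C⁻¹ is
   estimated by the **graphical lasso** — the ℓ₁-penalized Gaussian maximum
   likelihood estimator, argmin_Θ [−log det Θ + tr(SΘ) + λ‖Θ‖₁,off] —
   implemented here from scratch as block coordinate descent and verified
   against its KKT conditions and independent solvers.

2. **Scores structural balance.** Each closed triangle carries energy
   E_ijk = J_ij J_jk J_ki and is balanced iff E_ijk > 0. The triadic
   Hamiltonian is H₃ = −Σ E_ijk; the quartic Hamiltonian couples triangles
   sharing an edge, H₄ = −Σ Δ_ijk Δ_ijl = −s(G) with Δ the triangle's sign.

3. **Scans all thresholds at once with persistent homology.** Vertices enter
   at weight 0, each edge at |J_ij|, each (k+1)-clique at the maximum of its
   edge weights; sweeping the threshold produces a filtration of clique
   complexes. Homology over ℤ₂ tracks when components (β₀), loops (β₁) and
   voids (β₂) are born and die; classes that never die are *essential*. Betti
   curves, persistence diagrams and barcodes summarize the whole sweep, and
   two cohorts are compared by directional signatures: which network becomes
   connected at a smaller weight, which carries essential loops, which
   saturates β₂ earlier.

Everything is testable without any data download: the `synthetic` module
generates Gaussian cohorts from known sparse signed precision matrices
(including cohort pairs that differ only in the width of their
coupling-weight distribution — narrow "cancer-like" vs broad "normal-like")
and small toy networks with closed-form homology.

## Worked example

```python
from grntopo import generate_cohort_pair, compare_cohorts
from grntopo.pipeline import PipelineConfig, run_cohort

narrow, broad = generate_cohort_pair(n_genes=50, n_samples_a=2000,
                                     n_samples_b=2000, seed=0)
cfg = PipelineConfig(penalty=0.02)
rep_narrow = run_cohort(narrow, cfg)
rep_broad = run_cohort(broad, cfg)
for rep in (rep_narrow, rep_broad):
    print(f"{rep.label:12s} edges={rep.histogram['n_edges']:3d} "
          f"|J| sd={rep.histogram['abs_std']:.3f} "
          f"connects at w={rep.beta0_connect_threshold:.3f} "
          f"beta2 plateau={rep.beta2_plateau}")
comparison = compare_cohorts(rep_narrow, rep_broad)
print(comparison.flags)
```

prints

```
cancer-like  edges=279 |J| sd=0.049 connects at w=0.017 beta2 plateau=(0.19568973222115765, 3)
normal-like  edges=137 |J| sd=0.204 connects at w=0.333 beta2 plateau=(None, 0)
{'connects_earlier': 'a', 'loops_onset_earlier': 'a', 'more_essential_loops': 'b',
 'more_essential_voids': 'a', 'beta2_saturates_earlier': 'a', 'beta2_saturates_lower': 'b'}
```

The narrow-weight ("cancer-like") cohort's network becomes a single connected
component at weight ≈ 0.02 while the broad ("normal-like") one needs ≈ 0.33,
and only the narrow network's β₂ curve reaches a plateau inside its weight
range — the qualitative tumor-vs-normal topology contrast the pipeline is
built to detect.

The same analysis is available from the shell:

```bash
grntopo simulate --out-dir data --n-genes 50 --n-samples 2000 --seed 0
grntopo run data/cancer_like_expression.tsv --out-dir out --lambda 0.02 --top-k 0 --label cancer
grntopo run data/normal_like_expression.tsv --out-dir out --lambda 0.02 --top-k 0 --label normal
grntopo compare out/cancer_persistence_pairs.csv out/normal_persistence_pairs.csv
```

`grntopo run` writes the edge list, triad census, persistence pairs, Betti
curves, a JSON summary, and the standard figures (persistence diagram,
barcode, Betti curves, weight histogram). `grntopo topology --toy …` runs the
topology stage on a registered toy network; `grntopo balance` reports the
triad census and quartic energy of any signed edge list.

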