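# lumisig

Gene-signature analysis for two-channel microarray studies of breast
cancer: a from-scratch two-class SAM (Significance Analysis of
Microarrays) engine, inner-product signature-activity projection,
node-correlation gene-module extraction from correlation dendrograms,
signature-overlap decomposition, and expression-stratified
Kaplan–Meier/log-rank survival analysis — together with seeded synthetic
generators for every input shape, so the whole chain is testable against
known ground truth.

It is aimed at computational biologists who want the classic
knockdown-signature workflow (normalize → filter → SAM → signature →
project → module → survival) as a reproducible library and CLI rather
than a collection of one-off scripts.

## The statistics at the core

**SAM.** For gene *i*, the relative difference between classes is

    d_i = (x̄₂ᵢ − x̄₁ᵢ) / (s_i + s₀),
    s_i = sqrt[(1/n₁ + 1/n₂) · (Σ₁(x−x̄₁)² + Σ₂(x−x̄₂)²) / (n₁+n₂−2)]

with the fudge factor s₀ chosen from percentiles of s to stabilize the
variance of d across scatter levels (with s₀ = 0, d is the pooled
two-sample t). The null is built by permuting class labels — all C(n,n₁)
assignments enumerated exactly when feasible, e.g. 462 for a 5-vs-6
design — and genes are called at band half-width Δ around the
observed-vs-expected order-statistic line. The FDR at each Δ is the
median permuted exceedance count over the number called. Genes called
at the chosen FDR form a *signature*: gene → weight d_i, partitioned
into positive and negative sets.

**Activity projection.** The activity of signature w in sample x is the
inner product Σ w_i·x_i over matched genes (gene-median-centered by
default) — a relative, within-dataset measure compared across groups by
ANOVA.

**Gene modules.** Genes are clustered by average linkage on Pearson
correlation; a module around a seed gene is the largest subtree whose
merges stay at or above a node-correlation threshold (0.65 by
convention). Module genes are decomposed into exclusive
per-signature / multiple / unexplained categories.

**Survival.** A gene's expression is rank-ordered, split into halves,
and the halves compared by the log-rank test (chi-square, 1 df) with
Kaplan–Meier curves; cohort associations use ANOVA/t-tests and 2×2
chi-square.

## Worked example

Simulate a 5-vs-6 knockdown with 10% planted differential expression,
run SAM, and project the derived signature onto a sorted
mammary-lineage panel that expresses it most in mature luminal cells:

```python
from lumisig.synthdata import (KnockdownSimSpec, LineageSimSpec,
                               simulate_knockdown, simulate_lineages)
from lumisig.sam import SAM
from lumisig.activity import project_signature, compare_activity

matrix, labels, truth = simulate_knockdown(
    KnockdownSimSpec(n_genes=1000, de_fraction=0.10, effect_size=2.0,
                     sigma=0.5, seed=0))
est = SAM(fdr=0.05, random_state=0).fit(matrix, labels)
sig = est.signature_
print(f"s0 = {est.s0_:.3f}; {est.result_.n_permutations} permutations "
      f"(exhaustive={est.result_.exhaustive})")
print(f"signature: {len(sig)} genes ({len(sig.positive_set)} positive, "
      f"{len(sig.negative_set)} negative) at FDR<0.05")
print(f"planted DE genes recovered: "
      f"{len(set(sig.gene_ids) & set(truth.index))}/{len(truth)}")

panel, populations = simulate_lineages(LineageSimSpec(weights=sig.weights, seed=1))
act = project_signature(sig, panel)
res = compare_activity(act.scores, populations)
print(act.scores.groupby(populations.to_numpy()).median().round(1).to_string())
print(f"ANOVA F = {res['F']:.1f}, p = {res['p']:.3g}")
```

Output:

```
s0 = 0.519; 462 permutations (exhaustive=True)
signature: 105 genes (51 positive, 54 negative) at FDR<0.05
planted DE genes recovered: 100/100
LP       20.7
ML      125.4
MaSC    -38.2
St     -121.6
ANOVA F = 292.4, p = 1.11e-16
```

The 11-sample design is small enough that the permutation null is
enumerated exactly (462 labelings). All 100 planted genes are called at
FDR < 5% with only a handful of false positives, and the projected
activity is highest in the mature-luminal (ML) population — the planted
ordering — with a decisive ANOVA.

The same steps are available from the shell:

```bash
lumisig simulate --n-genes 1000 --seed 0 --out sim/
lumisig sam --matrix sim/matrix.tsv --labels sim/labels.tsv --fdr 0.05 --out sam/
lumisig module --matrix sim/matrix.tsv --seed-gene G00001 --min-corr 0.65 --out mod/
lumisig run --config config.yaml --out run/      # full pipeline from YAML
```

## Layout

- `lumisig.synthdata` — seeded generators with emitted ground truth
- `lumisig.prep` — expression I/O, lowess M-A normalization, gene filters
- `lumisig.sam` — the SAM engine (`SAM` estimator + step functions)
- `lumisig.activity` — `SignatureProjector` and ANOVA comparison
- `lumisig.modules` — `NodeCorrelationModules`, overlap decomposition
- `lumisig.survival` — rank split, Kaplan–Meier, log-rank, group tests
- `lumisig.pipeline` / `lumisig.cli` — end-to-end runs and the `lumisig` CLI

`lumisig.pipeline.reproduce_gse21371` re-derives the knockdown signature
from user-supplied GEO series files (GSE21371) and reports its counts
side by side with the reference values for that experiment; it skips
cleanly when the files are absent and is never part of the default
tests.
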