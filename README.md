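# dnmjoint

Joint multi-trait association testing for *de novo* mutation (DNM) counts
from trio sequencing studies.

Early-onset diseases such as congenital heart disease and autism share risk
genes, but single-trait DNM burden tests are underpowered at typical trio
cohort sizes. `dnmjoint` raises power by (a) borrowing strength across two
traits through a shared latent association class and (b) integrating
functional annotations. It is aimed at statistical geneticists analyzing
per-gene DNM counts from one or two case cohorts.

## Model

For gene *i*, mutability *μᵢ* and cohorts of *N₁*, *N₂* trios, a four-way
latent class *Zᵢ* ∈ {00, 10, 01, 11} with prior π says which traits the
gene is associated with, and

- *Y*ᵢₜ | null for trait *t* ~ Poisson(2*Nₜμᵢ*),
- *Y*ᵢₜ | risk for trait *t* ~ Poisson(2*Nₜμᵢγᵢₜ*),  γᵢₜ = exp(xᵢₜ'βₜ),

where xᵢₜ is the gene's annotation vector (intercept-only without
annotations). π₁₁ − (π₁₀+π₁₁)(π₀₁+π₁₁) measures pleiotropy. Θ = (π, β₁, β₂)
is estimated by EM (analytic π and intercept updates; safeguarded
Newton–Raphson with annotations). Genes are ranked by the joint local false
discovery rate — for trait 1, Jlfdr₁(*Y*ᵢ₁, *Y*ᵢ₂) = Pr(*Z*₀₀+*Z*₀₁ = 1 |
*Y*ᵢ₁, *Y*ᵢ₂) — and rejected by thresholding the running mean of sorted
Jlfdr values at a nominal global FDR level *q* (default 0.05).

Variant-level annotation scores are collapsed to gene level by summing over
the gene's observed DNMs (centered for continuous scores), then
standardized, pruned at Pearson correlation 0.7 and filtered at fitted
effect size |β| > 0.01. A simulation engine reproduces the method's
estimation, power and misspecification-robustness studies. See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from dnmjoint import (CohortInfo, SimulationConfig, evaluate_replicate,
                      fit_multi, pi_from_margins, run_inference,
                      simulate_true_model)

cfg = SimulationConfig(
    n_genes=10_000, n1=5_000, n2=5_000,
    pi=pi_from_margins(0.1, 0.1, 0.05),          # 10% risk genes per trait, half shared
    beta1=np.array([3.0, 0.3, 0.3]),             # relative risk exp(3) ~ 20 at baseline
    beta2=np.array([3.0, 0.3, 0.3]),
    base_seed=42,
)
table, (design1, design2), truth = simulate_true_model(cfg, 0)
fit = fit_multi(table, CohortInfo(n1=5_000, n2=5_000), design1, design2)
print("converged:", fit.converged, "after", fit.n_iter, "EM iterations")
print("pi  =", np.round(fit.params.pi, 4))
print("beta1 =", np.round(fit.params.beta1, 3))
result = run_inference(fit, table, q=0.05)
print("trait-1 rejections:", int(result["sig_t1"].sum()))
m = evaluate_replicate(result, truth, trait=1)
print(f"power={m.power:.3f} empirical FDR={m.empirical_fdr:.3f} AUC={m.auc:.3f}")
```

prints

```
converged: True after 9 EM iterations
pi  = [0.8475 0.05   0.0539 0.0485]
beta1 = [2.987 0.33  0.319]
trait-1 rejections: 695
power=0.669 empirical FDR=0.043 AUC=0.959
```

The fitted class prior recovers the generating values (π₁₁ = 0.05, trait
margins 0.1), the annotation effects (3, 0.3, 0.3) are recovered, 695 of
the 10,000 genes are called for trait 1, and the empirical false discovery
rate among them (0.043) respects the nominal q = 0.05.

The same pipeline is available from the shell:

```sh
dnmjoint simulate --config sim.yaml --out sim/
dnmjoint fit-multi --genes sim/genes.tsv --n1 5000 --n2 5000 \
    --annotations1 sim/annotations_t1.tsv --annotations2 sim/annotations_t2.tsv \
    --out fit/
dnmjoint test --genes sim/genes.tsv --fit-dir fit/ --q 0.05 --out results.tsv
```

plus `collapse` (variant-to-gene annotation collapsing), `select-features`
(two-stage feature selection) and `grid` (replicate power/FDR studies).
Gene tables are TSV with header `gene_id  mu  y1 [y2]`.

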