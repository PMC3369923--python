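# fruitnet

Reverse-engineer a multi-omics panel of recombinant inbred lines (RILs)
into a predictive linear steady-state model — genes → genes, genes →
metabolites, metabolites → agronomic traits — and then use that model to
search *in silico* for genome redesigns (gene knockouts and
over-expressions) that improve fruit-quality-style objectives. The
package is aimed at plant systems biologists working with line-by-feature
omics matrices (expression, metabolite levels, phenotypes) who want a
testable, seed-reproducible pipeline from raw panel to ranked redesigns,
with a synthetic-panel generator that plants a known ground truth so
every stage can be validated.

## The model

For gene *i*, metabolite *k* and trait *p* at steady state:

    g_i = Σ_j w_ij g_j + b_i + e_i        (sparse W, no self-loops)
    m_k = Σ_i v_ki g_i + b_k
    a_p = Σ_k u_pk m_k + b_p

with each gene bounded by its observed expression range (optionally
shrunk by a fraction δ). Sparse supports are found per target by a CLR
screen (mutual-information z-scores against row/column backgrounds, keep
z ≥ z\*), then LASSO along the LARS path with extended-BIC model
selection, then an OLS refit. A knockout clamps g_i at its range minimum,
an over-expression at its maximum; the remaining genes are re-solved
self-consistently within their bounds. Perturbations are scored by signed
weighted objectives over predicted metabolites/traits and ranked by
efficiency, `100·(s_pert − s_wt)/|s_wt|` per line. Model validation
follows the perturbation-signature route: the sets Ω⁺/Ω⁻ of single-gene
perturbations moving each metabolite by more than 1% of its wild-type
population sd predict metabolite–metabolite correlations, which are
compared with empirical correlations by precision/recall/F-score and a
Mantel permutation test.

See `docs/methods.md` for assumptions, estimator choices, and what the
synthetic benchmark does and does not demonstrate.

## Worked example

Generate a planted panel, infer the metabolite layer, score edge
recovery against the planted truth, and scan single-gene redesigns:

```python
from fruitnet import PanelConfig, generate_ground_truth, simulate_panel
from fruitnet.model import ModelStack
from fruitnet.netinfer import bootstrap_ppv_fpr, fit_layer
from fruitnet.optimize import ObjectiveSpec, rank_perturbations, scan_single
from fruitnet.panel import average_replicates
from fruitnet.preprocess import standardize

config = PanelConfig(n_genes=120, n_metabolites=12, n_traits=3,
                     n_lines_full=160, n_lines_expr=60)
truth = generate_ground_truth(config, seed=1)
panel = simulate_panel(truth, config, seed=2)
std = standardize(panel)

met = fit_layer(std, "metabolites")
print(f"metabolite training r (mean): {met.meta['training_r'].mean():.3f}")

boot = bootstrap_ppv_fpr(met.support_dict(), truth.support("metabolites"),
                         list(met.predictors), n_boot=10000, seed=3)
print(f"edge recovery: PPV={boot.ppv:.2f} (null {boot.null_ppv_mean:.3f}), "
      f"FPR={boot.fpr:.4f}, p={boot.p_ppv:.1e}")

stack = ModelStack(genes=fit_layer(std, "genes"),
                   metabolites=met,
                   traits=fit_layer(std, "traits"),
                   expression=average_replicates(std.expression))
spec = ObjectiveSpec(maximize=list(met.targets[:2]),
                     minimize=list(met.targets[2:4]))
records = scan_single(stack, spec, lines=stack.baseline_lines[:15])
top = rank_perturbations(records[1:], "mean_efficiency").head(3)
print(top[["perturbation", "mean_efficiency", "best_line"]].to_string(index=False))
```

prints

```
metabolite training r (mean): 0.857
edge recovery: PPV=0.46 (null 0.044), FPR=0.0210, p=1.0e-04
perturbation  mean_efficiency best_line
     G030:OE       321.992889      L012
     G048:OE       297.110848      L009
     G021:KO       270.477917      L009
```

Reading this: the fitted metabolite layer tracks the training panel
(mean Pearson r 0.857); 46% of the inferred predictor edges are planted
truth versus 4.4% expected for random same-size predictor lists
(bootstrap p = 1e-4), with a 2.1% false-positive rate; and the best
single redesign (over-expressing `G030`) improves the balanced
two-up/two-down metabolite objective by ~322% on average across 15
lines, peaking in line `L012`.

The same pipeline is scriptable from the shell:

```sh
fruitnet simulate --seed 7 --out raw/
fruitnet preprocess --panel raw/ --out clean/
fruitnet infer --panel clean/ --out model.json --folds 5
fruitnet optimize --model model.json --objective objective.json --out ranked.tsv --greedy
fruitnet validate --model model.json --metabolites clean/metabolites.tsv --out validation/
fruitnet report --scan ranked.tsv --out report/
```

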