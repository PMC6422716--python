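# cognet

Group-wise psychometric network analysis of executive-function and
behavior scores, built for the setting where three cohorts (e.g.
frontal-lesion patients, non-frontal-lesion patients, and controls)
show **no mean differences** on cognitive tests and the question is
whether the *pattern of conditional dependencies* between tests differs
instead. The package is aimed at neuropsychology / psychometric-network
researchers who want the full pipeline — sparse network estimation,
bootstrap stability, community structure — as tested, scriptable Python.

## What it computes

Per group, with scores `X` (n subjects x 9 tests) and correlation matrix
`S`:

1. **Sparse partial-correlation network** — graphical lasso
   `max_Theta log det(Theta) - tr(S Theta) - lambda sum_{i!=j}|Theta_ij|`
   over a 100-point penalty path, penalty selected by BIC
   (`-2l + E ln n`), edges `rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj)`.
2. **Bootstrap inference** — 1,000 full-pipeline resamples (penalty
   re-selected each time); 95% percentile confidence intervals
   (2.5th/97.5th) for every edge weight and node strength; group
   differences in centrality flagged by CI nonoverlap.
3. **Communities and stability** — Louvain with 100 restarts maximizing
   the asymmetric *signed* modularity
   `Q = Q+ - (s-/(s+ + s-)) Q-`; per-pair co-assignment proportions
   across the bootstrap partitions.
4. **Standard stage** — per-variable ANOVA (or Kruskal–Wallis for
   nonnormal scores) with Brown–Forsythe variance checks and Tukey HSD
   post-hocs.

Because the original clinical data are not public, the package ships a
synthetic-cohort generator that plants known sparse precision matrices
(three groups, n = 67/66/61, identical means) so every stage is testable
end to end. See `docs/methods.md` for the model details and validation
design.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic cohort (results under `results/`):

```bash
python analysis/01_simulate_cohort.py        # 194 subjects, 3 groups
python analysis/02_group_comparisons.py      # ANOVA / Kruskal-Wallis
python analysis/03_estimate_networks.py      # glasso + BIC per group
python analysis/04_bootstrap_stability.py    # B=1000 CIs (few minutes)
python analysis/05_communities.py            # Louvain + co-assignment
```

Stage 03 prints, per group, the selected penalty, edge count and the
strongest edge — the verbal-memory pair in every group:

```
   control: n=67, lambda=0.203, 7 edges; strongest 15T-15R = +0.388; Q=0.632, 4 communities
nonfrontal: n=66, lambda=0.198, 5 edges; strongest 15T-15R = +0.435; Q=0.646, 5 communities
   frontal: n=61, lambda=0.107, 18 edges; strongest 15T-15R = +0.446; Q=0.407, 2 communities
```

Stage 05 prints the co-assignment proportions for the key pairs:

```
            15T-15R  DSB-15T  FLU-15T  DSB-FLU  STR-TMT
control        1.00     0.02     0.01     0.99     0.50
frontal        1.00     0.87     0.88     0.99     0.44
nonfrontal     1.00     0.03     0.05     0.94     0.60
```

Read: the memory pair (15T, 15R) forms a community in 100% of bootstrap
samples in every group; working memory (DSB) and fluency (FLU) join
that community almost only in the frontal group (87%/88% vs 1–5%) —
exactly the planted group difference, recovered with no mean
differences anywhere (stage 02 finds none beyond the ~5% type-I rate).

The same pipeline runs from a config file on any cohort CSV:

```bash
cognet simulate --seed 7 --out cohort.csv
cognet run --config config.yaml        # input, B, restarts, seed, ...
cognet report --run-dir runs/latest    # re-render figures from saved ensembles
```

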