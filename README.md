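# smahp — survival mediation analysis of high-dimensional proteogenomic data

`smahp` finds protein mediators that transmit the effect of gene-expression
exposures onto a survival outcome. It is aimed at proteogenomic studies —
RNA-Seq exposures `X` (n×p), protein-abundance mediators `M` (n×k), clinical
covariates `Z`, and a right-censored follow-up time — where both the
exposure and the mediator layer are high-dimensional and the question is
which (gene, protein) pairs carry a nonzero indirect effect on survival.

## Model and procedure

The outcome follows an accelerated failure time (AFT) model on log-time,

```
log T = β_X' X + β_Z' Z + β_M' M + b ε,      ε ~ N(0,1) or extreme value,
```

with censoring handled through the likelihood; each mediator follows
`M_k = α_Xk' X + α_Zk' Z + ξ_k`. The natural indirect effect of gene j
through protein s is the product `α̂_js · β̂_Ms`; a positive coefficient
means longer survival. Pairs are found in three steps:

1. **Penalized screening** — penalized AFT of log-time on all mediators
   (candidate set 𝒮₁) and on all exposures (candidate direct genes 𝒯);
   MCP-penalized regression of each candidate mediator on all exposures
   (candidate genes 𝒥₁ₖ). Penalty weights are chosen by an extended-BIC
   rule on refitted supports (cross-validation available).
2. **Sure independence screening** — per-mediator refits give α̂ and β̂;
   the pairs with the largest |α̂·β̂| are kept, at most ⌊n/ln n⌋ of them
   (𝒮₂, 𝒥₂ₛ).
3. **Joint-significance testing** — a joint AFT with all screened
   mediators and covariates plus per-mediator mediation models give Wald
   p-values; each pair is tested with `P_max = max(P_α, P_β)` and
   Benjamini–Hochberg is applied over the tested gene×mediator matrix at
   level q = 0.05.

The package also ships the synthetic proteogenomic generator used for
validation (block-structured mediators, AFT outcome, calibrated
exponential censoring, known ground-truth pairs), two comparator methods
(`sis_sis`: univariate marginal screening + Steps 2–3; `naive`: all p·k
marginal pair tests), and a power/FDR study harness. See
`docs/methods.md` for the full statistical account.

## Worked example

```python
import smahp

cfg = smahp.SimulationConfig(n=200, p=50, k=100, censor_target=0.25, seed=7)
ds = smahp.generate_dataset(cfg)                     # X, M, Z, time, delta + truth
res = smahp.run_smahp(ds.X, ds.M, ds.Z, ds.time, ds.delta,
                      smahp.PipelineConfig(seed=7))

print(len(res.rows), "tested pairs,", len(res.discoveries), "significant")
print(res.rows[res.rows.significant]
      [["gene", "mediator", "alpha_hat", "beta_hat", "nie", "p_adjusted"]]
      .head(5).to_string(index=False))
power, fdr = smahp.compute_metrics(res, ds.truth)
print(f"power {power:.2f}  fdr {fdr:.2f}")
```

prints

```
30 tested pairs, 20 significant
 gene  mediator  alpha_hat  beta_hat      nie   p_adjusted
   10        14   0.416859   4.08054 1.701009 3.597916e-30
   20        14   0.371065   4.08054 1.514147 4.343040e-24
   24        14   0.395884   4.08054 1.615420 5.068099e-27
   45        14   0.422947   4.08054 1.725853 8.432896e-31
   46        14   0.392159   4.08054 1.600221 5.346358e-27
power 1.00  fdr 0.00
```

— the five genes shown are true parents of outcome mediator 14 (its
mediator-to-outcome coefficient `beta_hat` ≈ 4.1 recovers the generating
effect size 4.0, `alpha_hat` ≈ 0.4 is the generating 0.8 on the
standardized exposure scale since sd(X) = 0.5); `nie` is
the indirect effect per standard deviation of expression on the log-time
scale. On real data, use `smahp.io_read_tables` / the CLI with TSV inputs.

A command-line interface mirrors the library:

```
smahp simulate --n 200 --p 50 --k 100 --censor-target 0.25 --seed 7 --out data/
smahp run --x data/X.tsv --m data/M.tsv --z data/Z.tsv \
          --survival data/survival.tsv --seed 7 --out results/
smahp study --scenario 50,100 --n 200 --censoring 0.25 --n-reps 200 --out study.tsv
smahp prescreen --table genes.tsv --survival surv.tsv --top-n 100 --out kept.tsv
```

`smahp run` writes `result_pairs.tsv` (one row per tested pair),
`nde.tsv` (direct effects), `active_sets.json` (audit trail of
𝒮₁/𝒯/𝒥₁/𝒮₂/𝒥₂) and a machine-readable run manifest.

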