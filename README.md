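# ecmassembly

Neutral vs niche community-assembly analysis for ectomycorrhizal (EcM)
fungal ASV tables.

EcM fungi are root symbionts whose communities may assemble *neutrally*
(dispersal and drift from a regional pool) or through *niche* processes
(host filtering, environmental selection). For amplicon studies with a
crossed host design — host type (conifer/broadleaf) x developmental stage
(juvenile/adult) with replicated root samples — this package quantifies the
balance between the two per host group, and identifies the taxa driving
host differences. It is aimed at microbial ecologists working from an ASV
count table, sample metadata, and a genus-level guild annotation.

## What it computes

**Abundance–occupancy neutral fit** (the core model). For each host group,
per-ASV occurrence frequency f_obs (fraction of the group's samples with a
detection) is regressed on log10 mean relative abundance with a penalized
binomial GAM (logit link, cubic B-splines, GCV-selected smoothing). Two
statistics summarize each group:

* pseudo-R² = 1 − residual deviance / null deviance — how much occupancy
  deviance abundance alone explains (high → neutral-like);
* m = Σ f_obs(1−f_obs) / Σ f_pred(1−f_pred) — the ratio of observed to
  fitted occupancy variance terms, computed exactly as defined.

**Around the model:** the standard preprocessing chain (per-cell removal of
presences under 10 reads, single-sample ASV removal, EcM guild filter,
seeded rarefaction without replacement); alpha diversity (Shannon,
Gini–Simpson, Pielou, richness) with an audited ANOVA/Kruskal–Wallis
decision rule; beta diversity (Bray–Curtis on Hellinger-transformed
abundances, NMDS with stress and 95% ellipses, PERMANOVA R², ANOSIM R);
random-forest indicator taxa (1000 trees) with lnRR effect sizes and
bootstrap CIs; and a synthetic-study generator with ground-truth neutral
(Dirichlet-multinomial, migration parameter m_sim) and niche (host-affinity
filtering) regimes for validation. See `docs/methods.md` for the full model
description and design choices.

## Worked example

Simulate the default 120-sample study (niche-assembled juveniles,
neutrally-assembled adults with m_sim = 0.5), preprocess it, and fit the
occupancy model for two conifer groups:

```python
import ecmassembly as em

cfg = em.SyntheticConfig(seed=1)                      # 6 species x 2 stages x 10 reps
table, metadata, taxonomy, truth = em.generate_study(cfg)
tbl, prov = em.preprocess(table, taxonomy, seed=1)    # filters + rarefaction

adults = metadata.query("host_type=='conifer' and stage=='adult'")["sample_id"]
print(em.NeutralOccupancyGAM.from_table(tbl, list(adults)).fit().summary())
```

```
Neutral abundance-occupancy fit (binomial GAM, logit link)
==========================================================
ASVs:                 280
samples in group:     30
basis dim (k):        10
penalty alpha (GCV):  0.001
effective df:         6.96
null deviance:        5510.59
residual deviance:    93.83
pseudo R2:            0.9830
migration rate m:     0.9890
```

The adult (neutral-regime) group sits tightly on the occupancy curve:
abundance explains 98% of the occupancy deviance. The same fit on the
conifer *juvenile* (niche-regime) group gives pseudo R2 = 0.5053 and
m = 0.8592 — occupancy there is substantially decoupled from abundance
because each ASV tracks its host affinities, which is exactly the
qualitative contrast the model is built to detect. `fit_all_groups`
runs all four host-type x stage groups at once, and
`truth.regime_by_group` holds the generating regime for comparison.

The same analysis runs from the shell on real files:

```sh
ecmassembly simulate --out data/                      # or bring your own TSV/BIOM
ecmassembly neutral-fit --table data/asv_table.tsv --metadata data/metadata.tsv --out fits/
ecmassembly run-all --config pipeline.yaml --out results/
```

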