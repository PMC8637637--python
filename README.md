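# wealthbridge

Temporally-harmonized asset-based wealth indices for longitudinal household
panels.

## The problem

In low- and middle-income-country cohort studies, household wealth is usually
proxied by an *asset index*: the first principal component of indicators such
as television or refrigerator ownership, housing quality, and crowding.
Standard practice fits a separate index at every survey wave, which puts each
wave's scores on a different scale and makes within-household wealth
*trajectories* uninterpretable. A **temporally-harmonized** index solves this
by pooling all waves of a consistently collected asset set and fitting one
component, so a household's score at age 2 and at age 40 are directly
comparable.

Because the indicators are binary and ordinal, the pooled correlation matrix
is estimated on the latent-normal scale: polychoric correlations for
ordinal–ordinal pairs, polyserial for ordinal–continuous, Pearson for
continuous–continuous. Writing ρ̂ for that p×p matrix with leading eigenpair
(λ₁, v₁), the index model is

    loadings  a = v₁ · √λ₁          (sign-anchored on a positive asset)
    share     = 100 · λ₁ / p        (% variance explained)
    score_ht  = Σⱼ aⱼ · z_jht       (z = pooled z-scored integer codes)

standardized so the pooled household-wave sample has mean 0, SD 1.

The package implements the full workflow: asset eligibility (kept if missing
from at most one wave), two-rule imputation (carry the preceding wave
forward, else the cross-sectional mode), the pooled polychoric PCA fit and
scoring, a validation battery (per-wave cross-sectional indices, Spearman
rank agreement, Tucker congruence of loadings, construct validity against
schooling and anthropometry, clumping/truncation diagnostics), a sensitivity
suite (single-asset/wave/joint drops, inverse-wave-size weighting, Pearson
PCA, principal-axis EFA, MCA on binarized indicators), and a synthetic
cohort generator with known latent wealth that makes every stage testable
against ground truth.

## Worked example

```python
import wealthbridge as wb

cfg = wb.SyntheticConfig(n_households=1000, seed=7)
full, truth = wb.generate_panel(cfg)
panel = wb.apply_missingness(full, cfg, truth)
d = cfg.asset_dictionary()

common  = wb.select_common_assets(d, panel.waves)
imputed = wb.impute_missing(panel, common, d)
model   = wb.fit_harmonized_index(imputed, d, assets=common)
scores  = wb.score(model, imputed)

print(f"variance explained: {model.variance_explained_pct:.1f}%")
print(wb.summarize_by_wave(scores).round(2).to_string(index=False))
```

prints

```
variance explained: 49.7%
 wave_id  year    n  mean   sd  median  iqr_low  iqr_high
       1  1990 1000 -0.44 0.98   -0.44    -1.20      0.34
       2  1997  911 -0.19 0.99   -0.14    -0.96      0.58
       3  2004  823  0.07 0.95    0.18    -0.63      0.84
       4  2011  734  0.30 0.90    0.48    -0.32      1.00
       5  2018  661  0.50 0.86    0.65     0.03      1.17
```

The first component captures half the pooled latent-correlation variance;
wave means rise monotonically because the generator embeds a positive
secular trend in latent wealth, and the per-wave n shrinks under 10%
per-wave attrition. The fitted loadings recover the generating pattern,
including the two deliberately negative-loading assets (radio/livestock
analogues: −0.57 and −0.59 against generating values −0.50 and −0.55), and
the per-wave Spearman correlation between the scores and the true latent
wealth is 0.89–0.90.

The same workflow is available from the shell:

```bash
wealthbridge simulate --seed 7 --households 1000 --out run/
wealthbridge fit      --panel run/panel.csv --dictionary run/dictionary.json --out run/
wealthbridge validate --panel run/panel.csv --dictionary run/dictionary.json --out run/
wealthbridge sensitivity --panel run/panel.csv --dictionary run/dictionary.json --out run/
wealthbridge report   --seed 7 --out run/   # full pipeline in one step
```

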