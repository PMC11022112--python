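# valtrans

Hierarchical Bayesian analysis of **emotional-state transitions** in image
valence ratings: how fast do people shift from a neutral to a negative
emotional state, and does that speed differ between trauma-exposed
individuals with probable PTSD (pPTSD) and trauma-exposed controls (TEC)?

Participants rate images of known normative valence `x` (1–9 scale, most
negative ≈ 1.33 up to neutral 5) on a continuous visual-analog scale
(VAS, 0–1). Ratings are modelled per participant with a 5-parameter
logistic curve

```
f(x) = d + (a − d) / (1 + (x/c)^b)^g
```

(`a` lower asymptote, `b` Hill slope — the transition speed, `c`
inflection, `d` upper asymptote, `g` asymmetry), embedded in a
hierarchical Bayesian model with truncated-normal group-level priors and
fit with the No-U-Turn Sampler. The package provides:

- **screening** — PCL-5 scoring with the DSM-5 cluster rule
  (pPTSD ⇔ total > 33 and all four clusters endorsed), the
  emotional-numbing subscale (items 12–14), the >3 SD / >2 images rating
  exclusion rule, and the positive-image filter;
- **synthetic_data** — a generator reproducing the study design
  (35 + 5 images, two groups, questionnaires that screen correctly by
  construction, numbing-coupled slopes) with ground truth for recovery
  tests;
- **model** — the 5-PL, linear, and emotional-numbing
  (`B_i = numbing_z_i · EN + b_i`) model families with the full published
  prior block, plus analytic-gradient log densities (compiled kernels
  with a numpy reference path);
- **inference** — a self-contained NUTS implementation (dual-averaging
  step size; block-diagonal mass matrix with low-rank correction), 89%
  highest-posterior-density intervals, the TEC − pPTSD posterior
  contrast with the robustness rule, and R-hat/ESS diagnostics;
- **model_comparison** — PSIS-LOO tables (rank, loo, p_loo, d_loo,
  weight, se);
- **pipeline / CLI** — `valtrans generate | screen | fit | compare |
  loo | diagnose | run-all` orchestrating the whole analysis with
  deterministic seeding and a run manifest.

## Worked example

```python
from valtrans import (
    GeneratorConfig, SamplerConfig, build_5pl_model, compare_groups,
    filter_positive_images, fit, generate_norms, generate_participants,
)
from valtrans.screening import score_pcl5_frame

norms = generate_norms(n_images=35, n_positive=5, seed=7)
cfg = GeneratorConfig(n_per_group=25, seed=7)
ratings, questionnaires, truth = generate_participants(cfg, norms)

diagnosis = score_pcl5_frame(questionnaires)
print(diagnosis["group"].value_counts().to_dict())

negative, n_removed = filter_positive_images(norms)
ratings = ratings[ratings["image_id"].isin(negative["image_id"])]
print(f"{n_removed} positive images removed")

sampler = SamplerConfig(draws=400, tune=400, chains=2, seed=7)
fits = {}
for grp in ("TEC", "pPTSD"):
    ids = set(diagnosis.loc[diagnosis.group == grp, "participant_id"])
    fits[grp] = fit(
        build_5pl_model(ratings[ratings.participant_id.isin(ids)], negative),
        sampler,
    )

comp = compare_groups(fits["TEC"], fits["pPTSD"], ["mu_b"])[0]
print(
    f"TEC - pPTSD slope difference: {comp.mean:.3f} "
    f"(89% HPD {comp.hpd_low:.3f} to {comp.hpd_high:.3f}), robust={comp.robust}"
)
```

Output from this exact script:

```
{'TEC': 25, 'pPTSD': 25}
5 positive images removed
TEC - pPTSD slope difference: -0.400 (89% HPD -1.140 to 0.310), robust=False
```

The generator's two groups differ in their true mean Hill slope (1.2 vs
1.45) and through the numbing–slope coupling, so the TEC − pPTSD
difference is negative — the pPTSD group transitions faster. At 25
participants per group the 89% HPD still brushes zero (`robust=False`);
the group contrast acceptance check below runs the same analysis at 250
per group, where the interval falls clearly below zero.

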