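# netstate

Predicting within-person *change* in personality states from the
structure of workplace social networks.

Passive sociometric badges log who talked to whom during the work week;
ecological momentary assessment (EMA) prompts capture five
personality-state scores (extraversion, agreeableness,
conscientiousness, emotional stability, openness) three times a day on
a 1–7 Likert scale. `netstate` turns the badge log into undirected
weighted weekly contact networks, extracts 26 structural features per
person-week (whole-network, nodal, and egocentric measures such as Burt
effective size, efficiency and constraint), computes each person-week's
personality-state volatility as the root mean square of successive
differences of their EMA responses,

    RMSSD = sqrt( Σ_{i=1}^{N−1} (x_i − x_{i+1})² / (N − 1) ),

and fits five trait-specific gradient-boosted regressions under
leave-one-subject-out (LOSO) cross-validation. Permutation feature
importances, scaled 0–100 per trait and averaged across traits, rank
which aspects of social structure carry the predictive signal. A
synthetic cohort generator with a planted network–volatility link makes
the entire pipeline testable without any data download.

The package is aimed at computational behavioral-health researchers
working with passive-sensing interaction logs and EMA time series.

## Worked example

```python
import numpy as np
from netstate import (
    SimConfig, simulate_cohort, work_weeks, split_work_weeks,
    build_all_networks, assemble_feature_matrix, build_outcome_table,
    ModelConfig, fit_all_traits,
)
from netstate.model import REDUCED_GRID

config = SimConfig(seed=1)            # 54 people, 6 weeks, planted driver
cohort = simulate_cohort(config)
weeks = work_weeks(config.start_monday, config.n_weeks)

networks = build_all_networks(split_work_weeks(cohort.interactions, weeks))
features = assemble_feature_matrix(networks)          # person-week x 27 predictors
outcomes = build_outcome_table(split_work_weeks(cohort.ema, weeks))

results = fit_all_traits(features, outcomes,
                         config=ModelConfig(grid=REDUCED_GRID, seed=1))
print(results.summary())
profile = results.importance_profile(n_repeats=5, scope="pooled")
print(profile.head(3)[["feature", "average", "rank"]].to_string(index=False))
```

Output:

```
CohortResults (five trait-specific LOSO runs)
  extra  mean R2  0.574   mean RMSE  0.169   mean RMSE/range  0.091
  agree  mean R2  0.614   mean RMSE  0.169   mean RMSE/range  0.091
  consc  mean R2  0.625   mean RMSE  0.162   mean RMSE/range  0.087
  stabl  mean R2  0.616   mean RMSE  0.150   mean RMSE/range  0.081
  open   mean R2  0.567   mean RMSE  0.175   mean RMSE/range  0.094
  consistently informative participants: 40

    feature   average  rank
density_ego 92.356515     1
 efficiency 65.146959     2
       size 36.020741     3
```

Reading this: each line is one trait's LOSO run — `mean R2` is the
average squared correlation between a held-out participant's observed
and predicted weekly RMSSD values, and `mean RMSE/range` expresses the
prediction error as a fraction of the observed outcome range. The
importance table shows that the model's error grows most when
ego-network density/efficiency columns are shuffled: the generator
plants its volatility signal on ego-network efficiency, and the
pipeline surfaces that family of egocentric features (density_ego is
efficiency's strongest structural correlate) at the top of the ranking.

The same pipeline runs from the shell:

```bash
netstate all --out-dir run --seed 1 --grid reduced
netstate simulate --out-dir data --seed 1          # or stage by stage
netstate build-networks --interactions data/interactions.csv --out-dir nets
```

Real logs are analyzed identically by pointing `interactions`/`ema` at
CSV files in the documented dialects (column names configurable).

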