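# Methods

## The scientific question and the pipeline

`netstate` asks how much of the week-to-week *change* in a person's
personality states can be predicted from the structure of their workplace
social interactions. It implements a five-stage pipeline:

1. **Log parsing and work-week splitting** (`netstate.io`). Two inputs:
   a directed badge-detection log (`timestamp,logger_id,detected_id`, one
   row per detection event) and an EMA self-report log with five
   personality-state scores per prompt (1–7 Likert, half-point steps —
   each score the mean of two integer item responses). Records are
   assigned to Monday–Friday work weeks (calendar-date based, inclusive
   both ends; weekend records are dropped first, so only weekdays matter).
2. **Network reconciliation** (`netstate.networks`). Badge detectors of a
   dyad disagree; the undirected weekly edge weight is
   `min(c_ab, c_ba)` — the interaction count both sides agree on. Pairs
   with a zero direction get no edge; participants with no reconciled
   edge get no node that week, so their person-week predictor row is
   missing (isolated egos have no defined egocentric features).
3. **Feature extraction** (`netstate.features`). 26 features per
   person-week — 9 whole-network structural, 4 node-in-network, 13
   egocentric — plus the week index as a 27th predictor.
4. **Outcomes** (`netstate.outcomes`). Per participant, week and trait,
   the root mean square of successive differences of the ordered EMA
   responses, `RMSSD = sqrt(Σ (x_i − x_{i+1})² / (N−1))`. At least two
   responses are required; fewer yield a missing value, never zero.
   All of a week's responses form one series (the overnight gap is an
   ordinary successive pair; no imputation for missed prompts).
5. **Modeling and introspection** (`netstate.model`,
   `netstate.importance`). Five trait-specific gradient-boosted tree
   regressions (xgboost) under leave-one-subject-out cross-validation,
   with permutation feature importance scaled to 0–100 per trait and
   averaged across traits.

## Distance and degree conventions

Contact-count networks use two shortest-path schemes: *inverse weight*
(edge length `1/weight`, frequent contact = close) for closeness,
betweenness and geodesic means, and *hop* (unit lengths) for the diameter
and two-step reach. Betweenness uses inverse-weight distances by default
for consistency with closeness (`betweenness_scheme="hop"` switches).
Degree always means unweighted partner count, not strength.

Deliberate divergences from common conventions, following the feature
definitions as operationalized here:

* Degree centralization is `Σ_i (d_max − d_i)/(n − 1)` — the plain
  sum-of-shortfalls normalization, not Freeman's `(n−1)(n−2)`.
* Ego-network efficiency divides Burt's effective size by the ego-network
  *order* (ego + alters); `efficiency_denominator="alters"` restores
  Burt's original convention.
* Reach efficiency is the fraction of all other nodes within two hops of
  the ego, divided by the ego-network order.
* Community percent size is reported as a fraction of the weekly network
  order (the raw member count is a monotone transform of it, and the
  tree learners downstream are insensitive to monotone rescaling).
* Burt constraint is weight-proportional: `Σ_j (p_ij + Σ_q p_iq p_qj)²`
  with `p_ij` the share of the ego's total tie weight invested in alter
  j. A single-alter ego has constraint exactly 1.

Degenerate denominators (transitivity and centralization of a single-edge
ego network) fall back to 0 rather than missing, so the person-week row
survives; boosted trees tolerate near-constant columns, whereas
missingness would silently drop subjects.

## Community detection

Subcommunities are weighted-modularity communities at resolution 1.0.
Graphs of at most 8 nodes are partitioned by exhaustive search for the
exact modularity optimum; larger graphs (including every realistic weekly
network) use Louvain with eight seeded restarts, keeping the
best-modularity run. The hybrid exists because Louvain's greedy local
moves can miss the optimum on tiny graphs regardless of node order, while
exhaustive search is exact and affordable there; at study scale the
result is plain seeded Louvain. The partition is computed once per weekly
network (seed 2012 by default) and reused for every nodal row.

## Model and evaluation

Each trait's model predicts person-week RMSSD from the 27 predictors.
LOSO folds hold out *all* rows of one participant (1 to n_weeks rows).
Hyperparameters (`nrounds`, `max_depth`, `eta`, `gamma`,
`colsample_bytree`, `min_child_weight`, `subsample`) are tuned per fold
by participant-grouped 5-fold inner cross-validation — grouping prevents
within-person leakage during tuning — minimizing inner RMSE, ties to the
first candidate in grid order. The default grid has three levels for
tree count (50/100/150) and depth (1/2/3) and one level elsewhere; the
`reduced` grid is a single candidate (60 trees, depth 3, eta 0.3) for
large simulation sweeps, where a one-point grid skips the inner loop.
Per-fold seeds derive from the base seed plus a CRC32 of the participant
id, so results are independent of fold execution order; runs are
bit-identical for a fixed configuration.

Fold metrics:

* **R²** is the squared Pearson correlation between observed and
  predicted values (the convention of the R tooling this analysis
  lineage uses), undefined below three rows or under zero variance on
  either side; `r2_method="ss"` switches to 1 − SSres/SStot.
* **RMSE**, plus RMSE normalized by the observed RMSSD range pooled
  across the five traits (per-trait normalization available via
  `ModelConfig.norm_range`).
* A participant's five models are flagged *consistently informative*
  when the worst R² is ≥ 0.05 and the mean normalized RMSE ≤ 0.25
  (boundaries inclusive; any undefined R² fails conservatively).

`StateChangeResults.r2_pooled` additionally reports the cross-validated
R² over all held-out predictions pooled across folds. The two statistics
answer different questions: the fold average (the headline reporting
statistic) describes typical within-person predictability but carries a
chance floor of roughly `1/(n−1) ≈ 0.2` at 6-row folds under the Pearson
convention, because small-sample correlations are biased away from zero;
the pooled statistic is ≈ 0 in the absence of signal and is therefore
the right quantity for signal-versus-null comparisons, which is how the
test suite uses it. The fold-level SS convention is harsher still: when
within-subject outcome variance is small relative to RMSSD sampling
noise, even the generative volatility predicts negatively at fold level.

Comparator baselines (elastic net and k-nearest neighbors, library
defaults on standardized features) run under the identical LOSO scheme
via `fit_comparators`.

## Permutation importance

Raw importance of a predictor is the mean increase in model RMSE over
`n_repeats` (default 10) shuffles of its column; negative values —
permutation noise — are floored at zero, and the permutation RNG is
seeded per (fold, feature). By default importance is computed on each
fold's training rows and averaged across folds (`scope="folds"`);
`scope="pooled"` refits once on all rows and evaluates once, which is
the cheap setting used in the large simulation sweeps. Per trait, raw
vectors rescale linearly to 0–100 (min → 0, max → 100; an all-equal
vector maps to zero); the cross-trait profile averages the five scaled
columns feature-wise and ranks descending, ties broken alphabetically.
The boosted-tree lineage this follows describes importance as
error-change under permutation, and that description is what is
implemented here (gain-based tree importances are a different statistic
and are not used).

## Synthetic cohort generator

`netstate.simulate` emulates the structure of a six-week badge study so
the pipeline runs end to end with known ground truth:

* **Contacts**: 54 employees in four blocks (14/14/13/13); true contacts
  per unordered pair per workday are Poisson with rate 1.2 within a
  block and 0.15 between (within-team contact dominates, as in real
  workplaces); each true contact is logged by each side's detector
  independently with probability 0.85 (dropout 0.15), producing the
  reciprocity discrepancies the min-count rule reconciles. Timestamps
  are uniform over 09:00–17:59. The resulting weekly networks have
  ≈ 0.55 density at the default rates.
* **EMA**: prompts three times per workday at 11:00, 14:00 and 17:00
  (15 per week). Per participant, week and trait, true volatility is
  `σ = max(0.05, 0.3 + 0.5·z)` where `z` is the ego-network efficiency
  standardized within week across participants (isolated participants
  fall back to baseline). Responses follow a first-order latent walk —
  each response perturbs the previous by `N(0, σ)` — so σ maps
  monotonically onto expected weekly RMSSD; a small response noise
  (SD 0.1) is added and values are clipped to [1, 7] and rounded to the
  half-point grid. Trait means are drawn per person from N(4.5, 0.8)
  clipped to [2, 6].
* All randomness flows from one root seed through named substreams
  (contacts, dropout, trait means, per-week EMA), so outputs are
  byte-identical per (config, seed) and any week regenerates
  independently.

What the generator deliberately does **not** model: diurnal or weekday
rhythm in contact rates, participant dropout over weeks, heavy-tailed
dyad heterogeneity, demographic covariates, and any direct
person-to-person personality influence. Passing tests on this cohort
therefore show that the pipeline recovers a network-mediated volatility
signal when one exists and reports none when it does not — they do not
certify effect sizes on real badge data, whose contact structure is
burstier and whose EMA compliance is imperfect.

## Problem sizes and numerical choices

The simulation-based checks use the full default cohort (54 participants
× 6 weeks, ten seeds for the planted and null conditions) with the
one-candidate reduced grid and pooled-scope importance with 5 repeats —
the configuration chosen so a complete recovery experiment is a
desk-scale computation. Brute-force feature oracles run on random
connected graphs of 3–7 nodes whose weights are powers of two, which
makes inverse-weight path lengths exact in binary floating point so
shortest-path tie sets are decided identically by exact rational
arithmetic and by float Dijkstra; feature agreement is asserted to 1e-9.
Timestamp ties in EMA ordering resolve by input file order (stable
sorts throughout). Hyperparameter ties resolve to the first grid
candidate; modularity ties resolve to the first optimum in a canonical
node ordering.

## Known limitations

* Egocentric features are undefined for isolated person-weeks; those
  rows are dropped rather than imputed, which biases the modeled sample
  toward socially active weeks (the real deposit shows the same
  property: fewer modeling rows than participants × weeks).
* Fold-level R² on 1–6 rows is a noisy, convention-sensitive statistic;
  both conventions and the pooled alternative are reported, but
  idiographic (per-participant) conclusions from single folds remain
  fragile.
* The feature set is fixed to the 26 listed structural measures plus
  week; no eigenvector/PageRank centralities, weighted clustering, or
  temporal within-week dynamics.
* Permutation importance is a scalar magnitude; it does not give the
  direction of a feature's effect.
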