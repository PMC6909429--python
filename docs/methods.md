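# Methods

## Model

A resected pancreaticoduodenectomy specimen is idealised as a pool of
`total_nodes` = N regional lymph nodes, of which an unknown number M
(0 ≤ M ≤ N) are truly involved by tumour. A lymphadenectomy that examines
n ≤ N nodes is modelled as a simple random sample without replacement from
the pool, so the observed positive count m follows the hypergeometric
distribution P(n, m, N, M). The key exchangeability assumption is that
involved and uninvolved nodes are equally likely to be retrieved — no
involved node is preferentially sampled (or missed) by the surgeon or
pathologist.

The prior q(M) is empirical: among patients with n ≥ N examined nodes
("complete dissections", for whom m = M by construction), q(M) is the raw
relative frequency of each involved count, estimated separately per AJCC
8th-edition T stage (T1 ≤ 2 cm < T2 ≤ 4 cm < T3) because nodal burden
rises with tumour size. Bayes' theorem then gives the posterior
r(M | n, m) ∝ q(M) · P(n, m, N, M), normalised over M.

Two posterior summaries are reported: the **accuracy** r(m | n, m) that the
reported count is the true count, and the **N2 probability**
Σ_{M ≥ n2_cutoff} r(M | n, m) that the patient meets the N2 definition
despite an observed count below it.

### Structural zeros

The posterior support is exactly [m, m + (N − n)]: at least the observed
positives are involved, and at most the N − n unexamined nodes can hide
more. Hence the N2 probability is *identically zero* — for every prior —
once n ≥ N − (n2_cutoff − 1 − m); at N = 15 and cutoff 4 this gives the
rule-out minimums of 13, 14 and 15 examined nodes for 1, 2 and 3 observed
positives. These are arithmetic facts of the sampling model, not estimates.

## Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `total_nodes` (N) | 15 | nodes | the ISGPS adequacy standard for pancreaticoduodenectomy; the pool size the staging tables assume |
| `n2_cutoff` | 4 | nodes | AJCC 8th-edition N2 definition (≥ 4 positive regional nodes) |
| `certainty_threshold` | 0.90 | probability | default level for adequacy queries; 0.80 is also conventional and both are reported by `threshold_report` |
| prior `pseudocount` | 0 | patients | the estimation rule is a raw frequency; smoothing is available but off by default |
| table ranges | n = 4–14, m = 1–3 | nodes | the conventional display range of the published staging tables; configurable |

Threshold queries compare unrounded probabilities with ≥; rounding to one
decimal of a percent (half away from zero) happens only at display time.
Probabilities are computed with exact integer binomial coefficients (N is
small), so complete-dissection accuracies are exactly 1 and infeasible
cells exactly 0; the N2 probability is computed as the complement of the
below-cutoff posterior mass accumulated in the same order as the
normaliser, which makes the m = 3 complement identity
(N2 probability = 1 − accuracy) bitwise exact.

### Handling of edge cases

* Patients with more than N examined nodes are complete dissections; if
  they report more than N positives (possible in registry data), the count
  is capped at N with a logged warning ("cap" policy) or the patient is
  dropped ("exclude" policy). The cap is the default because it is the only
  choice consistent with a fixed N-node support.
* A prior whose support is incompatible with an observation (zero
  normaliser) raises an inference error naming the observation; table cells
  affected are left absent, never zero-filled.
* When a coded T stage and a tumour size disagree, the coded stage wins
  with a logged discrepancy (registry-coded stage is the source of truth).
* Cohort summaries report the examined-node spread as the 25th–75th
  percentile range around the median, and label it as such.

## Table inversion

Published staging tables are themselves posterior summaries, so each cell
is one homogeneous linear constraint on q: an accuracy cell v at (n, m)
gives v · Σ_M q(M) P(n,m,N,M) − q(m) P(n,m,N,m) = 0, and an N2 cell the
analogous cumulative form. The stacked system plus a normalisation row is
solved by non-negative least squares (deterministic, no initialisation).
Support points no supplied cell probes are structurally unidentifiable —
always M = 0 (zero likelihood in every m ≥ 1 cell) and, for tables with
m < n everywhere, M = N — and are excluded from the solve, reported as
`undetermined`, and assigned zero mass. The recovered prior is therefore
conditional on the identifiable support; it yields posteriors identical to
the generating prior's at every observation whose likelihood vanishes on
the undetermined points, which covers the entire printed table range.
Duplicate cells are averaged with a warning; an inconsistent system leaves
a logged residual (rounded tables are expected to carry ~0.05-percentage-
point quantisation noise) rather than failing.

## Synthetic cohorts

The simulator draws, per patient: a T stage from a mixture; the true
involved count M from the stage prior; an examined count n from a
categorical ELN distribution; and the observed count m by hypergeometric
sampling of n from N nodes (for n ≥ N, m = M). Drawing M first and
sampling nodes without replacement mirrors the model's exchangeability
assumption exactly, which is the point: the simulator is the model's own
generative counterpart, giving ground truth against which the posterior
summaries can be checked for calibration.

Defaults emulate the published registry cohort the staging tables came
from: stage mixture 18.5/60.8/20.7% (T1/T2/T3); examined-node mass
32.9/22.7/44.4% over the <10 / 10–14 / ≥15 categories, uniform within
category with a tail to 24 nodes (median 13); stage priors obtained by
inverting the published per-stage accuracy tables, with q(0) set to the
published node-negative proportions (47.8/33.2/31.4%) since inversion
cannot identify it; 3% metastatic and 2% incomplete records to exercise
the selection filters. Tumour sizes are drawn uniformly within the stage's
AJCC size band for record realism.

What the simulator does **not** emulate: survival and treatment fields,
demographic structure, correlation between tumour size and nodal burden
*within* a stage, inter-hospital variation in node retrieval, and any
violation of node exchangeability (e.g. involved nodes being larger and
preferentially retrieved). Passing calibration tests therefore shows the
inference machinery is correct under the model's assumptions — not that
the assumptions hold in real registries. In particular, if involved nodes
are preferentially examined in practice, real-world accuracies would be
higher (and N2 probabilities lower) than the model reports.

## Numerical choices

* Binomial coefficients via exact integer arithmetic (`math.comb`); no
  log-space evaluation is needed at N ≤ ~60.
* Prior estimation counts with rational arithmetic and divides once, so
  estimated priors sum to 1 to float precision regardless of patient
  counts.
* NNLS normalisation row weight 1.0; the homogeneous system fixes q only
  up to scale, so the recovered vector is renormalised exactly after the
  solve.
* Test problem sizes: Monte-Carlo calibration uses a 200,000-patient
  cohort (every default table cell is then populated well enough for a
  3-standard-error comparison) and prior recovery uses 50,000
  complete-dissection patients per stage, both seed-fixed; exhaustive
  enumeration oracles run at pool sizes ≤ 8, where the full (M, subset)
  space is small.

## Known limitations

* N is fixed at a single assumed pool size; real specimens vary around it,
  and no prior over N is modelled.
* No sampling-error uncertainty is propagated from the estimated q(M) into
  the posterior (the prior is treated as known).
* The inversion recovers q only on the support the supplied cells probe;
  q(0) (and q(N), for standard tables) must come from elsewhere.
* Accuracy for patients with ≥ 4 observed positives is not tabulated; the
  model applies but the published display convention stops at m = 3.
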