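# nodalstage

**How trustworthy is a node-positive report after an inadequate
lymphadenectomy?**

When a pancreaticoduodenectomy for pancreatic ductal adenocarcinoma (PDAC)
retrieves fewer than the recommended 15 regional lymph nodes, the reported
count of positive nodes may understate the truth: involved nodes can be left
behind unexamined. That matters clinically because AJCC 8th-edition N stage
hinges on the positive count — N0 (0), N1 (1–3), N2 (≥ 4, stage III) — and
an occult N2 changes prognosis and adjuvant-therapy decisions.

`nodalstage` quantifies that uncertainty for surgeons, pathologists and
registry analysts. It treats the specimen as a pool of N = 15 regional nodes
of which an unknown M are involved, models an n-node lymphadenectomy as
sampling without replacement, and combines the hypergeometric likelihood

$$P(n, m, N, M) = \frac{\binom{M}{m}\binom{N-M}{n-m}}{\binom{N}{n}}$$

with an empirical prior q(M) — the frequency of each true involved count
among complete-dissection patients (≥ 15 examined nodes), estimated
separately for T1/T2/T3 tumours — to give the posterior over the true count:

$$r(M \mid n, m) = \frac{q(M)\,P(n,m,N,M)}{\sum_{M'} q(M')\,P(n,m,N,M')}.$$

Two posterior summaries drive all outputs:

* **accuracy** — r(m | n, m), the probability the reported positive count is
  the whole truth;
* **N2 probability** — Σ_{M ≥ 4} r(M | n, m), the probability the patient is
  really N2 despite an observed count of 1–3.

The package provides the model core, stage-specific prior estimation from
patient-level cohorts, the per-stage accuracy and N2-probability staging
tables, adequacy threshold queries (minimum examined-node counts for a given
accuracy, or for a 0% residual N2 risk), a constrained-least-squares
inversion that recovers a prior from a printed staging table, a synthetic
registry-cohort simulator with known ground truth, and a CLI tying the
stages together.

## Worked example

The package ships the published per-stage staging tables for PDAC
pancreaticoduodenectomy (derived from a US SEER cohort under the 15-node
model). Inverting the T1 accuracy table recovers the T1 prior, which then
answers any query:

```python
from nodalstage import (Observation, accuracy, prob_at_least, invert_table,
                        reference_cells, min_eln_for_accuracy,
                        min_eln_rule_out_n2, accuracy_table)

prior = invert_table(reference_cells("T1", "accuracy"), stage_label="T1")
obs = Observation(n=9, m=1)   # 9 nodes examined, 1 positive
print(f"accuracy:       {accuracy(prior, obs):.3f}")
print(f"P(N2 | n=9, m=1): {prob_at_least(prior, obs):.3f}")
print(f"min ELN, 80% accuracy at m=1: {min_eln_for_accuracy(prior, 1, 0.80)}")
print(f"min ELN to rule out N2 at m=1: {min_eln_rule_out_n2(prior, 1)}")
print()
print(accuracy_table(prior, n_range=range(12, 15)).to_text())
```

prints

```
accuracy:       0.512
P(N2 | n=9, m=1): 0.051
min ELN, 80% accuracy at m=1: 13
min ELN to rule out N2 at m=1: 13

Accuracy of the reported positive-node count (T1)
positive_nodes_observed      1      2      3
examined_nodes
12                       74.0%  59.9%  52.4%
13                       82.4%  71.5%  66.1%
14                       91.1%  84.8%  82.0%
```

Reading: a T1 patient reported node-positive with 1 of 9 nodes involved has
only a 51% chance that "1 positive node" is the true count, and a 5% chance
of being an occult N2. Thirteen examined nodes are needed before a single
positive node is 80% believable — and 13 is also the point at which a
fourth involved node becomes arithmetically impossible (only 2 nodes remain
unexamined), so the residual N2 risk drops to exactly zero.

The same analysis runs from the shell on any cohort CSV (schema in
`nodalstage --help` and the `nodalstage.cohort` docstring):

```bash
nodalstage simulate --n-patients 10000 --seed 5 --out cohort.csv
nodalstage summarize cohort.csv
nodalstage estimate-prior cohort.csv --stage T2 --out prior_T2.json
nodalstage tables --prior prior_T2.json --out-dir tables/
nodalstage thresholds --prior prior_T2.json
```

## Layout

| module | contents |
| --- | --- |
| `nodalstage.model` | hypergeometric likelihood, posterior, accuracy, N2 probability |
| `nodalstage.priors` | q(M) estimation from complete dissections; serialization |
| `nodalstage.tables` | staging tables, threshold queries, display rounding |
| `nodalstage.inversion` | printed-table → prior recovery (NNLS); shipped reference tables |
| `nodalstage.cohort` | cohort CSV schema, selection filters, T staging, summaries |
| `nodalstage.simulate` | registry-like synthetic cohorts with ground truth |
| `nodalstage.pipeline` / `nodalstage.cli` | end-to-end runs, manifest, subcommands |

See `docs/methods.md` for the model's assumptions, parameter choices and
limitations.
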