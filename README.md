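# socspat

Who sits where during feeding competition, and why?  `socspat` analyses
scan-sampling data from a provisioned, group-living primate colony (the
motivating system is a semi-free mandrill group observed in front of a
feeding zone) and asks how an individual's spatial position relates to two
layers of social organisation: the **dominance hierarchy** and the
**affiliative association network**.

It is aimed at behavioural ecologists working with three standard field
tables — per-scan individual positions on a mapped grid, an ad libitum
agonistic log, and individual metadata (sex, age, matriline) — and
produces the full chain of analyses:

* **Spatial metrics.** Euclidean distance of every observation to the
  feeding-zone door centroid yields, per individual, the relative
  frequency of afternoon observations within 10 m (F10M, analysed as
  √F10M = SRF10M) and the count of observations over 20 m or out of sight
  (F20M).
* **Dominance.** Dyadic wins from clear-outcome two-party interactions
  give the chance-corrected dyadic dominance index
  D<sub>ij</sub> = P<sub>ij</sub> − (P<sub>ij</sub> − ½)/(n<sub>ij</sub> + 1),
  the modified David's score MDS<sub>i</sub> = w + w₂ − l − l₂ (Σ MDS = 0),
  and hierarchy linearity via Landau's h and de Vries' h′ with a
  randomization test.
* **Association networks.** Half-weight index
  HWI = x / (x + y<sub>AB</sub> + ½(y<sub>A</sub> + y<sub>B</sub>)) on 1-m
  proximity dyads; a within-scan permutation test of non-random
  association (degree-preserving double-edge swaps per scan, CV of the
  HWI matrix as statistic); Newman leading-eigenvector modularity to
  divide the group into subgroups; and a 5-m food-patch co-occurrence HWI
  network.
* **Matrix inference.** Permutation Pearson/t tests, Mantel tests, MRQAP
  with Dekker's double-semi-partialing, and variance partitioning with
  semipartial r² — all with seeded permutation p-values.
* **Synthetic data.** A generator that emulates the study design (39
  adults, 26 scans/day over 24 days, dominance-attracted feeding-zone
  use, cohesive kin/sex-assortative subgroups) with known ground truth,
  so every stage is testable without the unreleased field data.

## Worked example

Simulate a study-scale dataset and run the three hypothesis analyses:

```sh
socspat simulate --seed 7 --out data
socspat analyze --scans data/scans.csv --agonistic data/agonistic.csv \
    --individuals data/individuals.csv --config run.yaml --out report.json
```

with `run.yaml` setting `n_perm: 1000`, `seed: 7`.  The CLI prints

```
H1: r(SRF10M, MDS) = 0.266 (p = 0.05495); r(F20M, MDS) = -0.449 (p = 0.003996)
```

i.e. for this replicate high-MDS (dominant) individuals are observed near
the feeding door somewhat more (one-tailed permutation Pearson, marginal
here) and far from it significantly less.  `report.json` holds the full
results; highlights from the same run:

* hierarchy linearity h′ = 0.672, p(perm) = 0.0005 — a significantly
  linear hierarchy;
* non-random association, p(perm) = 0.001; modularity Q = 0.693 with 7
  subgroups (Q > 0.3 marks a useful subdivision);
* variance partition of SRF10M: semipartial r² = 0.02 for MDS vs 0.84
  for subgroups — spatial position is structured far more by subgroup
  membership than by rank once the other is controlled;
* the 5-m co-occurrence network correlates with the zone-excluded
  affiliative network (Mantel r = 0.31), and 100% of feeding-zone dyads
  also associate elsewhere.

The same pipeline runs unchanged on real field tables with the file
formats documented in `socspat.data_io`.

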