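# neobasket

Statistical machinery of a two-cohort neoadjuvant immunotherapy trial in
mismatch-repair-deficient (dMMR/MSI) colorectal cancer, rebuilt as a tested,
reusable Python package. One basket enrols clinical T4 colon cancers, the
other rectal cancers; each is scored by pathological complete response (pCR,
tumor regression grade 0, equivalently ypT0N0) against its own historical
control. The package is aimed at trial statisticians and methods
researchers who want to rerun, audit or extend this class of design.

It provides, in one place:

* **Individual-patient endpoint analysis** — a validated 22-patient data
  model (cohort, regimen, RAS/RAF, surgery, ypTN, TRG, follow-up), analysis
  sets (FAS/PPS/SS), and derivation of pCR, TRG, R0 and mutation-rate
  counts, each with a two-sided exact interval.
* **Exact binomial intervals** — Clopper-Pearson via the beta-quantile
  identity (lower bound solves `P(X >= x | n, p) = alpha/2`), plus Wilson
  and Jeffreys comparators and a deterministic enumeration oracle for
  coverage. Published cells that are inconsistent with the exact method are
  flagged, never silently matched.
* **Survival layer** — Kaplan-Meier product-limit curves with Greenwood
  variance and linear-scale intervals, reverse-KM median follow-up with
  IQR, and Tukey-hinge time-to-surgery summaries.
* **Bayesian hierarchical basket design** — binomial cohorts with
  exchangeable null-offset logits, `delta_j = logit(p_j) - logit(p0_j)`,
  `delta_j | mu, tau ~ N(mu, tau^2)`, `mu ~ N(0, 10^2)`,
  `tau ~ Half-Normal(1)`; deterministic quadrature and random-walk
  Metropolis posteriors cross-checked against each other; the literal
  two-stage go/no-go rule (colon >2/11, rectum >3/8, then 28/16 total);
  simulation calibration of the per-cohort success thresholds to a 5%
  type-I error; operating characteristics; and the posterior-predictive
  probability of success given interim data.
* **Synthetic data** — a generator reproducing the patient table's
  structure, used for end-to-end parameter-recovery tests.

## Worked example

```python
import neobasket as nb

records = nb.load_patients()                    # packaged 22-patient table
sets = nb.assign_analysis_sets(records)
colon = nb.derive_endpoints(records, sets, "colon", "fas")
print(colon.pcr_x, "/", colon.pcr_n,
      nb.clopper_pearson(colon.pcr_x, colon.pcr_n).as_percent_string())

design = nb.DesignSpec.published()              # 3%/15% and 10%/35%, 11->28, 8->16
cal = nb.calibrate_gamma(design, n_sim=10_000, seed=1)
stage1 = nb.stage1_counts(records, sets)
pos = nb.probability_of_success(
    design.with_gamma(cal.gamma),
    (stage1["colon"], stage1["rectum"]),
    n_sim=10_000, seed=2,
)
print(dict(cal.gamma), round(pos.joint, 4))
```

prints

```
8 / 14 57.1 (28.9-82.3)
{'colon': 0.5, 'rectum': 0.5} 1.0
```

Reading: 8 of 14 colon patients achieved pCR, 57.1% with exact 95% CI
28.9-82.3 — far above the 3% historical control. Calibration returns the
smallest grid threshold (0.50) for both cohorts because, under the literal
joint continuation rule, a null trial almost never reaches the final
analysis: the stage-1 bars alone control the type-I error. Given the
observed stage-1 results (8/14, 6/8), the posterior-predictive probability
that the completed trial succeeds in both cohorts is indistinguishable from
1 at 10,000 replicates — the design's "probability of success above 99%".

The same operations are scriptable from a shell:

```
neobasket validate src/neobasket/data/patients.csv
neobasket table2 src/neobasket/data/patients.csv --format md
neobasket design calibrate --n-sim 10000 --seed 1
neobasket design pos --stage1 8/14,6/8 --n-sim 10000 --seed 2
neobasket simulate patients --seed 5 --out synth.csv
```

`table2` rebuilds the efficacy table with a recompute-vs-printed audit:
four published interval cells are inconsistent with the exact method the
publication states (e.g. 6/8 printed as 35.6-95.5 where the exact interval
is 34.9-96.8); these are flagged with both values shown.

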