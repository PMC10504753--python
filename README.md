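# symptomnet

Symptom-network analysis of comorbid anxiety and depression in screened
survey cohorts: a reusable Python implementation of the full pipeline used
in network psychometrics studies of childhood-sexual-abuse (CSA) survivors
— screening and prevalence, descriptive group comparisons, regularized
partial-correlation network estimation, centrality and bridge indices,
sex-stratified permutation comparison, and bootstrap stability — driven by
a synthetic-cohort generator with a known planted network, so every stage
is testable without access to raw survey data.

## The scientific problem

Large surveys screen college students for CSA with the CTQ-SF (28 items,
1–5; a sexual-abuse subscale score ≥ 8 flags moderate-to-severe exposure)
and measure anxiety (GAD-7, 7 items, 0–3) and depression (PHQ-9, 9 items,
0–3) in the flagged subsample. Rather than comparing total scores, the
network approach treats each symptom as a node and estimates a Gaussian
graphical model (GGM): edges are partial correlations `w_ij` between
symptoms after conditioning on all other symptoms, so a missing edge means
conditional independence.

The estimator is the EBIC graphical lasso. Given an item correlation
matrix `S` (Spearman by default for ordinal Likert items) the penalized
precision matrix solves

```
max_Θ  log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θ_ij|
```

over a log-spaced λ path; each fit is scored by the Extended Bayesian
Information Criterion

```
EBIC = −2 logL + E log n + 4 γ E log p        (γ = 0.5, E = edge count)
```

with `logL` recomputed from the unpenalized fit restricted to the selected
sparsity pattern, and the winner is converted to partial correlations
`w_ij = −Θ_ij / √(Θ_ii Θ_jj)`.

On the selected network the pipeline computes, per node *i*:

* **expected influence** `EI(i) = Σ_j w_ij` (signed, one-step),
* **bridge expected influence** `bEI(i) = Σ_{j in other community} w_ij`
  across the anxiety/depression boundary (so `EI = bEI + within-community
  sum`, exactly),
* **predictability**: the `R²` of regressing item *i* on the remaining
  items.

Group networks (male vs female) are compared with a permutation network
comparison test (global strength `Σ|w_ij|`, maximum edge difference `M`,
and per-edge differences with Holm correction), and estimation uncertainty
is quantified by a non-parametric edge bootstrap plus the case-dropping
correlation-stability (CS) coefficient: the largest fraction of
participants that can be dropped while subsample and full-sample
centrality still rank-correlate ≥ 0.7 with 95% probability.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort at the emulated survey's scale (96,218 screened participants;
`python analysis/01_simulate.py` … `07_stability.py`; outputs under
`results/analysis/`, large intermediates under `scratch/`). The screening
stage prints:

```
synthetic: 3439/96218 CSA-positive (3.57%, 95% CI 3.46-3.69%)
retained after comorbid-abuse exclusion: 2399
published counts reproduce 3.62% (3.50-3.73%)
```

i.e. the generator's severity calibration lands the synthetic CSA
prevalence near the published survey value, and the published counts
(3,479 / 96,218) reproduce the published prevalence and Wald interval
exactly. Network estimation on the screened subsample then reports:

```
n=2399: 13 edges selected at lambda=0.0802
strongest edges:
node_i node_j   weight
  GAD2   GAD3 0.162928
  PHQ1   PHQ2 0.144139
  PHQ3   PHQ4 0.115652
rank correlation with planted nonzero weights: 0.908
```

The three strongest recovered edges are exactly the planted strong
within-instrument edges (control worry–worry a lot; anhedonia–sad mood;
sleep–energy), and the estimated weights rank-correlate 0.91 with the
planted truth. The stability stage reports `CS(expected_influence) = 0.60
[good]`, meaning 60% of cases can be dropped before the centrality ranking
degrades below the 0.7/95% criterion.

The same stages are available as a CLI
(`symptomnet simulate|screen|describe|estimate|centrality|compare|stability|run`)
and as one orchestrated run (`symptomnet run --config run.yaml`), which
writes a manifest with per-stage row counts, sub-seeds, and content hashes
(reruns are byte-identical).

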