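# cpapnet

Network-medicine analysis of CPAP treatment response in obstructive sleep
apnea (OSA), built around two linked questions:

1. **Which patients respond to one night of CPAP?** Patients are placed in a
   *risk-compatibility network*: each of six clinical measurements — gender,
   age group, hypertension (systolic > 140 or diastolic > 90 mmHg), obesity
   (BMI > 30 kg/m²), thick neck (NC ≥ 40 cm women / ≥ 43 cm men), sleepiness
   (Epworth score ≥ 11) — is discretized into classes, and two patients are
   linked when they fall in identical classes for at least 4 of the 6
   parameters (edge weight = number of shared classes). Modularity
   communities of this graph are phenotype groups; each community is scored
   by its *AHI improvement* — the percentage of patients severe before
   treatment (apnea–hypopnea index AHI ≥ 30 events/h) who are reclassified
   to normal/mild (AHI < 15) afterwards — and labeled a **best** (≥ 85%
   improvement) or **good** response class.
2. **Can a single tape-measure number predict the response class?** Neck
   circumference (NC) is evaluated as a screening score: ROC analysis of NC
   for OSA-diagnosed versus control cohorts, the Youden-optimal cutoff
   `argmax (sensitivity + specificity − 1)`, diagnostic metrics
   (PPV/NPV/LR±) at whole-centimetre cutoffs, and finally the chosen cutoff
   used to classify patients into the network-derived response classes.

The modularity of a partition A = {C₁..C_m} is

    M(A) = Σ_C [ W_C/W − (s_C/2W)² ]

with W the total edge weight, W_C the intra-community weight and s_C the
community strength; maximization is Louvain-style with seeded restarts,
single-node-move and pair-merge refinement, plus an exhaustive enumeration
oracle for graphs of ≤ 10 nodes. A force-directed layout (attraction
exponent a = 1 on edges, repulsion exponent r = −1 on all pairs) provides
the spatial-clustering diagnostic.

Because the underlying clinical tables are only available as published
summaries, a first-class synthetic-cohort module generates the three study
cohorts from their printed moments: a 145-patient CPAP-titration cohort
with planted phenotype communities and a thick-neck-dependent response
model, an OSA-diagnosed screening cohort (n = 836, NC 44.91 ± 4.45 cm) and
a control cohort (n = 65, NC 40.67 ± 5.77 cm), with NC–AHI rank dependence
induced by a Gaussian copula (Spearman ρ = 0.35).

## Worked example

The analysis is organised as numbered drivers over the library:

```sh
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_build_network.py --seed 1
python analysis/03_response_classes.py
python analysis/04_roc_cutoff.py
python analysis/05_nc_threshold_on_network.py
```

which prints (abridged):

```
network: 145 nodes, 5902 edges, density 0.565, giant component 145
communities: 3 at modularity 0.2134
layout agreement (intra/inter distance): 0.282 (<1 means clustered layout)
community 0: improvement  89.2% -> best; thick-neck class 1 (100%)
community 1: improvement  74.2% -> good; thick-neck class 0 (94%)
community 2: improvement  83.9% -> good; thick-neck class 0 (94%)
AUC 0.691 (95% CI 0.633-0.749) over 836 OSA vs 65 controls
Youden-optimal NC cutoff: 42 cm
Spearman NC-AHI in the OSA group: rho=0.367 (p=5e-28)
at the Youden cutoff 42 cm, good-class: TPR 0.887, TNR 1.000, PPV 1.000
```

Reading: the all-thick-neck community improves in 89% of severe patients
(best class) while thin-neck communities stay below the 85% threshold; on
the screening cohorts NC separates OSA from controls with AUC ≈ 0.69, and
the Youden cutoff (here 42 cm; across seeds it concentrates on 41–43 cm)
classifies the network's response classes with high precision. Note that
two of the four planted phenotype groups differ in only one of six
parameter classes, so resolution-1 modularity merges them and three
communities are detected — see `docs/methods.md`. Reports land in
`results/` as `table2.csv` … `table7.csv`, `roc.json`, `partition.csv`,
`layout.csv`, `network.gexf`.

The same stages are available as a console tool
(`cpapnet run-all --outdir out --seed 1`, plus `simulate`,
`build-network`, `communities`, `response`, `roc`, `evaluate-cutoff`).

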