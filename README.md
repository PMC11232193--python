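# cernet — patient-specific ceRNA networks and prognostic triplet screening

`cernet` builds **competing endogenous RNA (ceRNA) networks of lncRNA–miRNA–mRNA
triplets that are specific to an individual tumor sample**, and screens the
recurrently perturbed triplets as prognostic survival biomarkers.  It is aimed
at computational biologists working with matched normal/tumor RNA-seq cohorts
(e.g. TCGA-style data) who want per-patient network rewiring rather than one
cohort-level network.

## Method

Under the ceRNA hypothesis, a lncRNA *x* and an mRNA *y* that share miRNA
response elements compete for the same miRNA *z*, coupling their abundances.
For a candidate triplet (*x*, *z*, *y*) the coupling net of the shared miRNA is
the first-order partial correlation

```
ρ(x, y | z) = ( PCC(x,y) − PCC(x,z)·PCC(y,z) ) / ( √(1 − PCC²(x,z)) · √(1 − PCC²(y,z)) )
```

where PCC is the Pearson correlation.  A network cannot be estimated from a
single sample, so the pipeline proceeds in three steps:

1. **Reference network** — ρₙ per triplet over the *n* normal samples.
2. **Perturbed network** — for each tumor sample, ρₙ₊₁ recomputed on the *n+1*
   samples obtained by appending that single sample; the patient-specific edge
   weight is the differential partial correlation **Δρ = |ρₙ₊₁ − ρₙ|**.
3. **Selection** — per sample, keep edges with |ρₙ₊₁| > 0.7 and p < 0.05
   (t-test on n−3 degrees of freedom for one conditioning variable);
   then keep triplets whose mean Δρ over the passing samples differs from zero
   by a one-sample Z-test (α = 0.05, ≥ 3 passing samples).

Selected triplets are screened for prognostic value: each RNA is dichotomized
at its median over tumor samples, patients split into **Group 1** (opposite
lncRNA/mRNA levels) and **Group 2** (same levels), and within each group the
two sub-patterns form the binary covariate of a univariate Cox
proportional-hazards model (Efron ties).  Triplets with Wald p < 0.01 in
either group are reported as candidate prognostic biomarkers, with
Kaplan–Meier / log-rank outputs and Benjamini–Hochberg q-values alongside.

Candidate triplets come from two-column association lists (lncRNA–miRNA and
mRNA–miRNA, e.g. consensus exports of miRcode/starBase and
miRDB/miRTarBase/TargetScan) joined on the shared miRNA and restricted to the
genes measured in the cohort.  Networks are exported as SIF and GraphML
(Cytoscape-loadable, with `rna_type` node and `delta_rho` edge attributes).

## Worked example

The package ships a synthetic-cohort generator with known ground truth (20
planted triplets with conditional correlation 0.9 in normals, shifted by −0.5
in tumors, among 480 decoy triplets; one triplet also carries a planted hazard
effect):

```bash
cernet simulate --outdir demo --seed 7 --n-tumor 120 --log-hr 1.4
cat > demo/config.yaml <<EOF
expression: demo/expression.tsv
sample_classes: demo/sample_classes.tsv
lnc_mi: [demo/lncRNA_miRNA.tsv]
mrna_mi: [demo/mRNA_miRNA.tsv]
clinical: demo/clinical.tsv
outdir: demo/out
seed: 7
EOF
cernet run --config demo/config.yaml
```

which prints the per-stage manifest counts:

```json
{
  "cox_failures": 0,
  "cox_fits": 40,
  "edge_filter_survivors": 20,
  "excluded_triplets": 0,
  "initial_triplets": 500,
  "lnc_mi_associations": 260,
  "mrna_mi_associations": 260,
  "nonempty_patient_networks": 120,
  "normal_samples": 50,
  "prognostic_triplets": 1,
  "selected_triplets": 20,
  "tumor_samples": 120
}
```

All 500 candidate triplets were assembled from the association files; the edge
filter + Z-test kept exactly the 20 planted triplets (no decoy survives the
|ρ| > 0.7 filter), and the Cox screen flagged 1 triplet as prognostic — the
one carrying the planted hazard.  Its Group 1 row in `demo/out/cox_results.tsv`
reads hazard ratio 3.21 (planted: e^1.4 ≈ 4.1 diluted by median
dichotomization), p = 8.4e-4, while the same triplet in Group 2 shows p = 0.70
— the opposite-pattern group carries the signal, the same-pattern group does
not.  Per-patient networks and the pooled network are written under
`demo/out/networks/`.

The same stages are available as library functions
(`cernet.build_initial_triplets`, `cernet.perturb_cohort`,
`cernet.ztest_select`, `cernet.screen_triplets`, …) and as individual CLI
subcommands (`build-triplets`, `network`, `select`, `survival`, `export`).

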