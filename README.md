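# mesomark

Methylation-biomarker panel selection and MSRE/smMIP count classification
for pleural mesothelioma (PM).

PM is a rare, aggressive pleural tumor that is hard to tell apart from
healthy pleura, chronic pleuritis and pleural metastases of other cancers.
Tumor-specific DNA hypermethylation offers a molecular readout that
complements histopathology. `mesomark` implements a complete analysis chain
for such a biomarker assay, aimed at epigenomics analysts building or
evaluating methylation panels:

1. **Candidate CpG selection** from array-style beta values
   (β ∈ [0, 1], samples × CpGs). A CpG is a candidate when, against *every*
   control group, it is significantly hypermethylated in tumor
   (Benjamini–Hochberg adjusted p ≤ 0.05, Δβ > 0), control methylation is
   low and stable (mean ≤ 0.3, SD ≤ 0.1 per control group), and the CpG lies
   inside a recognition site of a methylation-sensitive restriction enzyme
   (MSRE) so that it is assayable by digestion. Survivors are ranked by
   min(Δβ) over control groups and truncated to the top k (default 1000).
2. **In-silico validation**: per candidate, a univariate LDA trained on one
   cohort scores an independent cohort; the AUC measures transferability.
3. **Count QC and normalization** for MSRE-digestion/smMIP-capture
   sequencing. Unmethylated lambda spike-in DNA gives a per-sample
   percent-undigested estimate, 100·mean(cut-site counts)/mean(reference
   counts); samples above 5% are excluded. Inefficient probes are removed
   using a cutoff of 1000 cumulative counts across undigested aliquots, and
   target counts are divided by the pooled human-reference count per sample.
4. **Two-step voting classifier.** For each retained probe a one-feature
   Gaussian LDA with shared variance is fit; its positive-class posterior is
   σ(ax + b) with a = (μ₁−μ₀)/σ², b = (μ₀²−μ₁²)/(2σ²) + ln(π₁/π₀), and a
   per-probe posterior cutoff maximizes accuracy. Probes with fivefold
   cross-validated AUC (cvAUC) < 0.8 are dropped, one probe per tiled CpG is
   kept, and the survivors vote: a sample is positive when ≥ C models agree,
   with the integer agreement cutoff C again chosen for maximum accuracy.
   Model A separates tumoral from nontumoral tissue; tumoral calls go to
   Model B, which separates PM from pleural metastasis.

A synthetic-data module generates beta-value cohorts and negative-binomial
smMIP count matrices with the structure the analysis assumes (injected
hypermethylated sites, digestion-dependent count means, spike-in controls,
library-size variation), so the whole pipeline is testable without access
to patient data.

## Worked example

```python
import mesomark as mm
from mesomark import classify as clf

cohort = mm.generate_two_step_cohort(n_per_group=20, seed=7)
normalized, qc, excluded, retained = mm.qc_normalize(cohort.matrix)
print("mean % undigested:", round(qc.percent_undigested.mean(), 2))
print("samples excluded:", len(excluded), "| target probes retained:", len(retained))

sheet = normalized.sample_sheet
y = sheet["group"].isin(["pm", "metastasis"]).astype(int)   # tumoral vs not
folds = clf.stratified_folds(sheet, k=5, seed=7)
reports = clf.evaluate_probes(normalized, y, folds)
kept = clf.select_smmips(reports, normalized.probe_annotation["cpg_id"])
model = clf.build_ensemble(normalized, y, folds, kept, positive_class="tumoral")
print("retained probes:", model.n_models, "| ensemble cvAUC:", model.cv_auc,
      "| agreement cutoff:", model.cutoff)
```

prints

```
mean % undigested: 1.03
samples excluded: 0 | target probes retained: 60
retained probes: 20 | ensemble cvAUC: 1.0 | agreement cutoff: 1
```

The simulated batch digested well (≈1% residual undigested, nobody above
the 5% exclusion line), all 60 probes passed the efficiency filter, and of
those, the 20 probes simulated as methylated in all tumoral samples were
retained (cvAUC ≥ 0.8, best tile per CpG). Out-of-fold votes separate the
groups perfectly here, so any agreement cutoff is optimal and the
documented tie-break picks the smallest, C = 1.

The same stages are available from the shell:

```sh
mesomark simulate --outdir sim --seed 7
mesomark select-dmcs --betas sim/betas.tsv --samples sim/beta_samples.tsv \
    --contexts sim/contexts.tsv --out dmcs.tsv
mesomark train --counts sim/counts.tsv --probes sim/probes.tsv \
    --samples sim/count_samples.tsv --seed 7 --outdir models
mesomark evaluate --confusion 33,29,2,4 --out metrics.tsv
```

The last command turns a confusion matrix (TP, TN, FP, FN) into the six
reporting statistics:

```
{"accuracy": 0.912, "balanced_accuracy": 0.914, "fn": 4, "fp": 2,
 "npv": 0.879, "ppv": 0.943, "sensitivity": 0.892, "specificity": 0.935,
 "tn": 29, "tp": 33}
```

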