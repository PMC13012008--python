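# napy-sclc — NAPY molecular subtyping of small cell lung cancer

Small cell lung cancer (SCLC) is commonly stratified into four molecular
subtypes named after the lineage transcription factor (TF) that dominates
each tumor's expression profile: **N**EUROD1, **A**SCL1, **P**OU2F3 and
**Y**AP1 ("NAPY"). This package implements a complete, reproducible NAPY
subtyping pipeline for bulk expression cohorts, aimed at computational
oncologists who need explicit, testable classification rules rather than
ad-hoc thresholds:

1. **TF-rule labeling.** Expression (log2(TPM+1)) is gene-wise z-scored
   across the cohort. The *strict* rule assigns sample *i* to the subtype of
   its top TF iff `z(1) − z(2) ≥ δ` (default δ = 0.3) and `z(1) ≥ 0`;
   samples failing either requirement stay unassigned ("borderline"). The
   *relaxed* rule is a plain argmax.
2. **Downstream-program derivation.** Every gene's Pearson correlation with
   each TF is computed on training samples; a gene is a candidate only for
   its argmax TF (*exclusive* association), and each TF keeps its top-*k*
   (default 20) candidates — four disjoint 20-gene programs, 80 features.
3. **Nested-CV linear SVM.** A one-vs-rest linear soft-margin SVM on the
   4×20 program genes, with programs, scaling and the cost hyperparameter
   selected inside a nested cross-validation (outer 4-fold × 5 repeats = 20
   runs, inner 3-fold), so performance estimates are leakage-free.
4. **Consensus calls.** A sample keeps a label only when the TF rule and
   the classifier agree; borderline samples are rescued when the relaxed TF
   call matches the classifier.
5. **Signature compendium scoring.** Per-sample signature score = mean
   z-score of the signature's genes; signatures must pass a *coherence*
   filter (mean pairwise gene–gene correlation > 0.2) and are retained when
   ≥ 3 of the 6 pairwise Wilcoxon tests between subtypes stay significant
   after Bonferroni correction.
6. **Genomic association.** Per-gene alteration frequencies (any of SNV /
   amplification / deletion, counted once per sample) filtered at > 5%, and
   a two-sided Fisher exact test on the 2×4 altered-by-subtype table (full
   enumeration with the probability-mass criterion, Monte Carlo fallback).
7. **Survival analysis.** Kaplan–Meier OS per subtype (log-log CIs) and Cox
   proportional-hazards models (Efron ties, Wald tests), with subtype
   contrasts reported against SCLC-P.
8. **Synthetic cohorts.** A seeded generator plants exactly this structure
   (elevated TFs, correlated 20-gene programs, borderline samples,
   subtype-enriched alterations, subtype-dependent survival) so that every
   stage is testable without any data download.

## Worked example

```python
from napy import (simulate, SimulationConfig, label_cohort, calls_to_series,
                  derive_programs, DerivationConfig, LabelingConfig,
                  nested_cv, TrainingConfig, stratified_split, fit_final_model,
                  predict_series, evaluate, consensus_labels, fisher_exact_rxc)

cohort = simulate(SimulationConfig(n_samples=400, seed=1))
m = cohort.expression

strict = calls_to_series(label_cohort(m, mode="strict"))
relaxed = calls_to_series(label_cohort(m, mode="relaxed"))
y = strict[strict != "unassigned"]
print(f"strictly labeled: {len(y)}/{m.n_samples}")

programs = derive_programs(m.subset_samples(y.index), LabelingConfig().tf_genes,
                           DerivationConfig(k=20))
train_ids, hold_ids = stratified_split(y, 0.2, seed=1)
cv = nested_cv(m.subset_samples(train_ids), y.loc[train_ids],
               DerivationConfig(k=20), TrainingConfig(seed=1))
model = fit_final_model(m.subset_samples(train_ids), y.loc[train_ids], cv)
rep = evaluate(predict_series(model, m.subset_samples(hold_ids)).to_numpy(),
               y.loc[hold_ids].to_numpy())
cons = consensus_labels(strict, relaxed, predict_series(model, m))
res = fisher_exact_rxc([[17, 6, 1, 1], [131, 112, 35, 74]])
```

Output:

```
strictly labeled: 279/400
subtype counts: {'N': 101, 'A': 91, 'Y': 52, 'P': 35}
NEUROD1 program head: ['NEUROD1_TGT13', 'NEUROD1_TGT12', 'NEUROD1_TGT08'] [0.734, 0.724, 0.718]
nested CV (20 runs): pooled macro balanced accuracy = 0.989
holdout macro balanced accuracy = 1.000 (cost = 0.0009765625)
consensus labels: 351/400 samples
MYCL amplification vs subtype: Fisher exact p = 0.018
```

Reading this: the strict rule labels 279/400 samples (the rest are
borderline by construction — the generator plants ~28% ambiguous cases);
the derived NEUROD1 program consists of planted NEUROD1 target genes with
correlations near the generator's 0.7 target; the nested CV's 20 runs and
the untouched 20% holdout agree closely (no optimism gap), and the
consensus step recovers most borderline samples. The final line recomputes
the Fisher exact association between MYCL amplification counts and subtype
from a published 2×4 contingency table; p = 0.018 rounds to the reported
0.02.

## Command line

Every stage is also a subcommand of the `napy` CLI, exchanging plain TSV
files (`napy simulate`, `label`, `derive`, `crossval`, `train`, `predict`,
`consensus`, `signatures`, `associate`, `survival`), and `napy pipeline
--config pipe.yaml` chains them end-to-end, writing a JSON manifest with
SHA-256 checksums of every artifact:

```bash
napy simulate --seed 1 --out-dir sim/
napy label --expr sim/expression.tsv --mode strict --out calls.tsv
```

## Layout

- `src/napy/expression.py` — matrix I/O, log2(TPM+1), separable z-scaling
- `src/napy/labeling.py` — strict/relaxed TF rules
- `src/napy/programs.py` — exclusive-correlation program derivation
- `src/napy/classifier.py` — nested-CV linear SVM, metrics
- `src/napy/consensus.py` — TF/ML consensus, χ² agreement
- `src/napy/signatures.py` — coherence filter, scoring, differential tests
- `src/napy/genomics.py` — alteration frequencies, Fisher exact r×c
- `src/napy/survival.py` — Kaplan–Meier, Cox PH
- `src/napy/simulate.py` — synthetic cohorts and the tiny worked example
- `src/napy/cli.py` — subcommand CLI and pipeline runner
- `docs/methods.md` — model assumptions, parameter choices, limitations
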