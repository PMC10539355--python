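# icplnc

Discovery of immune-checkpoint / lncRNA cooperative regulation pairs from
expression cohorts, and their evaluation as prognostic and
immunotherapy-response biomarkers.

Immune checkpoints (ICPs: PD-1, CTLA-4 and their relatives) are the
targets of checkpoint-inhibitor immunotherapy, and long non-coding RNAs
(lncRNAs) increasingly appear as their regulators. This package implements
a multi-step screening pipeline that starts from gene × sample log2
expression matrices and ends with pair-level biomarkers:

1. **Immune-cell screen** — quantile normalization, per-(gene, cell-type)
   batch mean-centering, and class-wise expression ranking across immune
   cell types. ICPs highly expressed (top 50% of their class) in ≥1 cell
   type are kept; lncRNAs are split into *immune-specific* (top 50% in
   exactly one cell type) and *immune-general* (top 50% in more than half
   of the cell types, i.e. >9 of 18).
2. **Infiltration and ICR grouping** — per-sample immune scoring with the
   single-sample GSEA running-sum statistic
   ES(s) = Σᵢ [P_in(i) − P_out(i)], with in-set steps weighted by
   rank^0.25; the top 75% of samples by immune score are retained and
   split into high/low groups by consensus clustering (resampled k-means,
   k = 2) of the 20-gene immunologic-constant-of-rejection (ICR) panel.
3. **Differential screen** — Welch t-test and fold change
   FC = 2^(mean_high − mean_low) between ICR groups (P < 0.05).
4. **Pair discovery** — every differential ICP × lncRNA combination is
   screened by two co-expression routes and accepted only when both hold:
   Pearson |r| > 0.3 with two-sided P < 0.05, and mutual information
   (plug-in estimate on equal-frequency bins) with permutation P < 0.05.
5. **Network analysis** — per-cohort bipartite networks of accepted
   pairs; scale-free R² from the log–log degree/frequency OLS fit; hubs =
   top 5% of nodes by degree; hubs in >5 cohorts are *common*, in exactly
   one are *specific*; cross-cohort similarity S(A,B) = |A∩B|/min(|A|,|B|).
6. **Survival screen** — per pair: random 50/50 cohort split, multivariate
   Cox model (z-scored ICP and lncRNA expression, age, sex; Efron ties) on
   the training half, held-out risk score
   β_icp·z(x_icp) + β_lnc·z(x_lnc), log-rank test between held-out
   median-split strata, and an empirical permutation null (1000
   permutations of the (time, event) columns by default, P < 0.05).
7. **Response prediction** — per-pair features feed an L1-penalized
   logistic regression (penalty by cross-validated deviance with the
   one-standard-error rule) to distil a small pair panel, a linear SVM is
   trained on the selected pairs, predictions are evaluated by ROC/AUC
   (Mann–Whitney form) and tested against the ICR groups with the
   two-sided Fisher exact test.

A synthetic-cohort generator (`icplnc.simulate`) produces immune-cell
panels and tumor cohorts with planted ground truth — correlated pairs, a
latent infiltration gradient, pair-driven hazards and response labels —
so every stage of the pipeline is verifiable end to end. It is intended
for computational biologists who want a tested, reproducible
implementation of this class of screen, or a calibrated test bed for
variants of it.

## Worked example

Simulate the reference two-cohort study and run the whole pipeline:

```bash
icplnc --config run.json --seed 7 --out-dir study run-all
```

with `run.json` containing `{"n_survival_perms": 200}`. This prints:

```json
{
  "planted_pair_recall": 0.975,
  "null_pair_acceptance": 0.002631578947368421,
  "coincidence_rate": 1.0,
  "prognostic_flag_rate": 1.0,
  "response_auc": 0.9425025329280649
}
```

Reading these numbers: of the 20 pairs planted with correlation 0.6 in
each cohort, 97.5% were accepted by the joint Pearson+MI screen, while
only 0.26% of the 380 unplanted combinations per cohort slipped through;
every Pearson-accepted pair was confirmed by the MI route (coincidence
rate 1.0); all planted prognostic pairs were flagged by the
200-permutation survival screen; and the SVM trained on cohort 1's
LASSO-selected pair panel separated responders from non-responders in
cohort 2 with AUC 0.94. Per-cohort pair tables and a JSON summary are
written to `study/`.

The same stages are available as individual subcommands (`simulate`,
`immune-screen`, `infiltrate`, `icr-de`, `pairs`, `network`, `survival`,
`response`) operating on plain TSV/GMT/JSON files, and as library
functions (`icplnc.run_study`, `icplnc.extract_pairs`,
`icplnc.permutation_screen`, ...).

## Layout

- `src/icplnc/data.py` — containers, TSV/GMT/JSON formats, configuration
- `src/icplnc/simulate.py` — synthetic panels and cohorts with truth
- `src/icplnc/immune.py` — normalization, batch adjustment, high-expression rules
- `src/icplnc/infiltration.py` — ssGSEA, sample selection, ICR consensus, DE
- `src/icplnc/pairs.py` — Pearson + MI pair screen
- `src/icplnc/network.py` — bipartite networks, hubs, similarity
- `src/icplnc/survival.py` — Cox/log-rank/permutation prognostic screen
- `src/icplnc/response.py` — pair scores, SVM, LASSO, ROC, Fisher
- `src/icplnc/pipeline.py` — end-to-end orchestration
- `docs/methods.md` — model assumptions, parameter choices, limitations
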