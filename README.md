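# emstate

Breast-cancer cells switch between an epithelial (E) program and a
mesenchymal (M) program, and cells co-expressing both — the hybrid E/M
state — behave stem-like and have been linked to poor patient outcome.
`emstate` is a tested analysis pipeline for the computational chain behind
that claim:

1. **Signature derivation** — from a clone-labelled bulk log2 expression
   matrix (E clones vs M clones), genes are ranked by a moderated
   two-sample t-test; the *effect size* is the difference of group means
   on the log2 scale. The top-*n* genes per direction form the E and M
   signatures and their interleaving forms a combined EM signature (e.g.
   60 = 30 E + 30 M genes).
2. **Signature-based survival analysis** — a patient's score is the mean
   log2 expression of the signature genes. The cohort is split at the
   best of the median/tertile/quartile cutoffs (smallest logrank *p*), and
   high- vs low-scoring groups are compared with the logrank test and a
   binary-covariate Cox model (Breslow ties): HR > 1 means high signature
   expression predicts poor outcome. Patients are subtyped from ESR1,
   MKI67 and HER2 marker probes (cutoffs 500 / 470 / 4800, strict `>`):
   luminal A, luminal B, basal, HER2.
3. **Resampling robustness** — random gene sets of the same size, run
   through the identical pipeline, give a permutation null for the
   signature's prognostic value (`permuted_p = (1 + #extreme)/(n_perm + 1)`),
   and sub-signature bootstrapping (e.g. 10 of 24 genes) measures how
   consistently subsets predict poor outcome.
4. **Single-cell qPCR state space** — raw Fluidigm-style Cq plates are
   converted via `Log2Ex = C_bg − C_q`, `expression = 2^Log2Ex` (Cq ≥
   background ⇒ 0), per-gene max-normalized over single cells, and each
   cell is projected to (mean of 10 E genes, mean of 7 M genes). Group
   separation in that plane is tested with the **cross-match test**: all
   cells are paired by a minimum-weight perfect matching and the number of
   cross-group pairs A1 has an exact combinatorial null,
   `P(A1=a1) = 2^a1 I! / [((n1−a1)/2)! a1! ((n2−a1)/2)! C(N,n1)]`.
   Per-panel Mann–Whitney U tests, standardized PCA and block-averaged
   Pearson correlations complete the picture.

A synthetic-data module generates all three modalities with known ground
truth (planted differential genes, a latent score driving an exponential
hazard with calibrated uniform censoring, and three-archetype Cq plates
with logistic detection dropout), so every stage is exercised end-to-end
without external downloads.

## Worked example

```bash
python analysis/01_simulate_data.py --seed 1
python analysis/02_derive_signatures.py
python analysis/03_signature_survival.py
python analysis/04_resampling_robustness.py
python analysis/05_singlecell_states.py
```

prints (seed 1):

```
differential test: 60 genes at BH-adjusted p < 0.01
recovered planted genes: E 30/30, M 30/30
all       HR= 2.84 [2.18, 3.70]  logrank p=9.51e-16  cutoff q=0.50  (150 high / 150 low)
basal     HR= 3.74 [1.90, 7.37]  logrank p=5.60e-05  cutoff q=0.50  (30 high / 30 low)
permutation null (999 random same-size gene sets): ... permuted p=0.0010 (signed)
E cells: 13/24 co-express E and M genes; M cells: 22/24 exclusively M
cross-match: A1=0 of 24 pairs, p=8.39e-08; Mann-Whitney p (E panel)=4.51e-10, (M panel)=2.46e-09
```

i.e. the 60 planted genes are recovered exactly as the top-ranked E and M
sets; the planted 10-gene signature carries a hazard ratio near its
simulated truth in every subtype; no random gene set of 999 matched its
logrank *p* (permuted p = 1/1000); and the synthetic E and M cells are
perfectly separated in the E-M state space (no cross-matched pairs among
24, exact p ≈ 8×10⁻⁸), with E cells promiscuously co-expressing M genes
while M cells stay exclusive — the asymmetry the hybrid-state model
predicts. Outputs land under `results/`.

The same stages are scriptable through the `emstate` CLI
(`emstate simulate|derive-signature|score-survival|permute|bootstrap|singlecell|run`);
`emstate run --config cfg.json` executes the whole chain with one seed and
writes a consolidated JSON report.

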