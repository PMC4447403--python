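# Methods

This note documents the models, estimators and design choices behind
`emstate`, and what the synthetic-data experiments do and do not show.

## Differential expression and signature derivation

Arrays are normalized in two additive steps on the log2 scale: *central
tendency* (each sample shifted so its median is 0, removing per-array
intensity offsets) and, optionally, *relative normalization* (each gene
re-expressed against the mean of a reference group — by default the pooled
E- and M-clone samples, so 0 means "between the two clone types"). Both
steps preserve between-group differences for any gene subset; a shift
common to *all* genes of a sample is indistinguishable from an array
offset and is deliberately removed.

Per gene, E-clone vs M-clone groups are compared with a two-sample t-test
using a light empirical-Bayes variance moderation: the pooled per-gene
variance `s_g^2` (df `n_E + n_M − 2`) is shrunk towards the across-gene
mean variance `s_0^2` with `d_0` prior degrees of freedom (default 4),

    s̃_g² = (d₀ s₀² + df s_g²) / (d₀ + df),   t_g = Δ_g / √(s̃_g² (1/n_E + 1/n_M)),

with `Δ_g` the difference of group means ("effect size", a log2 fold
change; positive = higher in the E group) and `df + d₀` degrees of
freedom. This is a deliberate simplification of a full hierarchical
moderated-t fit: the downstream contract is rank-by-effect-size among
significant genes, for which the shrinkage detail is immaterial.
Multiple testing uses Benjamini–Hochberg with threshold 0.01 by default
(a raw-p option exists). Ties in |effect size| break by smaller p, then
lexicographic gene id, so signature files are byte-reproducible. Probes
are treated as genes; no probe collapsing is attempted beyond what the
caller supplies.

Signatures: the top-n significant genes per direction, ranks recorded;
the combined EM signature interleaves the top-k of each (60- and 24-gene
variants are conventional sizes).

## Survival arm

Patient subtype is a deterministic function of three linear-scale marker
probes with strict-greater positivity at cutoffs ESR1 500, MKI67 470,
HER2 4800: ESR+/HER2−/Ki67-low → luminal A; ESR+ with HER2+ or Ki67-high
→ luminal B; ESR−/HER2− → basal; ESR−/HER2+ → HER2. Every record with
complete probes receives exactly one of the four labels; a missing probe
yields "unclassified" with a warning.

A signature score is the unweighted mean log2 expression over the
signature genes present (missing genes warn; zero overlap is an error).
The best-cutoff scan evaluates the logrank p at the five quantiles
{0.25, 1/3, 0.5, 2/3, 0.75} of the score ("median, quartile or tertile"),
assigns "high" to scores strictly greater than the quantile value
(deterministic under ties), and keeps the smallest p, with ties broken
toward the median then the smaller quantile. The selected-cutoff p is
reported as-is; because it is the minimum of five correlated tests it is
optimistically biased, which is why the resampling arm exists — the
permutation null repeats the *same* scan per random gene set, so the
selection bias cancels in the comparison. An optional fixed-cutoff mode
skips the scan.

The logrank statistic accumulates observed minus expected group deaths
over the shared risk sets with the hypergeometric variance at each
distinct event time; p from χ²(1). The Cox model has a single binary
covariate (high vs low); the Breslow partial likelihood then depends only
on the per-event-time death counts and at-risk counts per group, and is
maximized by a damped Newton iteration on a scalar, with a Wald 95% CI
from the observed information. Complete separation trips a divergence
guard (coefficient capped at ±15, fit flagged) rather than an error.
Both estimators are implemented directly on numpy arrays so the
resampling engines can run tens of thousands of fits; unit tests verify
agreement with lifelines to ~1e-6 on random cohorts, and the Kaplan–Meier
step table is taken from lifelines directly. Ties use Breslow throughout;
OS and RFS are separate endpoint columns, with no competing-risks
modelling.

## Resampling

`permutation_null` draws `|signature|` genes uniformly without replacement
from the cohort's full gene universe (the observed signature's own genes
are *not* excluded — no exclusion rule is defensible a priori, and with a
universe ≥ 10× the signature size the effect is negligible) and re-runs
the identical score → best-cutoff → logrank/Cox pipeline per draw. The
default extremeness criterion is *signed*: a null set counts when its
logrank p ≤ the observed p **and** its HR lies on the same side of 1 as
the observed HR, matching a direction-specific poor-outcome claim. Note
the signed criterion conditions the count on the observed direction, so
under the null its p-value concentrates on roughly (0, ½] — like a
one-sided test whose side is chosen by the data. It is therefore the
*two-sided* criterion (p ≤ p_obs regardless of side) whose null
distribution is uniform, and that is what the calibration experiments
check. `permuted_p` uses the add-one estimator and can never be 0.

"Bootstrapping" over sub-signatures is subsampling without replacement
within each set (each set holds distinct genes), sets drawn
independently; the summary reports the fraction of sets with HR > 1 and
the fraction significant with HR > 1.

## Single-cell qPCR processing

Background: per assay, `C_bg` is the **minimum** Cq over that assay's NTC
wells — conservative and deterministic; assays whose NTCs never amplify
fall back to a global detection limit (default 24 cycles, configurable).
Expression is `2^(C_bg − C_q)` for `C_q < C_bg` and exactly 0 otherwise
(missing Cq = no amplification = 0). Per gene, values are divided by the
maximum over *single-cell* wells only; 100-cell pools are scaled by the
same factor and may exceed 1; an everywhere-undetected gene stays all
zeros (normalization is idempotent).

The E-M state space is the plane (mean normalized expression over the
10-gene E panel, mean over the 7-gene M panel); both panels are
configurable and default to CDH1, CD24, EPCAM, IL1B, KRT5, LCN2, TP63,
TRAIL, SLPI, S100A8 / ABCA6, DCN, IL1R1, PCOLCE, WNT5A, VIM, ZEB2.
A cell "co-expresses" when at least one gene of each panel is detected
(normalized > 0); "exclusive" and "silent" classes follow the same
detection rule.

### Cross-match test

Units from both groups are paired by a minimum-weight perfect matching of
the complete graph (default distance: Euclidean in the 2-D state space;
full-profile distances are an option). Equal-weight matchings are broken
deterministically by adding a tiny penalty increasing in lexicographic
pair order (≤ 1e-9 of the distance scale — negligible against any real
distance difference, decisive under exact ties). A1 = number of
cross-group pairs; small A1 means separation. Conditional on the
matching, labels are exchangeable under the null and

    P(A1 = a1) = 2^a1 · I! / [ ((n1−a1)/2)! · a1! · ((n2−a1)/2)! · C(N, n1) ],

N = n1 + n2, I = N/2, a1 sharing the parity of n1; the reported p is the
lower tail P(A1 ≤ a1). The closed form is verified against exhaustive
enumeration of all labelings for every split with N ≤ 12. For an odd
total a phantom unit farther from every real unit than any observed
distance is added; its matched partner is discarded and the null uses the
reduced even count. Note the null is very discrete at small samples: for
8 vs 8 the support of A1 is {0, 2, 4, 6, 8} and the only rejection region
at the 0.05 level is A1 = 0 (probability 70/12870 ≈ 0.0054), so the exact
test is strongly conservative there — a property, not a defect.

Mann–Whitney U is two-sided, exact when both n ≤ 20 and tie-free,
tie-corrected normal approximation otherwise; an all-tied comparison
returns p = 1 with a warning. PCA standardizes each gene to mean 0 /
variance 1 (zero-variance genes dropped with a warning), decomposes by
SVD, and fixes each component's sign so its largest-magnitude loading is
positive. Pearson correlation matrices can be block-averaged over an
annotation (within-block diagonals exclude self-correlations).

## Synthetic data

All generators are pure functions of (spec, seed).

**Clone matrix** — values i.i.d. Normal(8, 1) per (gene, sample) by
default, +3 log2 planted shift for 30 E-up genes in the 6 E samples and
30 M-up genes in the 4 M samples, plus per-sample array offsets
(sd 0.3) that the central-tendency step must remove. At the default
observation sd of 1 the planted effect is only ~4.7 standard errors of
the effect estimator; with ~940 competing null genes, exact top-30
recovery is then *not* statistically achievable (the expected minimum
planted |effect| falls below the expected maximum null |effect|), and
only about a third of planted genes clear BH-adjusted 0.01. Recovery
demonstrations therefore run at observation sd 0.5 (a 6-sd planted
separation), where recovery is certain; both conditions are reported by
the acceptance script.

**Cohort** — latent score s ~ N(0,1) per patient; signature genes express
`baseline + a·s + noise`; survival times exponential with hazard
`h₀·exp(β·s)` (defaults h₀ = 0.02/month, β = 0.7); censoring uniform on
[0, c] with c solved (Brent) so the censored fraction, averaged exactly
over the realized hazards, equals the target (default 20% — averaging
over the hazard vector matters; using the mean hazard alone biases the
realized fraction upward by ~8 points at β = 0.7). Marker probes are
drawn inside the correct side of each cutoff to populate all four
subtypes at fixed proportions (0.35/0.30/0.20/0.15). Exponential rather
than Weibull times keep closed-form sanity checks; a two-arm generator
with a known binary-covariate hazard ratio provides the direct
parameter-recovery fixture for the Cox estimator.

**Cq plate** — three archetypes in latent linear units (E-panel mean,
M-panel mean): E (64, 1), M (0.25, 64), hybrid (32, 32) — the hybrid is
0.5× the pure "on" level on both panels, and the E archetype carries
low-level M expression near the detection limit while M cells are nearly
silent on the E panel, mirroring the observed asymmetry (promiscuous E
cells, exclusive M cells). Per gene a fixed log2 offset (sd 0.5) and per
cell a log2 spread (sd 0.75) apply; detection is Bernoulli with logistic
probability in the latent log2 value (slope 1.5, midpoint at log2 = 1),
detected wells report `Cq = 24 − log2(latent) + Normal(0, 0.5)`, and
anything at or past the background is recorded as no amplification.
NTC wells are silent except for rare (5%) late signals past background;
100-cell pools sum 100 latent draws. Dropout monotonicity in the slope
holds for transcripts expressed above the detection midpoint (a shallower
curve *raises* detection below it), and is tested there.

### What the synthetic experiments do not show

The generators emulate the *structure* of the study's data, not its
biology: microarray probe-level noise, batch effects, real censoring
mechanisms, the probe-set selection of a live survival database, qPCR
efficiency differences and melt-curve artifacts are all absent. Passing
tests demonstrate that the estimators are correct and calibrated under
the stated models, and that the pipeline recovers planted truth — not
that any particular biological signature is prognostic. Published
survival numbers that depend on a proprietary patient database are out of
reach at desk scale; the survival arm is therefore validated by parameter
recovery and null calibration only. The published single-cell
co-expression counts are recomputable only from the journal's
supplementary raw-Cq table, which cannot be redistributed here; the
dedicated test documents the expected local file layout and runs the full
computation when a copy is supplied.

## Problem sizes and numerics

Calibration experiments run at: 1,000 replicates for the cross-match
type-I rate (8 vs 8); 200 cohorts of n = 300 for Cox recovery; 200
replicates × n_perm = 199 (cohorts of 150 patients × 120 genes) for
permutation-null uniformity; 20 seeds for state-space separation. The
permutation count is configurable up to arbitrary sizes; analyses default
to 999. Newton iterations converge to |Δβ| < 1e-10 with steps damped to
±2; quantiles use numpy's default linear interpolation; all RNG flows
from explicit seeds through `numpy.random.default_rng`, and end-to-end
runs derive per-stage substreams from one `SeedSequence`.

## Known limitations

* Single-covariate Cox only; no multivariate adjustment, PH diagnostics,
  or interval censoring.
* The best-cutoff logrank p is reported unadjusted for the scan (by
  design, with the permutation null as the honest comparison).
* The cross-match p is exact but conservative at small, even group sizes
  because of the discreteness of A1.
* Probe-to-gene mapping is the caller's responsibility.
* The moderated t is a simplification of a full hierarchical fit; with
  very few genes the across-gene mean variance is a poor prior.
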