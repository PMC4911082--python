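# Methods

## Data model

A sample's CE-MS output is a peak list of (mass [Da], CE migration time
[min], amplitude) triplets; amplitudes are arbitrary normalized intensity
units. Downstream of clustering, data live in a samples × peptides matrix
in which an explicit 0 encodes "not detected". Zero and absent are the
same state throughout: the differential-excretion statistic is defined
over zero-imputed means, detection frequency counts strictly positive
entries, and the classifier's log(1+a) transform maps 0 to the finite
coordinate 0. Peak lists are rejected at parse time if masses/times are
non-positive, amplitudes negative, or two peaks coincide within 25 ppm and
0.175 min (half the clustering tolerances) — such duplicates indicate a
broken upstream deconvolution, not two peptides.

## CE-time calibration

Between-run migration-time variation is modelled as a smooth monotone
distortion. Reference peptides with known canonical times are located in
a sample by mass alone (nearest peak within 50 ppm, greedy by relative
deviation, each peak used once); canonical time is then regressed on
observed time by LOESS — local linear, tricube weights, span 0.3 of the
matched references, two robustness iterations — and evaluated at every
peak's observed time. Local-linear fits reproduce affine distortions
exactly, which the tests exploit as an oracle. Calibration fails loudly
(sample flagged, never silently passed) if fewer than 10 references match
or any matched reference still deviates by ≥ 0.35 min afterwards. The
0.35 min figure serves both as this QC bound and as the clustering CE
tolerance; using one constant for both roles is a deliberate design
choice.

## Housekeeping normalization

Urine dilution and instrument response rescale a whole run. The scale is
estimated as the *median* of (observed/reference) amplitude ratios over
housekeeping peptides matched within 50 ppm and 0.35 min; the median keeps
the estimate robust if a few housekeeping peptides misbehave. At least
half of the housekeeping set (29 peptides by default) must be detected.
The estimated scale is stored in the sample metadata for QC.

## Peptide matching

Peaks pooled over samples are processed in ascending mass order. A peak
joins the nearest-mass existing cluster whose centroid lies within 50 ppm
(relative to the centroid mass) and 0.35 min; otherwise it seeds a new
cluster. Centroids are running means. A cluster accepts at most one peak
per sample: on a collision the peak nearer the centroid mass stays and the
loser seeds a new cluster. Centroid anchoring is chosen over transitive
single linkage because chains of pairwise-close peaks could otherwise
merge far beyond 50 ppm; on toys with tight groups and wide gaps the two
rules agree (tested against a brute-force connected-components oracle),
and the 40-ppm chain case where they diverge is frozen in a test as
documentation. Peptide IDs are ascending integers in final consensus-mass
order, so the partition — not the labels — is the order-invariant object.

## Biomarker discovery

The detection-frequency gate (≥ 70% in either group, boundary inclusive)
is applied *before* testing, and BH adjustment runs over the gated set
only — multiplicity is paid only for peptides actually examined. The
two-sided Wilcoxon rank-sum test includes zeros as tied observations,
consistent with the zero-imputation convention (a detected-only mode
exists for sensitivity analysis). The null distribution is exact
(enumeration) for combined n ≤ 25 without ties; with ties and combined
n ≤ 14 the exact conditional permutation distribution is enumerated,
because the tie-corrected normal approximation is unreliable for tiny,
heavily tied samples (for {0,0,0,5} vs {0,0,0,0} it gives 0.45 where the
exact p is 1.0); otherwise the tie-corrected normal approximation with
continuity correction is used — at cohort sizes this is the operative
branch.

Differential excretion multiplies the zero-imputed group mean by the
detection frequency on each side before taking the signed ratio. Since
the zero-imputed mean already scales with frequency, frequency enters
twice; the statistic is implemented exactly in this product form (a
detected-only-mean variant sits behind a flag, so the convention is
explicit rather than guessed). Sign convention: positive when the case
product exceeds the control product, the ratio always arranged so
|DE| ≥ 1; one zero product yields ±infinity, two yield an undefined
sentinel with a flag.

## Classifier

Log(1+amplitude) panel intensities feed a soft-margin SVM with kernel
K(u,v) = exp(−γ‖u−v‖²). The reported score is the signed Euclidean
distance to the maximal-margin hyperplane in feature space — the decision
value divided by ‖w‖ = √(Σᵢⱼ αᵢαⱼyᵢyⱼK(xᵢ,xⱼ)) — which makes scores
comparable across models; positive is the case side. Defaults C = 6.4
and γ = 0.001024 follow the magnitudes customary for this assay family;
model selection uses leave-one-out balanced accuracy over a powers-of-two
style grid, ties broken toward smaller C then smaller γ. The dual QP is
solved by libsvm (via scikit-learn) at tolerance 1e-8; trained models
serialize to JSON (support vectors, dual coefficients, bias, ‖w‖) and
reload with bit-identical scores. Tests cross-check decision signs
against an independent generic QP solve of the dual.

The operating threshold maximizes Youden's J over the discovery cohort's
LOO held-out scores, evaluated at midpoints between adjacent distinct
scores; ties break toward the higher-specificity threshold.
Classification is "score strictly above threshold". Applying Youden to
validation scores is possible only via an explicitly labelled exploratory
flag, because it leaks validation labels into the operating point.

## Evaluation

Sensitivity/specificity intervals are exact two-sided Clopper–Pearson
(beta-quantile inversion), degenerate bounds handled closed-form. AUC is
pairwise concordance with ties counted ½; its variance, CI and the test
against 0.5, as well as the comparison of two correlated AUCs, use the
DeLong placement-component estimator (implemented in-package; the
choice of DeLong over bootstrap is a convention). Spearman's ρ gets a
Fisher-z interval with SE = 1/√(n−3). Likelihood ratios use the standard
definitions with an infinity sentinel at specificity 1.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes: a
fixed peptide catalogue (masses uniform in 800–3600 Da with pairwise gaps
≥ 200 ppm so the 50-ppm rule can resolve them; CE times uniform in 19–45
min), peptide-specific lognormal amplitude baselines (log-mean 5.0,
between-peptide SD 1.0, within-sample SD 1.0), per-sample lognormal
dilution (log-SD 0.4), Bernoulli detection at base probability 0.8
(housekeeping 1.0, references ≥ 0.95), mass noise 10 ppm SD, CE noise
0.05 min SD, and optional affine or smooth quadratic per-sample CE drift.
Housekeeping peptides are stably excreted (SD 0.1). Marker effects shift
the case log-amplitude mean and detection probability. The catalogue is
drawn from an RNG stream separate from sample noise, so discovery and
validation cohorts of one study share a peptide universe while differing
in samples.

Planted-effect conditions used by the recovery tests: the discovery
condition plants 10 markers (half up, half down) at |log-fold-change| 1.5
and detection shift ±0.2 in cohorts of 30+30; Monte-Carlo across 20 seeds
puts per-seed recovery at 7–10 of 10 (mean 8.6) with 0–2 false selections
(mean 0.4), so the recovery assertions are aggregate bounds across ten
fixed seeds (mean recovery ≥ 80%, mean false selections ≤ 1). The
strong-effect classifier condition uses |log-fold-change| 2.5 with
detection shift ±0.25 and LOO grid search, which yields LOO sensitivity
and specificity of 100% and held-out AUC 1.0 in all ten seeds checked —
perfect cross-validated separation as a reproducible property of a
strongly separated cohort, not as a claim about any particular dataset.

What the generator does *not* emulate: correlated peptide co-regulation
(fragments of one protein rise together in real data), amplitude-dependent
dropout by default (a mode exists but is off, keeping detection
independent of intensity for testability), batch effects beyond
per-sample drift/dilution, heavy-tailed contamination, and peptides
sharing a mass at different CE times within one sample catalogue. Passing
recovery tests therefore demonstrate correctness of the inferential
machinery under the stated model, not field performance on clinical
cohorts.

## Problem sizes and determinism

Default synthetic scale (300 peptides, 29 housekeeping + 60 reference,
30+30 discovery and 40+40 validation samples) keeps a full pipeline run
within a few seconds, chosen so that the whole property suite — including
ten end-to-end runs and twenty null-cohort simulations — stays a desk-scale
job. All randomness flows from explicit integer seeds through
numpy Generators; reruns are byte-identical (asserted on output hashes).

## Known limitations

- Greedy centroid clustering is input-order dependent in degenerate
  near-tolerance configurations; only the partition on well-separated
  input is order-invariant.
- The LOESS calibration extrapolates at the extreme ends of the observed
  time range with boundary bias; residual QC catches gross failures.
- DE's double frequency weighting follows the stated product definition
  verbatim; users wanting a single weighting must opt into the
  detected-only-mean variant.
- Exact Wilcoxon enumeration caps at combined n = 25 (no ties) / 14
  (ties); beyond that, p-values are asymptotic.
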