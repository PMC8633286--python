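# Methods

`csfpanel` implements a two-stage cerebrospinal-fluid (CSF) tryptic-peptide
biomarker workflow for discriminating Parkinson's disease (PD) from atypical
parkinsonism (AP = multiple system atrophy, MSA, plus progressive
supranuclear palsy, PSP), together with a synthetic-cohort generator that
reproduces the statistical structure such a study assumes, so every stage is
testable without raw mass-spectrometry data.

## Discovery screen and candidate selection

The discovery stage takes a shotgun-proteomics peptide intensity matrix
(peptides × samples, arbitrary units, missing = below the detection limit;
numeric zeros are treated as missing, following the common search-engine
convention). Peptides pass a detection filter when observed in at least a
fraction `detection_fraction` (default 0.75) of samples in at least one
group (`one_group` scope) or in every compared group (`both_groups` scope);
the fraction is compared inclusively on exact counts. Both scopes are
exposed because a 75% filter can reasonably be applied per comparison pair
or across all cohort groups.

The PD-vs-MSA screen uses a two-sided Mann–Whitney U test per peptide on
non-missing values (exact null distribution for tie-free samples of at most
10 per group, tie- and continuity-corrected normal approximation otherwise).
No multiple-testing correction is applied at this stage: the screen is a
candidate generator, not a confirmatory analysis. The fold ratio is
direction-agnostic, `max(mean_a, mean_b) / min(mean_a, mean_b) ≥ 1`, which
is the convention the discovery tables use regardless of which group is
higher. Group means use non-missing values only.

SRM candidates must satisfy seven criteria simultaneously: (1) p < 0.05;
(2) fold ratio ≥ 1.5; (3) detection ≥ 75% in both PD and MSA; (4) length
≤ 20 residues; (5) unique protein assignment; (6) knowledge-base presence;
(7) no sequence liabilities. Liabilities are oxidation-prone residues (M, C),
the NG dipeptide (deamidation-prone asparagine) and an N-terminal Q or E
(pyroglutamate formation). The deamidation rule is deliberately narrow —
isolated N, NN runs and internal Q residues are accepted, since broader
rules would reject peptides that validated assays of this kind do carry.

## SRM relative quantification

Transition-level peak areas (Skyline-style export; the endogenous channel
may be labelled "light") are summed per (sample, peptide, label) —
summation is standard SRM practice where fragment responses are additive;
keys backed by fewer than `min_transitions` (default 2) transitions are
flagged low-evidence rather than dropped. The relative quantity is the
endogenous/heavy area ratio against the spiked-in isotope-labelled internal
standard; a zero heavy area yields a missing ratio with reason code
`HEAVY_UNDETECTED` (never a fabricated value), mirroring how peptides whose
standards cannot be detected are excluded from an assay.

Ratios are normalized by total CSF protein. The division uses protein in
g/L (metadata carries mg/L; `protein_scale = 1000`), which keeps normalized
ratios in the 0.03–3 range typical of validated CSF SRM panels; the scale is
configurable because the convention is assay-level, not universal.

Pooled QC samples (two per digestion batch) monitor preparation-day drift.
`monitor` mode (default) reports per-batch QC means and the across-batch CV
per peptide without touching the data; `correct` mode multiplies each
batch's values by (grand QC mean / batch QC mean), which exactly equalizes
QC means across batches and is idempotent. Correction is off by default
because including QC pools in a run does not by itself justify rescaling
cohort values.

## Assay validation

Seven criteria: calibration linearity (OLS of area on concentration over
the full replicated dilution series, default design 0, 0.625, 1.25, 2.5, 5,
10, 20, 40 fmol × 3 replicates; zero-concentration points are part of the
stated series and are included; R² = squared Pearson correlation; fits with
R² < 0.7 are excluded) and six CV suites — intra-assay (5 same-day
injections), inter-assay (10 days), sample preparation (5 aliquots),
autosampler stability (7 time points: 0–24 h every 4 h), and freeze/thaw of
the digested (5 cycles) and pre-digestion (3 cycles) sample. CV uses the
sample (n−1) standard deviation (population mode behind a flag). Thresholds
are boundary-inclusive: R² = 0.7 and CV = 20.0% pass; a strict mode exists
because "below 20%" and "at most 20%" genuinely differ at the boundary.

## Group statistics

* **Mann–Whitney U**, two-sided; `auto` mode switches from the exact null to
  the tie/continuity-corrected normal approximation above n = 10 per group.
* **Kruskal–Wallis** (tie-corrected H, χ² on k−1 df) with **Dunn's post
  hoc**: z statistics from pooled mid-ranks with tie-corrected variance,
  Bonferroni-multiplied by the number of pairs.
* **Rank analysis of covariance**, used for age-adjusted group comparisons:
  the Quade-style residuals-of-ranks procedure. Values and the covariate are
  converted to mid-ranks over the pooled sample, value ranks are regressed
  on covariate ranks by least squares, and the residuals enter a one-way
  ANOVA F on (k−1, N−k) df. Pairwise comparisons repeat the procedure per
  pair with Bonferroni correction over k(k−1)/2 pairs. Several rank-ANCOVA
  variants exist; this one is chosen for its transparency and is isolated
  behind a single operation. Its operating characteristics are verified by
  simulation: under an age-confounded null (groups differing in age, values
  depending on age only) the empirical type-I error at α = 0.05 is ≈ 0.04
  over 2,000 replicates, where a naive Kruskal–Wallis rejects ≈ 0.77.
  Constant values (zero residuals) return p = 1 flagged degenerate.
* **Spearman correlation** on mid-ranks of paired complete observations.
* **Pearson chi-squared** without continuity correction for count tables.
* **ROC AUC** by the rank (Mann–Whitney) formulation — ties contribute ½ —
  so AUC = U/(n₁n₂) holds exactly; orientation is fixed by the caller (AP
  treated as the positive class in the pipeline's PD-vs-AP tables, with an
  auto-orient option reporting max(AUC, 1−AUC)).

## Multivariate models

Four feature-family datasets: (1) peptides; (2) peptides + biochemical
markers (NfL, α-synuclein, Aβ42, t-tau, p-tau, RT-QuIC as 0/1) + age;
(3) peptides + markers + clinical scores (UPDRS, ICARS, MMSE, Hoehn–Yahr,
treated numeric) + age; (4) markers + clinical + age. Each run splits the
cohort 70/30 stratified by diagnosis (deterministic per seed), imputes
missing values with an expectation-maximization fit of a multivariate-normal
working model — fitted on the training fold only and applied unchanged to
the test fold — and fits a random forest (default 500 trees, √p feature
subsampling, unlimited depth) on the training fold. The held-out AUC is
computed from out-of-sample scores. Multiple imputation (bootstrap refits +
conditional-normal draws) averages held-out scores over completions; single
imputation uses conditional means. An optional permutation-importance
retention step keeps training-fold features above a configurable importance
quantile, reproducing the sparse "model included …" behaviour of published
panels without asserting any particular selection mechanism.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes:

* **Cohort sizes** default to the validation design: control/PD/MSA/PSP =
  39/46/17/8.
* **Total CSF protein** is normal per group with means (SD) 425.6 (211.2),
  533.2 (164.7), 510.7 (157.6), 723.8 (366.1) mg/L — PSP elevated.
* **Discovery intensities** are log-normal with σ_log = 0.8 (matching
  discovery tables whose SDs are of the order of their means); **SRM
  relative ratios** use σ_log = 0.4 (validation-stage ratio tables show
  CV ≈ 0.3–0.5). Planted group effects multiply (direction `up`) or divide
  (`down`) the affected group's level by the fold change, so the ratio of
  group means recovers the planted fold in expectation.
* **Age association** is induced by a Gaussian-copula latent factor shared
  with age; the latent Pearson correlation is set by the closed form
  r = 2·sin(π·ρ_S/6), exact for the bivariate-normal working model, so the
  empirical Spearman ρ hits the target well within the documented ±0.15.
* **Left-censoring**: values below the per-peptide
  `missing_censor_quantile` (default 0.1; a modest detection-limit fraction
  chosen once, as the discovery stage's censoring rate is not a published
  quantity) of the pooled distribution are replaced by an explicit missing
  marker, never zero. Observed means therefore exceed pre-censoring means.
* **SRM report**: 3 transitions per peptide with fixed relative responses,
  multiplicative log-normal technical noise of CV 10%, heavy-standard areas
  independent of the sample, endogenous areas proportional to the sample's
  relative level × total protein (g/L) so protein normalization divides the
  protein signal back out; two pooled QC samples per digestion batch at the
  pooled mean level. One RNG stream per logical block (metadata,
  intensities, censoring, SRM) so adding peptides does not perturb earlier
  draws; a fixed seed gives a byte-identical cohort (digest-tested).
* **Calibration series** areas are proportional to concentration with
  multiplicative noise of the stated CV; **replicate sets** are mean-one
  log-normal with σ = √ln(1+CV²), so the expected CV equals the target.

What the generator does **not** emulate: raw spectra, chromatographic peak
shapes, retention-time drift, ionization interference, peptide-correlated
(non-MCAR beyond left-censoring) missingness, or inter-peptide biological
correlation beyond the shared age factor. Passing tests therefore show that
the pipeline's algorithms behave correctly under the stated statistical
model, not that any particular peptide panel validates on real cohorts.

## Numerical and design choices

* Detection fractions, R² and CV thresholds are boundary-inclusive (strict
  modes behind flags).
* Fold ratios require strictly positive means; non-positive means are
  rejected rather than clamped.
* Untestable peptides (fewer than 2 non-missing values per group) are
  flagged, never given a fabricated p value.
* The test suite and the reproduction script use deliberately compact
  problem sizes — 500-peptide screens, 20-seed Monte-Carlo suites, 2,000
  null replicates, forests of 200 trees — chosen so each property is
  measured with comfortable statistical margin while the whole suite stays
  quick on a laptop.
* Monte-Carlo example checks assert the mean over a fixed 20-seed panel
  where a single seed's estimate is materially noisy (e.g. fold-recovery at
  the discovery stage, where the log-ratio of group means has sd ≈ 0.19 at
  n = 50/group under σ_log = 0.8).

## Known limitations

* The rank-ANCOVA variant used by any given published analysis may differ;
  agreement is demonstrated at the level of operating characteristics, not
  per-table p values (which depend on unpublished per-sample data).
* The EM/multivariate-normal imputer assumes joint normality; heavily
  skewed features should be transformed first.
* Batch correction equalizes QC means only; it cannot remove within-batch
  heteroscedastic drift.
* Model AUCs on synthetic cohorts characterize the algorithms, not any real
  cohort's separability.
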