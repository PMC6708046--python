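# Methods

## Corpus model

One record is one reported conductivity value for one tissue in one
study, with the covariates the synthesis analyses: measurement method
(DAC, EIT, E/MEG-based estimation, MREIT, DTI), condition (in vivo,
ex vivo, in vitro), applied-current frequency (Hz), sample temperature
(°C), participant age (years) and pathology. All values are held in SI
units; reported resistivities are converted by σ = 1/ρ after rescaling
to Ω·m, and conductivity units are rescaled to S/m. Impedance values
that would need an electrode-geometry model to convert are rejected
rather than guessed. The brain-to-skull conductivity ratio (BSCR) is
carried as a dimensionless pseudo-tissue and may not carry S/m.

Tissues form a two-level taxonomy — compartments scalp / skull / CSF /
brain / BSCR with sub-tissues (e.g. spongiform, inner and outer compact
bone and sutures under skull; GM, WM and its parallel/perpendicular
orientations, dura, blood, cerebellum, lesions and the epileptogenic
zone under brain). "Whole" labels are used when no sub-compartment
breakdown was reported.

Classification rules:

* **Temperature**: 35–38 °C → body; 18–25 °C → room; anything else
  (including the 25–35 °C gap and values above 38 °C) → unknown. Mapping
  the gap to the nearer band would invent a boundary no measurement
  protocol states, so unknown is the conservative choice.
* **Age**: all participants ≥ 18 years → adult; all < 18 → paediatric;
  mixed → both; otherwise unknown. When only a numeric mean age is
  available the class follows the mean. In regression, age enters as
  mean age in years when at least half of a tissue's records report it
  numerically; otherwise age-class indicators are used. The two never
  mix in one design.
* **Frequency filter**: records above 1 kHz (configurable) are removed —
  such frequencies are outside the bandwidth of the neural signals
  E/MEG records. The comparison is strict (exactly 1 kHz is retained)
  and records with unreported frequency are kept. A handful of published
  protocols sweep to a few hertz above 1 kHz, which is why the cutoff is
  configuration, not a constant.

The exchange format is a 14-column tab-separated file with a versioned
header; empty string means absent, and absent never silently becomes a
number. Per-study participant counts and provenance travel in a separate
study-metadata JSON because they are properties of studies, not records.

## Quality weighting

Systematic error is scored per study with a risk-of-bias checklist: each
relevant item gets a score in [0, 1], irrelevant items are ignored, and
the Quality Assessment Score (QAS) is the mean over relevant items. The
checklist is data, not code — a generic 11-item default is shipped and
any scored checklist can be loaded. Disagreement between two raters is
resolved by a mean-of-scores merge.

Random error is scored per record as a confidence value: 1 − relative
error, floored at 0, where the relative error is the reported SD
percentage as a decimal or — only when no SD is reported — the
methodological error. Records with relative error above 100% (SDs of
thousands of percent occur in unstable estimator outputs) are clamped to
confidence 0 and flagged: they keep their row in the corpus, preserve
the audit trail, and contribute exactly nothing to any weighted
statistic.

weight = QAS × confidence ∈ [0, 1]. Records reporting neither an SD nor
a method error need an explicit policy (`unit`, `zero`, a fixed value,
or reject); the pipeline default is `unit` — no penalty beyond the study
QAS — because the rule defines a *penalty* for reported error, not a
prior on unreported error. Per-study weights are reported as mean ±
sample SD (n − 1) over that study's record weights.

## Weighted synthesis

Per tissue: unweighted min / max / mean / sample SD, the weighted mean
Σwᵢxᵢ/Σwᵢ, and counts of values, contributing studies and participants
(participants counted once per study, then summed; unknown counts
contribute zero). The weighted SD uses the frequency-weight estimator

    √[ Σwᵢ(xᵢ − x̄_w)² / (Σw · (n_eff − 1)/n_eff) ],  n_eff = (Σw)²/Σw²,

chosen over the alternatives because it degrades *exactly* to the n − 1
sample SD under equal weights — a testable reduction — and it is
isolated behind one function should a different convention be preferred.
The summary table's "standard deviation" column is the unweighted sample
SD; the weighted SD is a separate quantity.

Boxplot statistics use inclusive-median quartiles (Tukey hinges), with
whiskers at the data extremes by default (matching how the per-tissue
spread is usually displayed) and an optional 1.5·IQR mode that flags
outliers for per-covariate displays.

## Inference

The meta-regression is weighted least squares minimising
Σwᵢ(yᵢ − xᵢᵀβ)², solved through the √w-scaled design. Categorical
covariates are reference-coded against their most frequent level (ties
broken lexicographically — deterministic and documented); covariates
with a single observed level are dropped with a warning; exactly
collinear columns are dropped until the design is full rank. Records
missing any required covariate are masked out and counted. R² is the
weighted coefficient of determination; the omnibus F has
(p − 1, n − p) degrees of freedom; coefficient standard errors are
s²(XᵀWX)⁻¹ with s² = Σwe²/df_resid. The implementation is plain numpy
linear algebra so it can be (and is) checked against a brute-force
normal-equations solve and against an independent WLS implementation.

A tissue is analysable when more than three records survive masking and
at least two covariates retain contrast; below that the stage reports
"insufficient data" explicitly.

Group comparisons — one-way ANOVA for three or more levels, pooled
two-tailed t tests for two — are **unweighted** on record values by
default: the quality weights are attached to the regression stage, and
the classical unweighted forms keep the familiar degrees of freedom.
Frequency-weighted variants (weighted means and sums of squares with
effective n) are available behind a flag. Pearson correlations handle
the continuous covariates, with two-tailed p via t = r√(n−2)/√(1−r²).
Raw p-values are reported; a Benjamini–Hochberg adjuster is provided but
off by default. Degenerate inputs resolve deterministically: identical
groups give F = 0 / t = 0 with p = 1, zero-variance separated groups
give an infinite statistic with p = 0, constant inputs to the
correlation are rejected.

## Reference values

The packaged table carries the recommended quality-weighted means with
their SDs and the observed min/max per tissue — scalp 0.41 ± 0.18 S/m,
whole skull 0.02 ± 0.02, spongiform 0.048 ± 0.07, inner compact
0.007 ± 0.004, outer compact 0.005 ± 0.003, CSF 1.71 ± 0.3, GM
0.47 ± 0.24, WM 0.22 ± 0.17 (0.12 parallel / 0.12 perpendicular), BSCR
50.4 ± 39, among others. `build_head_profile` assembles a layer → σ map
with explicit, mutually exclusive skull (whole vs three-layer) and brain
(whole vs GM/WM) modes; isotropic vs anisotropic WM is an explicit user
choice, never a silent default.

`sample_individual` draws from a log-normal moment-matched to each
entry's (mean, SD) — conductivities are strictly positive and
right-skewed — truncated by rejection to the observed [min, max].
Truncation shifts the mean slightly toward the centre of the observed
range; for entries whose bounds sit several SDs out (e.g. CSF) the shift
is far below the between-study spread. The distribution family sits
behind one function and is replaceable.

## Synthetic corpus generator

The generator emulates the *structure* of a real extraction corpus, not
any particular study's values: 56 studies by default; method mix
DAC 14 / EIT 10 / E-MEG 7 / MREIT 15 / DTI 9; condition mix
in vivo 42 / ex vivo 8 / in vitro 7; pathology mix 40 healthy,
10 epilepsy, 3 tumour, 2 stroke, 1 each for other neurological disorder
and Parkinson's; ~10 records per study across tissues sampled in
proportion to the per-tissue value counts of the reference table, whose
weighted means serve as base means.

Per record,

    σ = base_mean(tissue) · Π effects(levels) · exp(ε − s²/2),  ε ~ N(0, s²).

Effects are multiplicative because conductivity is positive and the
contrasts of interest (e.g. in vivo vs in vitro skull) are ratio-like;
the regression stage exposes an optional log transform of the response
(off by default) that makes such effects exactly linear. The noise is
mean-one log-normal so the per-tissue weighted mean converges to the
configured base mean as n grows, at any noise level.

Latent study quality is Beta(5, 2) (mean 0.71, mass over roughly
0.2–1.0 — together with record confidences this reproduces the observed
spread of published study weights, ~0.03–1.0); emitted checklists score
every relevant item at the latent QAS, so the scoring stage recovers it
exactly. Reported SD percentages are log-normal (median 10%, log-SD
0.8), occasionally exceeding 100% so the confidence clamp is exercised;
a fraction of records report a method error instead, or nothing at all.
Under the default `"quality"` noise model the record noise scale is
s = base_log_sd/√max(weight, 0.05) — the classical meta-analytic premise
that quality weights behave like inverse variances — which makes WLS the
correctly specified estimator and gives its 95% intervals nominal
coverage, as the parameter-recovery suite verifies (the mean-one
correction term −s²/2 varies with the record's weight, independent of
the covariates, so it inflates residual spread slightly without biasing
effect estimates). A `"homoscedastic"` model is available for studying
weight misspecification. Covariate missingness (frequency ~45%,
temperature ~55%, numeric age ~60% of studies missing) mirrors how
incomplete real extraction tables are and exercises the masking logic.

What passing on synthetic corpora does **not** show: the generator has
no between-study random effects beyond the quality-linked noise, no
correlation between covariates (method and condition are drawn
independently, whereas in reality DAC is mostly ex vivo/in vitro), no
frequency- or temperature-dependence of σ unless injected, and no
reporting biases. Results on real corpora depend on assumptions the
generator cannot certify.

## Problem sizes and determinism

Default synthetic corpora are 56 studies / ~560 records; the
parameter-recovery study uses 200 replicates of 30-study single-tissue
corpora, enough for the Monte-Carlo standard error of the coverage
estimate (~1.6 percentage points) to make the [90%, 99%] band
meaningful. All randomness flows from a single seeded generator in a
fixed iteration order, so a seed fixes the corpus byte-for-byte, and the
pipeline bundle (JSON with sorted keys, fixed float formatting, no
timestamps) is byte-identical across re-runs with identical inputs and
config.

## Known limitations

* The per-study QAS is applied uniformly to all of a study's records;
  differentiations within a study share one checklist.
* The weighted SD convention is one of several defensible choices (see
  above); comparisons across tools should check conventions.
* Frequency enters the regression linearly; the literature suggests
  conductivity–frequency relationships may be non-linear above the
  E/MEG-relevant band, which is part of why the >1 kHz filter exists.
* Group tests are marginal (one covariate at a time) and unweighted by
  default; they will disagree with the regression when covariates are
  confounded, which is expected behaviour, not a defect.
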