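# Methods

## The grading model

Blood contamination of CSF is graded on an ordinal five-level scale
{1, 10, 20, 30, 40} (negative, very low, low, high, very high). Three
modalities map onto the scale independently:

* **ELISA.** A hemoglobin concentration *c* (ng/mL) is placed in the
  left-open, right-closed interval (b_i, b_{i+1}] of the breakpoint ladder
  (0, 1,000, 15,000, 100,000]; *c* = 0 grades 1. The "> a to b" phrasing of
  the published interval table is read literally, so the upper endpoint
  belongs to its interval (1,000 ng/mL grades 10, 1,000.01 grades 20).
  Values below an assay's limit of detection are the caller's concern; the
  rules see only the reported concentration.
* **Test strip.** The five semi-quantitative readings map one-to-one onto
  the scale. The manufacturer's nominal erythrocyte equivalents
  (≈10/25/50/250 cells/µL for 1+..4+) are carried as metadata.
* **LC-MS.** Unique-peptide counts of the marker panel run through a
  cascade: pooled hemoglobin below 5 peptides → 1; hemoglobin alone → 10;
  plus CAH1 (≥ 1 peptide) → 20; plus CATA → 30, or 40 once CATA reaches
  5 peptides. The published rule text attaches its peptide thresholds to
  the last-named protein; we therefore apply the "< 5 / ≥ 5" qualifiers to
  pooled hemoglobin in the low rows and the "≤ 4 / ≥ 5" qualifiers to CATA
  alone in the high rows, and treat CAH1 presence as ≥ 1 unique peptide.
  Hemoglobin pooling deduplicates peptide sequences across the three
  subunit accessions (a per-subunit-maximum mode is available, since
  per-subunit counting is an equally defensible reading).

The combined sample grade is the **maximum** over available modalities.
The combining rule is ours (the source system grades modalities
independently): a conservative maximum guarantees that a contaminated call
by any single modality is never averaged away — exactly the situation of
lysed-cell samples, where only hemoglobin-driven modalities fire. Missing
modalities are reported absent, never imputed. The exclusion flag is
raised strictly above a configurable threshold, default 30: gradings up to
30 (≈ 0.01% blood) are treated as acceptable for quantitative work. The
source material is not fully consistent here — one passage ties
contamination value 30 to 0.1% blood and calls for its exclusion, while
the categorization itself and the closing recommendation tie 30 to 0.01%
and accept it. We keep the threshold a config field and default to
"exclude strictly above 30". The RBC count never enters the grade; it is
carried alongside for the lysed-cell logic.

## Concordance and discordance

Agreement statistics operate on a sample × method grade matrix. The
headline pairwise percentage is **truncated** toward zero (13/15 → 86%),
matching how such figures are conventionally printed; the exact fraction
is always returned with it. The lysed-cell flag fires when any modality
grades ≥ 30 while the RBC count is below 50 cells/µL (the recommended
clinical cut-off, configurable): hemoglobin without countable cells means
the cells ruptured between collection and counting. Samples lacking an RBC
count are never flagged. A second flag marks samples whose method grades
span ≥ 2 steps of the five-level ladder.

## Proteome impact model

Because a fixed peptide mass is injected per run, measured intensities are
compositional: at blood fraction *f*, protein *i*'s expected normalized
intensity is proportional to ((1−f)·a_csf,i + f·a_blood,i) / Σ_j mixture_j.
Whole blood carries roughly 500× the protein concentration of CSF, so the
denominator grows rapidly with *f* and CSF-specific signal is suppressed
while blood proteins intrude. `impact_summary` quantifies this per spiked
run against the subject's 0% reference run: the CSF-specific set is
defined as every protein quantified in the reference run; *suppressed*
counts CSF-specific proteins down by at least the fold threshold (default
2-fold, inclusive, so an exactly halved protein counts; a protein that
drops out of detection entirely also counts); *intrusions* counts proteins
quantified in the spiked run outside the CSF-specific set; the median log2
ratio is taken over proteins quantified in both runs. Missing intensities
mean "not quantified" — no imputation, since presence/absence is itself
the detection signal here.

Two normalizations are provided. Ratio-median normalization scales each
run so the median log-ratio of its shared proteins against a reference run
is zero — the standard correction for injection and instrument-response
variation, implemented as the documented equivalent of proprietary
label-free normalizers. Total-intensity normalization equalizes summed
signal instead. For the suppression analysis the total-intensity mode is
the right default: ratio-median normalization against a clean reference
re-centers the very shift the analysis measures (its scale factor is
computed from the mostly-CSF shared set), whereas under fixed loading the
total signal is already comparable across runs and the compositional
displacement remains visible.

## aSyn bias model

Observed aSyn follows two-component linear mixing,
c_obs = (1−f)·c_csf + f·c_blood. Defaults c_csf = 0.15 ng/mL and
c_blood = 8,000 ng/mL are a **calibration**, not measured constants: the
blood value is back-calculated so that 0.1% blood lands in the published
5–10 ng/mL range against a 0.1–0.2 ng/mL clean baseline (the ~100-fold
worst case). With this ratio (~5×10⁴) the model reproduces the observed
ordering: no visible shift at 0.001% blood, a clear shift at 0.01%,
50–100-fold at 0.1%. Reliability flags are expressed in both fraction and
grade units because clinical samples lack known fractions: ELISA-based
aSyn is flagged from fraction 1e-4 or combined grade 30, MS-based from
1e-3 or grade 40. `fit_mixture` inverts the model from observations at ≥ 2
known fractions by linear least squares.

## Synthetic spike-in generator

The generator emulates the spike-in study design: subjects × blood
fractions (default study set {0, 1e-5, 1e-4, 1e-3, 1e-2}), one run per
sample. Its defaults are the study conditions, chosen once from the
published measurements and physiology:

* CSF proteome: 700 proteins (the scale of a routine CSF identification
  run) totalling 4×10⁵ ng/mL, log-normal abundances with σ = 0.8 decades;
  a small hemoglobin baseline (20 ng/mL per HBA/HBB) reproduces the
  observation that hemoglobin peptides appear even in clean CSF at < 5
  peptides. Between-subject variation is a 30% CV log-normal jitter.
* Blood: hemoglobin 1.4×10⁸ ng/mL (physiological ~140 g/L; this yields
  ~1,400 ng/mL at 0.001% blood, inside the published 800–5,555 ng/mL band
  for that fraction — a consistency check, not a fit), CAH1 at 1% and CATA
  at 0.1% of hemoglobin, 150 plasma proteins shared with CSF at a
  log-normal ~200× concentration ratio, and a 10⁷ ng/mL blood-specific
  background; 300 blood proteins in all.
* Detection: each protein's theoretical peptides (fixed for the markers,
  e.g. 10 for HBA, 20 for CAH1, 30 for CATA; a stable 5–40 draw otherwise)
  are detected independently with p = logistic(2.0 · (log10 x + 3.28)),
  where x is the protein's normalized share of the fixed load. The
  midpoint and slope are calibrated jointly so that a clean run identifies
  ≈ 700 proteins and the marker staircase matches the published pattern —
  hemoglobin detected everywhere, CAH1 appearing at 0.001% blood, CATA
  mostly absent at 0.001% and consistently present from 0.01%.
* Readouts: ELISA hemoglobin and aSyn follow their linear mixing laws with
  multiplicative log-normal noise (CV default 15%, capped at the assay's
  reported worst case of 25%), averaged over duplicate readings. The RBC
  count is Poisson around f·(5×10⁶/µL)·(1−lysis_fraction) — blind to lysed
  cells. The strip responds to hemoglobin chemistry, so its
  erythrocyte-equivalent signal includes lysed cells; the published
  equivalence of 0.01% blood ≈ 50 cells/µL sets the default
  fraction-to-equivalents scale ("published" mode), although physiological RBC
  density would put 0.01% at ~500 cells/µL ("physiological" mode,
  selectable). The two readouts are deliberately allowed to disagree, as
  they do in the source data.
* Randomness is split into independent streams per readout (proteome,
  ELISA, detection, counting), so switching one noise source off leaves
  the others' draws unchanged; `noise=False` replaces all draws by their
  (rounded) expectations, making every mixing law exactly invertible —
  `estimate_fraction` and `fit_mixture` then recover the truth to 1e-9
  relative.

What the generator does **not** emulate: retention-time or spectral
structure, peptide-level quantification noise, FDR errors in
identification, inter-laboratory assay offsets, and real biological
covariation between proteins. Passing tests therefore demonstrate that
the grading logic, the concordance arithmetic and the compositional
suppression mechanism behave correctly under the stated statistical
assumptions — not that the specific thresholds are optimal for any given
cohort.

## Numerical choices and degenerate inputs

Interval lookup uses bisection over the breakpoint ladder and exactly
reproduces a linear scan of the printed rows (property-tested). Grades at
exactly a breakpoint fall into the lower interval (right-closed). The
ratio-median scale factor falls back to 1 (with a warning) when a run
shares fewer than 10 proteins with the reference. Zero or missing
modalities: grading requires at least one; agreement statistics silently
exclude incomplete samples and error only when a method pair has no
comparable sample. Test sizes: simulations in the suite use 4 subjects ×
5 fractions, with 100 replicates for frequency assertions — large enough
that the asserted orderings have comfortable margins under binomial
sampling error, small enough to keep the whole suite under a minute.

## Known limitations

The grade is ordinal, not an absolute blood-volume estimate, and cannot
distinguish intrathecal hemorrhage from traumatic puncture. The aSyn blood
concentration is a calibration constant; recalibrate it before using the
bias model quantitatively on a new assay. The "published" strip mapping and
the physiological RBC count intentionally encode inconsistent
fraction↔cells conversions, mirroring the source material; choose one mode
consciously when absolute cell counts matter.
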