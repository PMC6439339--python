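# Methods

This note documents the statistical models implemented in `pharmapop`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter
when comparing results across tools.

## Genotype representation and allele orientation

Genotypes are dosages in {0, 1, 2, missing} of an explicitly recorded
*counted allele* (`ref` or `alt`). All drug-response statistics are
defined on the *effect allele* — the allele that increases the annotated
response (efficacy, required dosage, or toxicity risk) — so analysis
starts by re-coding dosages against the annotation
(`orient_to_effect_allele`; d → 2 − d when the counted allele is the
non-effect allele).

Orientation is resolved only when the VCF allele pair equals the
annotation allele pair on the same strand. Any mismatch — including
apparent strand flips, and always for the intrinsically strand-ambiguous
A/T and C/G pairs — drops the variant with a logged reason. Strand
guessing is never attempted: a silently flipped effect allele inverts
every downstream direction-of-effect, which is a worse failure mode than
losing a variant. Coordinates are 1-based throughout, as in VCF.

## Frequency statistics

MAF is the folded counted-allele frequency, p = (minor allele count) /
(2 × called samples), with missing genotypes excluded from numerator and
denominator. F_ST is Wright's fixation index computed directly from
per-population allele frequencies:

    F_ST = sigma^2 / (p_bar (1 - p_bar))

with p_bar the *unweighted* mean across populations and sigma^2 the
*population* variance (divide by the number of populations). The
divide-by-N convention is a genuine choice — Wright's formula does not
fix it — so the sample-variance convention is available as `ddof=1`.
Population-size weighting is not applied. Variants with p_bar ∈ {0, 1}
have undefined F_ST and are excluded from set averages; this also means
variants monomorphic everywhere never dilute a mean F_ST. No
Weir–Cockerham or Hudson estimator is provided; the point of this
implementation is the variance-ratio form itself.

## LD pruning

`ld_prune` slides a 50-variant window by steps of 5 variants; within a
window, while any pair of retained variants has squared dosage
correlation r² above 0.5 (computed pairwise-complete over samples called
in both; a zero-variance variant has r² defined as 0), the lower-MAF
member of the currently worst pair is removed (MAF ties drop the later
position). The procedure is deterministic. Windows are counted in
*variants*, and the criterion is pairwise r² on dosages (composite LD,
no phase assumption) — the one self-consistent reading of the
conventional "r² 0.5 / window 50 / step 5" pruning recipe, whose
descriptions elsewhere mix variance-inflation and pairwise semantics and
nucleotide and variant-count windows.

## Distances and ordination

The inter-genome distance is 1 − identity-by-state:
d(a,b) = Σ_j |g_aj − g_bj| / (2 × variants called in both), ranging
from 0 (identical genotypes) to 1 (opposite homozygotes everywhere).
Pairs sharing no called variant are an error rather than an arbitrary
value. Projection uses classical (Torgerson) MDS: double-centre the
squared distance matrix, eigendecompose, scale the top eigenvectors by
the square root of their eigenvalues. Axes are ordered by descending
eigenvalue and signs fixed so the first non-zero loading of each axis is
positive (eigenvector sign is otherwise arbitrary, and deterministic
output matters for byte-identical reruns). A negative eigenvalue among
the requested axes — possible when distances are not
Euclidean-embeddable — warns and is clamped to zero. The implementation
is checked in the test suite against scikit-bio's principal-coordinates
analysis on random Euclidean configurations.

## Supervised ancestry estimation

Individual ancestry fractions q (K = 3 components: African, European,
Native American, in that fixed order) are estimated against a reference
panel of component allele frequencies f_kj by maximising the binomial
log-likelihood

    L(q) = sum_j [ g_j log p_j(q) + (2 - g_j) log(1 - p_j(q)) ],
    p_j(q) = sum_k q_k f_kj

with the multiplicative EM update

    q_k <- (q_k / 2M') sum_j [ g_j f_kj / p_j + (2 - g_j)(1 - f_kj) / (1 - p_j) ]

(M' = called variants), initialised uniform and run until the
log-likelihood gain drops below `tol` (default 1e-6, `max_iter` 2000).
The update preserves the simplex and never decreases L; monotonicity is
asserted per-iteration in the tests. Supervised estimation was chosen
over unsupervised model-based clustering because reference-labelled
panels anchor component identity directly — no label-switching, no
choice of K — and is the desk-scale equivalent of running an
unsupervised K = 3 fit jointly with reference populations. Panel
frequencies are clipped to [1e-6, 1 − 1e-6] so fixed sites cannot make
the likelihood infinite; the bound only matters for variants whose panel
frequency is exactly 0 or 1 and perturbs estimates far below the
statistical error at any realistic marker count.

## Ancestry association

For each variant, ancestry fraction y is regressed on effect-allele
dosage x by OLS; the slope β (ancestry fraction per effect-allele copy)
is tested with t = β / SE_β on n − 2 degrees of freedom, two-sided.
β > 0 means the effect allele is enriched with that ancestry. Because
fractions sum to one, the three per-component slopes of any variant sum
to zero — a useful internal check, asserted in tests. Raw P-values are
reported (no multiplicity correction by default, matching how such
screens are usually read; Benjamini–Hochberg can be applied downstream).
Degenerate fits are reported rather than crashed on: constant genotype →
undefined slope, flagged; constant fraction → β = 0, P = 1; perfect
non-constant fit (zero residuals) → P = 0 with a `degenerate_fit` flag
instead of a division by a zero standard error. Regression pools all
individuals across cohorts: the ancestry gradient *between* cohorts is
part of the signal of interest, not a confounder to be removed.

## Divergence statistics and the screen

For effect-allele frequencies f1, f2 in two populations:
R = log₂(f1/f2) captures relative differences at low frequencies,
Δ = f1 − f2 absolute differences at high frequencies, and the composite
E = √(R² + Δ²) — the Euclidean distance from the origin when the two are
plotted orthogonally — ranks overall between-population difference.
A frequency of exactly 0 or 1 would make R singular; for R only, such
frequencies are continuity-corrected by half an allele count,
f* = (2n f + 0.5)/(2n + 1), so population-private alleles still rank
(exclusion was the alternative; correction was chosen because private
effect alleles are precisely the interesting case). Δ always uses raw
frequencies, and interior frequencies are never touched. The screen
filters to evidence levels {1A, 1B, 2A, 2B} and keeps E strictly
greater than 0.5 (a record at exactly 0.5 is excluded), sorted by
descending E with rsID tie-break.

On the published Colombian table bundled in `pharmapop.datasets`, 11 of
the 13 curated pharmaSNPs exceed E = 0.5; the other two (rs1799853,
rs4244285) were clinically rather than divergence-selected, and the
screen correctly does not admit them.

## Assay concordance

Two call sets over the classes {homozygous non-effect, heterozygous,
homozygous effect} are cross-tabulated with the truth set (e.g., exome
calls) on rows — a flag swaps axes. Samples missing from either set are
excluded from n and counted separately; the data are silent on whether a
no-call is an error, and treating it as one would conflate assay
dropout with miscalls. Accuracy is trace/n; per-class metrics are
one-vs-rest sensitivity, specificity, and precision, with zero
denominators reported as undefined (NaN), never as 0. The formatted
report prints accuracy as a one-decimal percent (e.g., 97.7%); TSV
output keeps full precision.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- **Reference panel.** Balding–Nichols: ancestral mean p_j ~
  Uniform(0.05, 0.95), then f_kj ~ Beta(p_j(1−F)/F, (1−p_j)(1−F)/F) per
  component, so E[f_kj] = p_j and Var[f_kj] = F p_j(1−p_j). One knob, F
  (default 0.15, of the order of continental-scale human
  differentiation), controls the expected between-component F_ST. F = 1
  is rejected (degenerate).
- **Cohorts.** q_i ~ Dirichlet(α_c); g_ij ~ Binomial(2, Σ_k q_ik f_kj).
  The default cohorts mirror the two Colombian populations' published
  mean ancestries — Antioquia-like (7% African / 61% European / 32%
  Native American) and Chocó-like (76/11/13) — with concentration 50,
  which keeps individual ancestry realistically variable (sd ≈ 5
  percentage points per component) yet recoverable.
- **Re-called genotypes.** Each called genotype is independently
  replaced with probability ε (default 0.023, the discordance level of a
  validated allele-specific PCR assay) by one of the other two classes,
  uniformly.

All randomness flows from one integer seed; identical configurations
are bit-identical. By construction each genotype is Hardy–Weinberg given
its own p_ij, so pooling differentiated cohorts shows the Wahlund excess
of homozygotes (tested). What the generator does **not** emulate —
linkage disequilibrium (variants are unlinked; LD pruning is exercised
on purpose-built correlated fixtures instead), recombination maps,
phased haplotypes, selection, genotype-error asymmetry between classes,
and ascertainment bias of genotyping arrays. Passing tests therefore
demonstrate correctness of the estimators under the admixture model,
not robustness to LD or array ascertainment in real cohorts.

## Pipeline and problem sizes

`run_pipeline` sequences simulate (or read) → orient → prune →
frequencies/F_ST → distances/MDS → ancestry → divergence screen →
association → concordance, logging counts in/out per stage and writing
a run manifest with parameters and input hashes (paths recorded relative
to the run directory so reruns of identical configs are byte-identical).
The pipeline is a pure function of its configuration and inputs.

Default problem sizes (M = 2000 variants, two cohorts of 100) run the
whole pipeline in well under a minute on one CPU; the test suite uses
M = 250–800 with cohorts of 30–60 for sub-second stages, and the
recovery checks use M = 5000 with 50 individuals — sizes at which the
Monte-Carlo error of the checked quantities is comfortably below their
assertion tolerances.

## Known limitations

- Single-SNP resolution only: star-allele haplotypes, copy-number and
  structural pharmacogenomic variants are out of scope (multi-SNP
  dosing algorithms, e.g. for warfarin, cannot be expressed here).
- Supervised ancestry only: no unsupervised clustering, cross-validation
  over K, or local-ancestry inference.
- The F_ST estimator is the variance-ratio form; it is not unbiased for
  small, unbalanced samples the way Weir–Cockerham is.
- The annotation reader enforces a closed evidence-level and category
  vocabulary; knowledgebase exports with other schemas need mapping
  first.
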