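# Methods notes

This note records the statistical model behind each module, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that a maintainer would otherwise have
to reverse-engineer.

## Collocation scoring

Collocates are collected in a right-only window of `span` tokens (default
4), stopping at sentence boundaries. Right-window-only is deliberate:
semantic prosody of verbs is carried by what *follows* them, and the config
rejects other directions rather than silently symmetrizing.

Mutual information uses the corpus-interface convention
`MI = log2(co·N/(node·coll·span))`. The `span` term divides the expected
co-occurrence count by the window width; textbook PMI omits it, so our
scores are directly comparable to collocate lists exported from
English-Corpora.org-style interfaces but are `log2(span)` lower than PMI.
The MI filter is strict (`> mi_min`, default 3 bits): a collocate at
exactly 3.0 bits is excluded.

"Overly common words" are removed by a packaged stoplist of ≈200 English
function words (`prosodikit._stopwords`). No such list is canonical, so it
is an ordinary config value; pass any word set to replace it. Stoplist
tokens still occupy window slots — they are not counted, but they do not
extend the window either.

Ranking ties at the top-k cutoff are broken by higher MI, then
lexicographically, to make output deterministic.

The frequency weight in the collocate-valence average is the
node–collocate co-occurrence frequency by default; weighting by the
collocate's overall corpus frequency is available
(`weight="coll_freq"`) since the two readings of "frequency-weighted"
are both defensible. Collocates missing from the valence lexicon are
excluded from numerator and denominator and reported — never imputed at
the neutral midpoint, which would bias scores toward 5.

Prosody classification: neutral band default [4.5, 6.0] on the 1–9 scale
(wide enough to contain the canonical near-neutral exemplars rated 5.1 and
5.9), prosody margin default 0.5. Both are config keys and the classifier
reports the thresholds it used. Surface forms only; no lemmatization —
corpus-interface collocate queries are form-based, and per-tense scores can
be averaged by a thin wrapper if needed.

## Embedding bias

"Cosine distance" is implemented as cosine *similarity* (higher = more
associated); this is the only reading under which a positive standardized
difference means positive-leaning. Vectors are validated nonzero at load
because cosine is undefined for zero vectors; the word2vec *text* format is
the only input format (convert binary models with any standard tool, e.g.
gensim's `KeyedVectors.save_word2vec_format(..., binary=False)` elsewhere;
the reader here stays dependency-free and bit-exact testable).

The two similarity samples pool (form × attribute) pairs as independent
observations. That is the simplest reading of "difference of similarity to
positive vs. negative words", and it is what the g/CI formulas assume; note
that pooled observations sharing a form or an attribute are in truth
positively correlated, so the normal-approximation CI is mildly
anti-conservative for multi-form targets. A paired-by-attribute mode and a
noncentral-t CI (`ci_method="noncentral-t"`) are available. Out-of-vocabulary
forms and attributes are dropped and reported.

Default inflection set for verbs: {base, -s, -ed, -ing} with a small
irregulars table, user-overridable per word.

## Priming analysis

Preprocessing order: (1) drop practice trials, (2) drop inaccurate trials
(proportion reported), (3) log-transform, (4) winsorize at the grand mean
± 2.5 SD of the log latencies pooled over all remaining trials and
conditions. Winsorization replaces, never drops. Natural log is the
default; the base provably cannot change F, t, p, dz or ηp² (the transform
differs by a positive constant factor on every cell mean), only the units
of mean differences and CIs — this is covered by a test. Per-participant
winsorization exists behind `frozen_cutoffs` composition but the pooled
("grand latency mean") reading is the default, matching standard
reaction-time outlier practice.

Millisecond descriptive tables are computed from accurate, *non-winsorized*
raw latencies (mean and SD across participants of per-participant cell
means); a winsorized variant is emitted alongside, since either convention
is found in the literature.

The repeated-measures ANOVA implements the classical fully-within-subjects
decomposition of a complete subjects × conditions layout with one
observation per cell: every effect's sum of squares comes from
inclusion–exclusion over marginal means, and each effect is tested against
its own effect × subject interaction. No sphericity correction is applied:
two-level factors are exempt, and uncorrected tests are the documented
convention for this design family. Partial η² = SS_effect/(SS_effect +
SS_error). The decomposition is verified in tests against (a) a
design-matrix least-squares oracle built from orthonormal Kronecker
contrast bases and (b) statsmodels' AnovaRM, and satisfies exact SS
conservation.

Simple effects are paired t tests on participant cell means; the effect
size is dz (mean difference / SD of difference scores). A zero-variance
nonzero difference is reported as a degenerate infinite t rather than an
exception. Congruity contrasts in the report are oriented
incongruent − congruent, so facilitation is positive. p-values are exact
upper-tail probabilities; no multiple-testing correction is applied.

## Effect sizes and power

Conversions: η² = f²/(1+f²); ηp² = F·df₁/(F·df₁+df₂); r = √(F/(F+df₂)),
restricted to df₁ = 1 designs. The sensitivity solver works on the
noncentral F distribution for the group × measurement interaction of a
k-group, m-measurement repeated design: df₁ = (k−1)(m−1),
df₂ = (N−k)(m−1), λ = f²·N·m·ε/(1−ρ) with ε fixed at 1. That λ is the
G*Power "as in G*Power 3" effect-size convention; `convention="spss"`
drops the m/(1−ρ) factor (folding it into f) for SPSS-style effect sizes.
The minimal detectable f is found by bisection (Brent) to machine
tolerance; the solved f reproduces the target power to < 1e−6 across the
tested grid N ∈ {20…200}, ρ ∈ {0.1…0.9}. An inverse solver for the
smallest N at fixed f (`required_n`) is included.

## Synthetic data

The generators exist so that every pipeline stage can be exercised and
calibrated offline. They are pure functions of config + seed.

**Corpus.** Tokens are drawn from a unigram model with
Poisson-distributed sentence lengths (mean 12 by default, floored at 1).
Inside the `span` tokens after a planted node, each planted collocate's
probability is lifted to p·lift; outside any window it is *lowered* so that
the collocate's unconditional unigram rate is preserved — planting changes
where the collocate occurs, not how often. Consequently the
corpus-interface MI of a plant converges to log2(lift), corrected only by a
sentence-truncation factor (windows cut off at sentence ends shorten the
effective span); the ground truth emits both the corrected expectation and
the asymptotic log2(lift), with the truncation factor computed numerically
from the sentence-length distribution. MI-recovery tests use long sentences
(mean 100) and a rare node (p = 0.002) so that the corrections stay below
0.05 bits; at 10⁵ tokens the estimate then sits within ±0.15 bits of
log2(lift). Configs whose windows are too frequent to preserve the
collocate's rate are rejected at construction.

**Embeddings.** Attribute words form two Gaussian clusters (centroids one
unit apart along a dedicated axis, within-cluster SD 0.3, dimension 50,
displaced off the origin so cosines do not sit on the ±1 rails). A target
with planted standardized bias g is placed on the centroid axis at an
offset found by bisection against a fixed quadrature sample of attribute
draws, because the cosine geometry admits no usable closed form. The
quadrature sample is mirror-symmetric across the hyperplane between the
centroids, which makes the bias-vs-offset curve exactly antisymmetric and
eliminates even-order Monte-Carlo calibration error; the offset for a given
geometry is cached. Target-form jitter is small (SD 0.02) — inflected forms
of one lemma are nearly collinear in real embedding spaces — and this also
keeps each form's realized bias close to the planted value, which is what
makes the estimator's nominal CI approximately calibrated in the null
tests. Optional filler words provide an unbiased vocabulary for the
random-baseline operation.

**Trials.** Log-latency model:
`log RT = μ + b_i + δ(prime type)/2 · (±1) + ε`, with participant
intercepts b_i ~ N(0, τ²), residual ε ~ N(0, σ²), sign negative for
incongruent pairings so that δ = congruent − incongruent mean log latency.
Defaults: μ = log 640 ms, σ = 0.20, τ = 0.15, δ = −0.075 (strongly
valenced), −0.060 (prosodic), 0 (control), 4% error rate independent of
condition, 16 primes × 4 presentations (two per target valence) per
participant in the two-prime-type design and 24 × 4 in the three-type
design. These values are fixtures chosen to echo a ≈45 ms congruity spread
around ≈640 ms baselines with plausible between-participant variability;
they are not estimates of any real dataset. Balanced assignment is by
construction; targets are drawn from the configured pools at random.

What the generators deliberately do *not* emulate: item random effects
(off by default — the analysis is participant-only), condition-dependent
error rates, practice-phase dynamics, fatigue or break effects, response
deadlines, and any non-lognormal latency shape. Passing tests therefore
demonstrate correctness and calibration of the *analysis machinery* under
the stated model, not robustness of the scientific conclusions to real-data
pathologies (item variance, skew beyond lognormal, speed–accuracy
trade-offs).

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to keep Monte-Carlo error well
below the tolerances they assert: 2,000 null experiments at 40 participants
for type-I calibration (exact binomial acceptance band), 150 seeds per cell
of the δ × N recovery grid (MC standard error ≈ 0.001 log-units against a
±0.005 unbiasedness band), 500 seeds for null CI coverage, and 10⁵-token
corpora for the collocation oracles. Bit-level oracle comparisons
(brute-force counts, GLM projection, AnovaRM) need no replication and run
at small sizes.

## Known limitations

- The pooled (form × attribute) bias CI is anti-conservative when targets
  have several nearly-parallel forms; use the paired mode for inference
  that leans on the CI.
- The RM-ANOVA requires a complete balanced table; participants with empty
  cells are excluded (and listed) rather than imputed.
- The MI convention includes the span term; compare to PMI values only
  after adding log2(span).
- `required_n` and the sensitivity solver cover only the within-between
  interaction family (ε = 1); they are not a general power calculator.
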