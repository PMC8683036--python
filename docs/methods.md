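# Methods

## Score model and aggregation

The raw substrate is a long panel of ordinal scores: each of five raters
scores every vocalization on tone, interval, rhythm, repetition and
transposition (1 = lowest to 10 = highest) and counts its distinct syllable
shapes (unbounded). Missing rater cells are simply absent; per-cell means
use whatever raters scored that cell. Rater agreement is summarized three
ways:

- **mean pairwise Spearman rho** per feature (midrank ties,
  pairwise-complete vocalizations per rater pair; pairs with fewer than
  three shared calls are skipped with a warning);
- **Cronbach's alpha** with raters as items and vocalizations as cases
  (complete cases, sample variances; alpha is NaN when the rater-sum
  variance is zero, since the coefficient is then undefined);
- **subset-aggregation stability**: |mean(subset A) − mean(subset B)| over
  all disjoint rater subsets of two chosen sizes. Averaging over larger
  subsets cancels rater noise, so pair/triad splits vary less than
  single-rater splits — the justification for analyzing rater means.

After averaging, the five bounded features are divided by 10 and treated as
probabilities. The syllable count deliberately keeps its native scale: the
index is a count expectation, and its worked examples multiply a raw mean
count by a tenth-scale probability sum. Rater-dispersion columns stay on
the 10-point scale so the "average sigma below 2 of 10" yardstick applies
directly.

## The index

Repetition (same-frequency reappearance) and transposition
(different-frequency reappearance) of a given unit are modeled as mutually
exclusive, so P(reappearance) = P(repetition) + P(transposition) with a
zero joint term. The sum is **not clamped by default**: scores are
human judgments rather than true probabilities and the worked examples use
sums above one as-is (e.g. 0.54 + 0.56 = 1.10). A `clamp_reappearance`
switch re-bounds it at 1 for users who prefer proper probabilities. ARDI is
the exact product `syllables × P(reappearance)`, stored at full precision;
two-significant-figure rounding is purely a display convention
(`round_sigfigs`). Some published per-call examples print factor values that
are themselves rounded, so their displayed products cannot be reproduced
from the printed factors under any rounding convention; the package
reproduces the arithmetic-consistent ones.

The approximate song complexity index uses the uniform per-syllable
repetition estimate E(m) = l/n (`l` units, `n` syllables):
`SCI ≈ sqrt(n·l² − n·(l/n − 1)²)`, with the exact form
`sqrt(n·l² − Σ(mᵢ−1)²)` available when per-syllable counts are known; the
two coincide whenever the mᵢ are uniform. `log(SCI)` uses the natural
logarithm (the choice is conventional — the index is arbitrarily scaled —
and is documented rather than configurable-by-stealth). SCI is defined as 0
at n = 0 and a negative radicand is an error echoing its inputs rather than
a silent NaN.

Species-level analyses use the **maximum** per-species index: the question
is the most elaborate display a species can produce, not its average call.

## PCA and variable reduction

PCA is an eigendecomposition of the sample correlation matrix of the six
standardized features (standardization makes the /10 rescale irrelevant
here and gives each feature equal a-priori weight). Loadings are
variable–component correlations (eigenvector × sqrt(eigenvalue)); signs are
canonicalized so each component's heaviest variable loads positively, since
eigenvector sign is arbitrary.

Variable elimination follows Jolliffe's backward method B2 in single-PCA
(batch) mode by default: one decomposition, walk components from the
smallest eigenvalue upward, and while the eigenvalue is below the cutoff
(default 0.7) discard the not-yet-removed variable with the largest
|loading| on that component; stop at the first component at or above the
cutoff. An iterative mode (re-decompose after every elimination) is
provided for sensitivity analysis. The further consolidation to
{syllables, repetition, transposition} — preferring repetition over rhythm
as the more elemental temporal-redundancy proxy and transposition over
tone/interval as the spectral one — is a declared configuration default
(`final_feature_set`), not an algorithmic step: it rests on substantive
argument, and the elimination itself only establishes that one member of
each coupled pair is redundant.

Stopping rules implemented: Kaiser–Guttman (eigenvalues ≥ 1), the lowered
Kaiser cutoff (≥ 0.7), cumulative variance (smallest k reaching 90%),
Horn's parallel analysis (per-rank mean — or 95th percentile — of
correlation-matrix eigenvalues of iid standard-normal data at the observed
n × p; retention stops at the first observed eigenvalue not exceeding its
threshold), the broken-stick expectation b_k = (1/p)Σ_{i≥k}1/i, Velicer's
minimum-average-partial test (argmin over m of the mean squared off-diagonal
partial correlation after partialling out m components; the loop stops on a
degenerate partial covariance), Bartlett's sequential chi-square test of
trailing-eigenvalue homogeneity, and mechanical scree/log-eigenvalue elbows
(maximum second difference, smallest index on ties — a stated approximation
of a visual judgment). On a reconstructed six-eigenvalue spectrum whose
published counts are known, Kaiser–Guttman (2), the 0.7 cutoff (4) and
parallel analysis (2) reproduce the published counts; the broken-stick count
does not (the second variance fraction, 1.30/6 ≈ 0.217, falls below
b₂ ≈ 0.242), which we note rather than patch — the reconstruction rounds
the middle eigenvalues from printed variance percentages.

## Statistical tests

- **Rank-sum**: midrank ties; U for the first group plus the rank sum of
  the smaller group (W is software-convention-dependent, so the convention
  is recorded in the output). When n₁·n₂ ≤ 400, p-values come from the
  exact tie-aware permutation distribution, computed by a dynamic program
  over doubled midranks (equivalent to full enumeration, verified against
  it in tests); otherwise from the normal approximation with tie
  correction. Two-sided p is 2·min(tail) capped at 1; both one-sided tails
  are exposed.
- **Welch t**: unequal-variance statistic with Welch–Satterthwaite df;
  reduces to the pooled test when variances and sizes agree. Zero variance
  in both groups with equal means yields t = 0, p = 1; with unequal means
  the statistic is unbounded and an error is raised.
- **Index–label correlation**: the phrase "rank correlation with a binary
  label" admits several conventions, so Pearson-on-ranks (= Spearman with
  midranks, the default), plain Pearson and Spearman are all available and
  reported side by side by the analysis driver.
- **Battery**: Welch t of species-maximum index for each binary covariate
  (monogamous, wooded, arboreal, territorial) and for small groups (mean
  size 2–6) versus large (> 6) and solitary pooled; a solitary flag
  dominates the size. Covariates with a single class are skipped with a
  notice. P-values are deliberately unadjusted — the design is exploratory —
  and flagged as such, with a Holm column provided alongside.

Call names are classified as musical by case-insensitive substring matching
against an editable keyword list (song, duet, trio, chorus, great, music,
scale, coda, intro, interlude); the free-text context field maps into
higher-order categories through an editable keyword→category table, since
no canonical enumeration of context groupings exists.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes: 40
species × 12–28 scored call types (~800 vocalizations), five raters, and
four call archetypes (musical / temporal-repetitive / spectral-tonal /
noisy single-unit) mixed per species. Key choices:

- **Couplings are constructive**: rhythm's within-call deviation is a
  0.8-weighted copy of repetition's plus independent noise, and interval's
  a 0.5-weighted copy of tone's — exact, seedable, transparent. Ordinal
  censoring (round to integers, truncate to 1–10) attenuates realized
  correlations below these nominal weights; the realized rank correlation
  between rhythm and repetition on aggregated scores is ≈ 0.75 and between
  tone and interval ≈ 0.46, matching the correlation structure the
  reduction step targets (≈ 0.8 and ≈ 0.5).
- **Archetype means are compressed** (all within ≈ 0.25–0.57 on the
  probability scale) and syllable ranges overlap across archetypes, so that
  no single global factor swamps the spectrum: the resulting eigenvalue
  spectrum has exactly two components below the 0.7 cutoff — the two
  within-pair contrasts — which is what makes the elimination recovery test
  meaningful. These means are free parameters chosen once to reproduce the
  qualitative three-cluster loading geometry (diversity / temporal
  redundancy / spectral redundancy); no per-archetype score distributions
  were available to fit.
- **Rater noise** is additive on the 10-point scale (sd 1.5) plus a small
  per-rater bias (sd 0.5), giving a mean per-feature rater sigma ≈ 1.3,
  inside the "below 2 of 10" reliability envelope. Syllable counts get
  noise sd 1.4, floored at zero.
- **Covariate effects enter through the archetype mixture**: monogamy adds
  0.55 and wooded habitat 0.10 to the musical archetype's base weight of
  0.06 (renormalized). With ~20 calls per species, non-monogamous species
  frequently lack a musical call entirely while monogamous species almost
  always have several, producing a species-maximum index difference of
  about +1 — in the same direction and order of magnitude as the reported
  monogamy effect — whose direction the Welch battery recovers in ≥95% of
  seeds.
- **Unit counts** are per-syllable geometric repetition draws (mean 2)
  summed into l, so the exact SCI form has a testable per-syllable ground
  truth and E(m) = l/n holds in expectation.

What the generator does **not** emulate: phylogenetic covariance among
species, per-study recording/selection biases, rater learning over time,
and the long right tail of real repertoire sizes. Passing recovery tests
therefore shows the pipeline recovers known structure under its own
assumptions, not that real primate data satisfy those assumptions.

## Numerical conventions and problem sizes

Standardization uses sample (n−1) variance; a zero-variance feature is an
error naming the column. Eigenvalues are clipped at zero (rank-deficient
input is legal). The exact rank-sum DP uses int64 counts (the largest
possible total, C(40, 20) ≈ 1.4·10¹¹, fits comfortably). Parallel analysis
defaults to 1000 replicates and the per-rank mean criterion; the 95th
percentile is available. Recovery tests run 50 generator seeds at the
default ~800-call scale and the worked-example and oracle tests run in
milliseconds; the whole suite completes in well under a minute on one CPU.

## Known limitations

- Reappearance sums above 1 mean ARDI is not strictly an expectation unless
  clamped; the default follows the published formulation, and both modes
  are first-class.
- The elbow rules replace a visual judgment with second differences and can
  disagree with a human reading on flat spectra.
- The analysis applies no phylogenetic control; species are treated as
  independent observations, as in the preliminary published tests.
- Which member of a coupled feature pair the elimination discards is
  seed-dependent on synthetic data (the pair members are statistically
  exchangeable proxies); the declared final feature set is a configuration
  choice layered on top.
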