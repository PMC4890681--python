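# Methods

## The problem and the model

The package predicts sporulation capacity of gut bacteria from gene
content. The training signal is an ethanol-resistance phenotype: vegetative
cells are killed by 70% ethanol while endospores survive, so cultured,
sequenced isolates can be labelled spore-former / non-spore-former without
any genetic prior. Three linked models follow:

**Gene families.** Orthology is inferred with bidirectional best hits
(BBH). All-vs-all protein comparison uses an exact affine-gap local
alignment (BLOSUM62; gap open −11, extend −1, a gap of length L costing
open + (L−1)·extend), gated by a heuristic prefilter that skips pairs
sharing fewer than one 4-mer. Identity is matches/aligned-columns (`X` and
gap columns never match) and coverage is the query span of the local
alignment over the query length. A hit qualifies at identity ≥ 40% and
coverage ≥ 0.7 — standard orthology practice; both are configurable and the
prefilter can be disabled (`min_shared_kmers=0`) for exhaustive runs.
Mutual best hits (ties broken by score, then identity, then smaller subject
id, so runs are bit-reproducible) form a graph whose connected components
are families; when a component carries two genes from one genome the member
with the largest summed within-component score stays and the rest demote to
singletons. A family is *conserved* — and enters the presence/absence
matrix — when present in ≥ `conservation_fraction` of genomes (default
0.5). There is no published definition of "conserved" to match here; the
threshold is exposed, and `conservation_sensitivity` tabulates the retained
family count over a grid. Note one consequence of the 0.5 default: a
phenotype-balanced panel places signature-like families (present in
essentially one class only) right at the retention boundary, so roughly
half of them can drop out of the matrix; mining still succeeds on the
remainder, but panels with unbalanced class sizes may want a lower
fraction.

**Signature.** A linear maximum-margin classifier (hinge loss, L2 penalty,
balanced class weights, resistant = positive class) is trained on the
binary genome × family matrix, then pruned: at every round, features whose
coefficient is ≤ 0 (presence predicts the *sensitive* class — meaningless
for a detection-based score) are removed first; otherwise the 10% of
features with smallest |coefficient| are dropped, until at most
`target_size` (default 66) positively-oriented features remain. Stratified
k-fold cross-validation accuracy (k = 5) is recorded at every round; an
alternative `one_se` stop rule picks the smallest round within one standard
error of the best accuracy instead of a fixed size. Final weights are the
remaining coefficients normalized to sum to one.

The regularization default is deliberately strong (C = 0.001). With a
separable panel and dozens of mutually redundant predictive families, a
weakly regularized SVM satisfies its margin on a sparse, unstable subset:
coefficients of equally informative families flip sign between refits and
the orientation filter then erodes the signature. In the heavy-L2 limit the
fit approaches weighting each family by its class association, which is the
intent of contrast-set weighting: every family predictive of the resistant
class earns a positive weight proportional to its signal. C is exposed for
users who want sparser, margin-driven signatures.

**Score and decision rules.** A genome's score is s = Σ wᵢ·dᵢ with weights
normalized, so s ∈ [0, 1] always. Detection dᵢ is binary by default — some
gene aligns to family i's representative at the shared identity/coverage
thresholds, evaluated with the representative as the query so that a
genome fragment cannot claim full detection — with a fractional mode
(dᵢ = identity × coverage, capped at 1) behind a flag, since "percentage
detection" admits either reading. s > 0.5 (strictly; s = 0.5 is a
non-spore-former) calls the species a spore-former. A genus is
spore-forming only when every scored species in it exceeds 0.5, giving the
three-way genus verdict {spore-forming, non-spore-forming, unclassified}.

## Community statistics

Counts standardize to per-sample relative abundance; a log2(count+1)
column is kept for comparison plots but every ratio/fraction statistic runs
on the linear relative scale (fractions of a log-transformed total are not
meaningful). Detection filters are literal: a sequence is present at mean
coverage ≥ 2× across its length; a metagenomic species is detected at
≥ 100 unique reads. Spore-former fractions per sample count only genera
with a verdict; unclassified genera leave both numerator and denominator.

Spearman's ρ, Welch's t (Satterthwaite degrees of freedom) and the paired t
are implemented from their textbook formulas (scipy supplies only the
t-distribution tail); scipy.stats is used in the test suite as an
independent oracle at 1e-10, never as the implementation. A constant
vector makes ρ undefined and raises; identical paired vectors return
(t = 0, p = 1) rather than raising, since the zero-variance difference is
then exactly the null.

Temporal turnover between paired samples counts a species as changed when
max(p₂/p₁, p₁/p₂) ≥ 2; a species detected at exactly one time point counts
as changed (its fold change exceeds any finite bound; configurable), and
species absent at both are excluded.

The colony-sampling question — how many colonies must be picked so that
every species in a community is seen at least once — is the
unequal-probability coupon collector. The expectation
E[T] = ∫₀^∞ (1 − Πᵢ(1 − e^(−pᵢt))) dt is evaluated by adaptive quadrature
(upper limit 50/min(p), leaving tail mass < S·e⁻⁵⁰; tolerances 1e-10);
by Poissonization this integral equals the discrete pick-count expectation
exactly, and the uniform case reproduces S·H_S to 1e-6 in the tests. The
Monte-Carlo validator samples T = maxᵢ Exp(pᵢ) — the continuous-time
embedding with the identical mean — and a direct discrete-process
simulation cross-checks the embedding at small S. A second mode returns
the smallest N with minᵢ (1 − (1 − pᵢ)^N) ≥ γ. A zero-probability species
makes the all-species expectation infinite and is reported as such.

## 16S

Identity is a global alignment with free end gaps (match 2, mismatch −3,
gap −5/−2); terminal gap columns are excluded from the denominator so
full-length and partial sequences compare fairly, and IUPAC ambiguity codes
align but never count as matches. OTUs come from average-linkage
agglomeration (single/complete by flag) cut at 0.987 (species) or 0.97
(general). The merge order is fully specified — highest mean identity
first, ties by the lexicographically smallest cluster label — which makes
clustering input-order invariant; the tests confirm agreement with
scipy's average-linkage on tie-free data. Cluster representatives are the
longest member, ties lexicographic. Novelty of a query against a reference
set is ranked by best identity: ≥ 98.7% known species, then candidate novel
species, genus (< 94.5%) and family (< 86.5%); the genus/family cutoffs are
conventional rank thresholds, not measured here, and are configurable.

## Assays

Germination response is the per-replicate fold change of c.f.u. with a
germinant over c.f.u. without. When the germinant-free plate shows nothing
countable, the limit of detection (200 c.f.u./ml) substitutes for the zero
denominator — by default *only* then (`zero_only`), with an `always_floor`
mode that clamps every denominator. Replicates with zero counts under both
conditions are undefined and flagged rather than invented. Summaries report
mean and range (geometric mean available); the optional significance test
is a one-sample t of log10(fold change) against 0, because fold changes are
multiplicative. Oxygen tolerance is 100 × exposed/control against
anaerobic controls, assembled into a survival curve over exposure times.

## Synthetic data: what it emulates, and what it does not

The generator plants a known truth behind every input. Gene content: every
genome carries all core families; accessory families appear with
probability q = 0.3; each of 66 signature families appears with probability
0.95 in resistant and 0.05 in sensitive genomes (defaults; 30 + 30 genomes).
Each family has one ancestral protein, uniform over the 20-letter alphabet,
length 80–150; carriers receive copies mutated per site at 0.05. Uniform
random ancestors maximize between-family separability, which is what makes
the BBH oracle tests sharp; real proteomes share domains and low-complexity
stretches that would blur it. One gene per family per genome — BBH
behaviour under paralogy is exercised through the clustering stage's
demotion rule, not the generator. Communities: log-normal species
abundances (meanlog 0, sdlog 1.5, 20 genera × 1–5 species, 6 samples)
renormalized per sample, with whole genera flagged spore-forming with
probability 0.5 so the genus rule has a planted answer. Time points:
per-species multiplicative log-normal drift, sdlog 1.0 for spore-formers
vs 0.3 for the rest, reflecting the higher observed temporal variability of
the spore-forming fraction. Assay counts are Poisson around
baseline × fold-change with sub-LOD counts censored to 0. 16S sets are
drawn from centroids with pairwise divergence 0.5% within and 5% between —
the divergence parameters are expected *pairwise* divergences (each copy is
mutated at half the rate), chosen so the planted centroid structure sits
clearly on either side of the 98.7% species cutoff. All randomness flows
through one seeded generator; a fixed seed reproduces outputs byte for
byte, and abundance zeros are absent rows, as in sparse classifier output.

Passing tests on these data show the *algorithms* are correct and the
planted signal is recovered under the stated noise model. They do not show
that real genome panels are separable, that real communities are
log-normal, or that the 66-gene scale transfers to any particular taxon
set — no claim about real data is made or tested here.

## Problem sizes and numerical choices

The orthology oracle comparisons run on 3–6-genome, 10–40-family panels
with proteins of 40–60 residues, where exhaustive no-prefilter enumeration
(score-checked against an independent dynamic-programming oracle) is
cheap; signature mining and scoring run at the full default conditions
(66 planted families, 30 + 30 training genomes, 10 + 10 held out), where the
input is the presence matrix itself and alignment is not the question. The
end-to-end pipeline profile (8 + 8 training genomes, 15 signature families,
proteins 60–90 aa) is sized so the real BBH stage runs in seconds while
keeping a learnable signature; its manifest records a SHA-256 per artifact
and two runs with one config + seed are byte-identical. Scores are clamped
to [0, 1] only against float round-off at the boundaries; all tie-breaks
(best hits, family naming, weight ordering, OTU merges, representatives)
are lexicographic after the scientific criterion, so no output depends on
iteration order.

## Known limitations

- BBH with component clustering merges families bridged by a chance mutual
  best hit; no inflation/modularity step is applied (determinism and
  testability were preferred), so very low-divergence paralog pairs could
  coalesce.
- The signature weights are association weights, not effect sizes; with
  strong regularization, redundant families share weight almost equally.
- The coupon-collector estimate assumes picks are independent draws from
  the relative-abundance vector — no plate saturation, colony-size bias or
  culturability differences.
- Genus verdicts inherit whatever taxonomy the abundance table carries;
  misassigned lineages propagate directly into the fractions.
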