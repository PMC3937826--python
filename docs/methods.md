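# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design choices that were genuinely open.

## 1. Increase rates and the two-group comparison

A species network is a triple of identifier sets (enzymes as EC numbers,
reactions as R numbers, primary metabolites as C numbers); metabolites are
derived from the reaction→compound links, never stored independently.  Given
global oxic/anoxic classification lists, the *increase rate* on a basis
(enzyme or metabolite) is

    rate = n_total / n_anoxic,

with `n_total` the classified items of the network and `n_anoxic` its anoxic
subset.  Items absent from both global lists are excluded from both counts
by default; `unclassified=count_in_total` instead counts every network item
in the numerator — both behaviours are provided because "total" is ambiguous
when classification lists lag the reaction universe.  A species with no
anoxic items has an undefined rate: it is flagged and dropped from group
statistics rather than given a sentinel value.  Since the anoxic items are a
subset of the total, the rate is ≥ 1 whenever defined.

Aerobes (including facultative aerobes, configurable) and anaerobes are
compared with (i) a two-tailed WMW test (exact null when the pooled sample
is ≤ 20 and tie-free, otherwise the normal approximation with midrank tie
correction and continuity correction) and (ii) OLS of rate on the group
indicator.  For a binary regressor the OLS slope equals the difference of
group means and its t statistic has n_a + n_b − 2 df; the test suite asserts
this equivalence at 1e-12 against an independent closed-form computation.

## 2. Brunch contrasts for a binary predictor

The phylogenetically controlled version replaces the linear model with
CAIC-family *brunch* contrasts:

1. post-order traversal of a rooted binary tree; tips carry the predictor
   (aerobic = 1) and the response (increase rate);
2. at an internal node whose two daughter values are both available, the
   nodal value is the weighted average with weights 1/v (v = adjusted branch
   length), and the daughter branch-length adjustment is
   v' = v + v₁v₂/(v₁+v₂) (Felsenstein's pruning rule);
3. when the two daughter *predictor* values differ (tolerance 1e-10 —
   nodal predictors are continuous averages, so exact comparison is
   fragile), the standardized response contrast
   (value_high − value_low)/√(v₁'+v₂') is emitted, signed so the daughter
   with the larger predictor value is the minuend, and the entire clade is
   retired — each tip therefore informs at most one contrast;
4. a node with a single available daughter adopts its values, adding branch
   lengths; the k contrasts are tested against zero with a one-sample
   t test on k−1 df (equivalent to a through-origin regression on unit
   predictor contrasts).  k < 2 yields a flagged, untested result; a
   constant predictor is a validation error.

Polytomies are resolved beforehand into deterministic ladders (children
sorted by smallest descendant label, inserted branches of length ε = 1e-6 by
default, floor 1e-8); zero-length branches are replaced by ε and counted.
Under the Brownian-motion null the standardized contrasts are iid normal
regardless of where the predictor changes state, so the t test is calibrated;
scaling all branch lengths by c divides every contrast by √c and leaves t
unchanged (both properties are tested).

## 3. Effect sizes and the evaluation value

Per species and descriptor, the descriptor values of the network's oxic and
anoxic metabolites are compared with a one-tailed WMW test (alternative:
oxic stochastically greater).  The p-value convention is
P(rank statistic ≥ observed) — the convention of the standard exact
implementations, matched to brute-force enumeration at 1e-12 in the tests.
The effect size is ES = z/√N with z = Φ⁻¹(1 − p); deriving z from the
p-value (rather than from the rank statistic directly) keeps the exact and
asymptotic regimes on one scale.  p is clamped to [1e-300, 1 − 1e-16] before
the transform so z stays finite; a fully tied input yields p = 0.5, ES = 0.
Because of the clamp and the discreteness of the exact null, ES antisymmetry
under swapping the two sides is exact only in the asymptotic regime (to
continuity-correction accuracy); the extreme exact cases saturate at the
clamp.

Quantiles use linear interpolation at h = (n−1)q + 1 on the sorted sample
(type 7, the default of the common statistical environments); a
nearest-rank convention is available for sensitivity analysis.  The
evaluation value of the integral (all-species union) network is

    EV = |ES_int − M_ES| / |Q_c − M_ES|,

with Q_c the 97.5% quantile of per-species effect sizes when ES_int exceeds
their median M_ES and the 2.5% quantile otherwise.  EV = 0 when ES_int
equals the median; a zero-width tail with ES_int off the median gives
EV = ∞ and the over/under verdict.  The verdict is `over_or_under_estimated`
strictly when EV > 1.  Under the exchangeable null (ES_int drawn from the
same distribution as a 100-point sample), P(EV > 1) is ≈ 0.067 with the
type-7 convention — within the nominal 5% ± 2% band but not exactly 5%,
because the type-7 sample quantiles of n = 100 points under-cover slightly;
the acceptance test measures this rate with a vectorized indicator
(cross-checked against `evaluation_value`) at 400k replicates so the
Monte-Carlo error is small relative to the band.

Reported alongside each EV: the median of per-species P = −log₁₀(two-tailed
p) and the fraction of species with two-tailed p < 0.01.  The two-tailed p
feeds the P columns; the one-tailed p feeds only z.  No multiple-testing
correction is applied across descriptors.

## 4. Input handling

Identifier syntax is validated (EC dotted quads with `-` wildcards matched
only verbatim, R#####/C##### codes); comparisons are case-sensitive after
trimming.  The reaction→compound dialect is
`R#####: <map>: C##### [+ …] (=>|<=|<=>) C##### [+ …]`; a reaction on
several map lines is merged by set union (direction kept, `reversible` on
disagreement, unused downstream).  Metabolite classification derives from
reaction classification: each side's metabolites are the union over its
reactions, minus the metabolites of *augmented* reactions (oxic
intermediates excluded from the chemical comparison).  A compound reachable
from both sides is resolved by policy — `anoxic_priority` by default
("available without oxygen" is the conservative baseline; the source
material does not state a rule), `oxic_priority` and `drop_overlap` as
alternatives; the resulting sets are always disjoint.

Species selection has two modes.  `phylo` intersects the metadata with the
tree's tips (for the contrast analysis).  `nonredundant_groups` keeps
free-living mesophiles, one species per genus — earliest genome-completion
year, ties broken by the lexicographically smallest organism id; the genus
is an explicit column or the first token of the species name — and splits
them into strictly aerobic bacteria (no facultative aerobes), unicellular
eukaryotes and multicellular eukaryotes; archaea are excluded (too few
survive the filters to form a group).

Functionally-unknown proteins are those whose annotation contains at least
one of eight keywords ("hypothetical", "predicted", "putative", "unknown",
"-related", "-family", "-like", "probable") as a case-insensitive substring;
hyphens are significant, so "flagellin-like" matches and "unlikely" does
not.  Substring (not token) matching was chosen because the keyword rule is
stated without a tokenization; the keyword list and case sensitivity are
configurable.  Group comparison uses Kruskal–Wallis with midrank tie
correction and a chi-square reference (complete ties → H = 0, p = 1).

## 5. The synthetic-data model

The generator emulates the complete input bundle:

* **Phylogeny.**  Yule subtrees per clade (bacteria, archaea, unicellular
  and multicellular eukaryotes; default sizes 134/18/33/34, the study-scale
  species counts) joined on a backbone with 1.0-length stems.  The
  pure-birth simulation is conditioned on the tip count and every tip edge
  is extended by one exponential holding time so the youngest cherry has
  positive terminal branches.
* **Oxygen requirement.**  A two-state Markov chain along the prokaryote
  branches (default gain 0.45 / loss 0.15 per unit length: stationary
  anaerobe fraction 0.25, matching roughly a quarter of prokaryotes being
  anaerobic), producing the phylogenetically clustered anaerobe patches the
  contrast analysis needs; eukaryotes are aerobic.  A configurable fraction
  of aerobic prokaryotes is marked facultative; small fractions of
  symbionts and non-mesophiles exercise the selection filters.
* **Reaction universe.**  Default 3200 reactions / 2900 compounds, mirroring
  the real classified universe (~2850 classified reactions ≈ 1627 oxic +
  1225 anoxic enzyme listings; ~2900 reachable compounds of which ~60% have
  resolvable structures and hence descriptor values).  Each reaction carries
  one EC number and 2–4 compounds; 57% of classified reactions are oxic, 10%
  of all reactions are unlisted, 5% of generic oxic reactions are
  "augmented".  A `specific_fraction` (default 20%) of oxic reactions draws
  from a reserved "higher-organism-specific" compound pool.
* **Descriptors.**  Values are N(0, 1) by default (lognormal optional),
  plus sign_d · δ_common for compounds reachable *only* through oxic
  reactions, plus sign_d · δ_specific on the specific pool.  Attaching the
  shift to oxic-only-reachable compounds keeps the generated shift aligned
  with the anoxic-priority classification for the integral and the species
  networks alike — compounds a classified anoxic reaction also touches
  belong to the oxygen-free baseline chemistry.  Per-descriptor signs
  default to (+,−,+,−,+,−) for (AlogP98, SOL, FNSA, FPSA, pLC50, RotBonds),
  the directions reported for these descriptors.
* **Species networks.**  Independent per-reaction retention: anoxic 0.7
  for everyone; generic oxic 0.6 for aerobes/facultatives vs 0.25 for
  anaerobes (the expansion effect; set both equal for a null study);
  specific oxic 0.7 for multicellular species vs 0.05 otherwise (the bias
  mechanism); unlisted 0.5.  Every probability is multiplied by a
  per-species factor drawn from U(0.4, 1): genome-scale networks vary
  severalfold in size, and this heterogeneity is what gives per-species
  effect sizes a realistic spread — without it the per-species ES
  distribution is far tighter than any real study's.
* **Annotations.**  Per genome, 200 proteins whose annotations are drawn
  from keyword-bearing or clean templates with a per-oxygen-class unknown
  fraction (default 0.35 for all classes — the no-difference scenario).

What the generator does **not** emulate: the true tree-of-life topology,
KEGG's reaction-multiplicity statistics and EC↔R many-to-many structure
(one EC per reaction here), correlated descriptors (84 real descriptors are
far from independent), or annotation-driven network error.  Passing tests
therefore establish that the statistics behave as designed under the stated
mechanism, not that the real data satisfy that mechanism.

## 6. Calibration results the suite reproduces

* With no true expansion effect, a clustered trait and a Brownian response,
  brunch rejects at the nominal 5% (binomial 99% bounds at 1000 replicates)
  while the naive two-group model rejects ~6× too often — the motivation for
  the contrast analysis, reproduced as a property of the implementations.
* With δ_specific = 2 (a two-SD shift on multicellular-specific compounds),
  the aerobic-bacteria EV exceeds 1 in ≈ 98% of replicates while the
  multicellular group stays consistent — the sampling-bias phenomenon by
  construction.  With a homogeneous shift, every group's verdict is
  consistent in well over 90% of replicates.
* Replicate loops use a desk-scale configuration (80/8/28/28 species, 1000
  reactions, 1400 compounds, one descriptor) chosen so a replicate costs
  ~0.3 s; its behaviour matches the full-scale construction.

## 7. Pipeline and reproducibility

`run_all` drives simulate → load → expansion → phylo → diversity → unknown
from one YAML/JSON config; all randomness flows from a single master seed
(sub-seeds via a seed sequence).  Outputs are plain TSV/JSON; the manifest
records the config hash, input digests, output paths and warning count.
Identical seeds produce byte-identical studies and reports (doubles are
written with %.17g and re-read with round-trip parsing).  Any stage failure
aborts with a nonzero status naming the stage; warnings never change the
exit status.

## 8. Known limitations

* Branch lengths are taken from the input tree as-is; there is no GLS/PGLS
  generalization, no lambda estimation, and no crunch algorithm for
  continuous predictors.
* The ES estimator inherits the WMW test's behaviour under heavy ties;
  descriptor tables with many tied values (e.g. small integer counts) push
  the test into the tie-corrected asymptotic regime even at small N.
* EV's null exceedance depends on the quantile convention and the
  per-species sample size (see §3); EV values near 1 should not be read as
  a sharp 5% test.
* Reaction directionality is parsed but unused; all metrics are set-based.
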