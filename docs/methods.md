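# Methods

This note documents the models behind each `pbrhet` module, the defaults
that matter, the design choices made where the design was genuinely open,
and what the synthetic experiments do and do not establish.

## Substitution counting (`pair_stats`)

Counting follows the unweighted Nei–Gojobori pathway method with no
multiple-hit correction. For each differing codon pair, every ordering of
the differing positions is enumerated with equal weight; pathways passing
through a stop codon are excluded and the weights renormalized (if every
pathway is blocked, the exclusion is waived for that codon pair — a rare
case involving double mutants around stop codons). Synonymous steps accrue
to `K_S` wherever they occur; nonsynonymous steps accrue to `K_B` at masked
(PBR) codons and `K_N` elsewhere. Transition/transversion counts at PBR
codons come directly from the differing positions (they are pathway
invariant). Codons containing gaps, `N`, or stops in either sequence are
excluded pairwise and logged, since the field offers no standard convention
here. `m = K_S + K_N` is binned by rounding to the nearest integer, ties
up, because pathway averaging yields fractional counts while the analysis
is organized around integer `m`.

Site counts are fractional Nei–Gojobori sites (per position, the fraction
of single-nucleotide changes that are synonymous; changes to stop codons
count as nonsynonymous), averaged over the two sequences of a pair; `L_S`
spans the whole gene and `L_N` is restricted to non-PBR codons, mirroring
the definitions of `K_S` and `K_N`.

Raw counts (no Jukes–Cantor/Kimura correction) are used deliberately: the
analysis plots near-integer `m` values, and all saturation behaviour is
then a property of the data rather than of a correction. Consequences of
this choice are visible at the PBR, where deep pairs undercount true events
(the observed `K_B` ceiling of ~25–30 on 27 codons).

The molecular-clock check is a Tajima-style relative-rate test: per
non-PBR codon, nucleotide sites where one ingroup sequence differs while
the other matches the outgroup, and where the change is nonsynonymous in
the outgroup-context codon, are counted as unique to that sequence;
`χ² = (n_a − n_b)²/(n_a + n_b)` with 1 df. This is the standard desk
substitute for a full ML clock test and assumes the outgroup is equidistant
from both sequences.

## Recombination screen (`recomb_filter`)

Under clonal descent, the substitutions separating two alleles fall
uniformly along the gene, so the count inside any fixed region is binomial
with success probability the region's length fraction. The test is the
exact two-sided binomial tail (twice the smaller tail, capped at 1). The
default region scheme — the codon-aligned first third of the gene (an
exon-2-equivalent window) plus a 90-bp sliding window with 30-bp step — is
an explicit reconstruction; the original method's partition is not
described in the source material for this implementation.

For the allele-removal decision a pair counts as flagged when any region
clears a within-pair Bonferroni threshold (`α` divided by the number of
regions). Without this, the 21-window default flags ~40% of clean pairs
and the screen dismantles recombination-free alignments; with it, splice
signals (p ~ 1e-13) are untouched and the pair-level false-positive rate
stays at or below `α`. Removal is greedy per allele: the allele in the most
flagged pairs is dropped (lexicographic tie-break) and the screen repeats
until no pair is flagged.

Two caveats. The binomial null assumes a uniform substitution rate along
the gene; a clustered PBR (as in real DRB1, where the PBR sits in exon 2)
violates it, so on real data the screen is also sensitive to regional rate
contrast, exactly as the original. Calibration experiments therefore use a
uniform-rate generator configuration. And the exact test plus Bonferroni is
conservative — measured pair-level false-flag rate ~0.01 at nominal 0.05.

## Trees, parsimony mapping, JTT (`tree_ops`)

Externally estimated trees (newick, bootstrap as internal node labels) are
preferred input; the fallback builds neighbour-joining trees from pairwise
maximum-likelihood distances under HKY restricted to non-PBR sites, with a
pooled ML estimate of the transition/transversion ratio, site-resampling
bootstrap supports, and negative NJ branch lengths clamped to zero.
Saturated pairs (distance at the optimizer bound) raise an error naming the
pair. Rooting uses the configured outgroup leaves.

PBR amino-acid changes are mapped per site by generalized Fitch parsimony
with Hartigan majority-rule state sets (exact on multifurcations, identical
to Fitch on binary nodes) and a delayed-transformation tie-break: ambiguous
changes are pushed toward the tips, which is conservative when attributing
rate shifts to deep stems. The per-site event total equals the parsimony
score (verified against exhaustive minimal-mutation search over every
rooted topology with up to six leaves). Identical (site, exchange) events
on two or more branches constitute a parallel substitution; the census and
a per-phase tally over allele-pair paths are emitted alongside.

JTT amino-acid distances are maximum-likelihood under the Jones–Taylor–
Thornton replacement model with its published equilibrium frequencies
(27 sites are far too few to estimate frequencies); the rate matrix is
eigendecomposed once and the likelihood maximized in the single time
parameter. Saturated pairs return a documented cap (10 substitutions/site)
with a warning. `nnls_branch_lengths`/`jtt_branch_lengths` fit per-branch
substitution counts to pairwise model distances on a fixed topology by
non-negative least squares; on 27 sites these estimates are unbiased but
high-variance, which is why the rate regression defaults to parsimony
counts (below).

## K_B(m) curve and phases (`kbm_curve`)

The expected curve is the bounded exponential `E[K_B(m)] = B(1 − e^{−am})`,
a stand-in with the qualitative behaviour the theory predicts (linear rise,
saturation); the model object is pluggable so an exact published form can
replace it. The fit is least-squares on the leading `n_fit` bins (default
5) — in the headline analysis the parameters are calibrated so the first
several observations agree with expectation. Numerically the fit is
parameterized as (initial slope `s`, rate `a`) with `B = s/a`, which
degrades smoothly to the linear limit instead of diverging along the flat
`B·a` ridge when the data show no curvature. Note the corollary: `B` is
not identifiable from the early linear segment, so calibration experiments
fit over all bins.

The Z test compares each bin mean with the expectation using
`SE = sqrt(V/n_pairs)`. The default variance model is `V = E` — the
maximum-variance form of a bounded count in the large-capacity limit, which
matches the near-Poisson dispersion measured on homogeneous synthetic data
(per-bin variance ≈ 1.0–1.5 × mean). The capacity-`B` binomial form
`V = E(1 − E/B)` is available (`var_model="binomial"`) and is appropriate
when `B` is a theoretical capacity well above the observed ceiling; with
`B` fitted to the data it understates the variance and roughly triples the
false-significance rate. Pairs sharing alleles are treated as independent,
exactly as the original analysis does; this understates the SE on real
data (measured inflation: ~15% of clean bins "significant" at nominal 5%
when pairs share alleles, ~6% with disjoint pairs) and is a documented
caveat, not corrected.

Phases partition the `m` axis: rising (I, `m ≤ 19`), plateau (II, 20–28),
rising again (III, 29–35), saturated (IV, `m ≥ 36`). Only the I/II boundary
and the II range are data-backed; the III/IV split is an arbitrary,
documented default. The per-phase fast/slow frequency accounting counts an
allele occurrence per pair member, twice when both members carry the class,
and zero for pairs mixing fast with slow; frequency = count / (2 × pairs).

## Rate-shift detection (`rate_het`)

Each non-outgroup branch contributes a point: x = non-PBR substitutions
(branch length × non-PBR sites, or a parsimony/distance-fit re-estimate),
y = mapped PBR events. Two statistical choices depart from the obvious
textbook regression, both forced by the data type:

* **Clock line.** Ordinary least squares with intercept is masked by
  exactly the branches the procedure hunts for: rate-shifted stems are the
  longest, highest-leverage points and drag the line toward themselves
  (measured sensitivity ~0.1 in recovery experiments). The default fit is
  therefore a through-origin trimmed Poisson rate — `Σy/Σx` iteratively
  refitted after symmetrically dropping the 10% most extreme standardized
  residuals on each side. Theil–Sen and OLS remain available; Theil–Sen
  fails here because most branches carry zero events, collapsing the median
  pairwise slope.
* **Outlier band.** Branch counts are small and their variance grows with
  branch length, so a homoscedastic band is simultaneously too wide for
  short branches and far too narrow for long ones (measured false-flag
  rates of 20–90% on clock-like long branches). Candidate calls use exact
  tail probabilities of an overdispersed count — Poisson, or gamma-Poisson
  (negative binomial with variance `φμ`) when the robust dispersion
  estimate `φ` exceeds 1. `φ` is estimated from the median absolute
  standardized residual over trim-retained branches with predicted count
  ≥ 2, floored at 1 (counts cannot be under-Poisson); branches predicted
  below 2 events are never called, since no deviation there is
  distinguishable from zero. The homoscedastic prediction and
  mean-response confidence bands remain as options.

Candidates survive only if the branch-length CI excludes zero (site-
bootstrap of per-branch parsimony counts; free, because parsimony scores
are per-site additive) and, for internal branches, bootstrap support
exceeds 80%; terminal branches bypass the support filter. Flagged branches
below the line are slow, above fast; every leaf inherits the class of its
nearest classified ancestor.

Measured operating characteristics at the validation conditions (36
alleles, 12 lineages, deep lineage span, ten-fold slow-downs on the three
longest stems, 100 replicates): sensitivity ≈ 0.93–0.95, precision
≈ 0.88–0.90, null flag rate ≈ 0.05–0.06 at α = 0.05. A ten-fold *speed-up*
is not recoverable through parsimony on 27 amino-acid sites: ~140 expected
events compress to ~15 visible ones (saturation), so the fast direction is
demonstrated with the count-level simulator instead, where no such
measurement ceiling exists.

## Branch-Poisson simulator (`branch_sim`)

On a fixed tree with per-branch neutral lengths `T_i` (absolute
substitutions), each replicate draws `K_i ~ Poisson(multiplier_i · μ · T_i)`
and sums branch counts along leaf-pair paths; pair counts are binned by
pairwise `T` (unit-width bins by default — the binning of the original
figure is unstated). Defaults: μ = 1 per unit time, slow multiplier 0.1,
fast 10 (both configurable; the factor of ten is an arbitrary but
illustrative choice), 200 replicates with heterogeneity and 100 without.
Homogeneous rates give bin-mean `K` vs `T` correlation > 0.999; slowing
three mid-depth stems produces a mid-`T` window whose local slope falls
well below half the global slope; speeding them steepens late accumulation
several-fold.

## Synthetic data (`synthetic_data`)

The generator emulates the statistical structure the analysis assumes:

* **Genealogy.** The default "mhc" model reflects balancing selection:
  allelic lineages are old and their coalescences do not pile up near the
  present, so the `n_lineages` (default 8) lineage-level merges are evenly
  spaced over a deep span (2.5 time units × `depth_scale`; one unit ≈ 10 My
  at the default rates) with random merge order, and each lineage carries a
  shallow Kingman crown (depth `crown_frac` = 0.15 of its attachment time).
  Stems therefore hold most of the tree length, as in real MHC genealogies.
  Plain Kingman and Yule models are available for neutral-shaped controls.
* **Sequences.** The root is random sense codons; non-PBR sites take
  nucleotide changes at `rate_nonpbr` (default 0.02/site/unit) accepted
  unless they create a stop; PBR sites propose at `rate_pbr_nonsyn`
  (default 0.18/site/unit, of which ~70% are accepted) and accept only
  nonsynonymous non-stop changes, so the PBR process is nonsynonymous-only
  by construction and the truth table logs exactly the quantity parsimony
  tries to recover. Proposals are transition-biased (κ = 2, a typical
  nuclear value). The PBR default rate is anchored to the published early
  curve, where `K_B` at `m = 19` is ~17 over 27 codons, implying an
  accepted PBR rate ≈ 0.13/site/unit against the neutral 0.02.
* **What it does not emulate.** Synonymous changes at PBR codons (absent by
  construction, slightly depressing `K_S` relative to real data); indels;
  intragenic recombination except by explicit splice injection; the
  clustering of real DRB1 PBR codons within exon 2 (the synthetic mask is
  spread uniformly, which keeps the recombination screen's regional null
  clean); and allele-frequency dynamics under selection — the genealogy
  shape is a modeling stand-in, not a population simulation.

Passing tests on these data show the estimators recover known inputs under
the model's assumptions; they do not certify behaviour under real-data
features listed above.

## Validation experiment sizes

Chosen as the package's own scaled designs: rate-shift recovery and null
calibration use 36 alleles / 12 lineages / lineage span 4.0 (deep, as for
genealogies including nonhuman-primate outgroups) at PBR rate 0.1 — the
regime where parsimony mapping remains a valid estimator — with 100 and 50
replicates; accumulation-curve simulations use the full 56-leaf default
tree with 100/200 replicates; recombination calibration uses 40 uniform-
rate replicates and power 100 two-lineage splice replicates (parents below
10% divergence are skipped, the power claim being conditional on divergent
parents); Z-test calibration uses 100 replicates of 12 disjoint pairs each.

## Known limitations

* Fast (ten-fold accelerated) lineages cannot be detected from 27 PBR
  sites by parsimony mapping; only the count-level simulator shows them.
* The expected-curve form and its variance model are reconstructions of a
  theory whose exact published equations are not reproduced here; both are
  pluggable.
* The Z test ignores pair dependence (shared alleles), as in the original
  analysis; its p-values on real data are optimistic.
* Parsimony undercounts PBR events at deep divergences; `K_B` ceilings are
  counting artifacts as much as biology, which is also true of the raw
  (uncorrected) pairwise counts the analysis is built on.
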