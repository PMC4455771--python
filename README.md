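# pbrhet

Temporal heterogeneity of nonsynonymous substitution rates at the
peptide-binding region (PBR) of MHC/HLA alleles.

## The problem

The PBR of classical MHC genes is the most polymorphic coding region in
vertebrate genomes, maintained by balancing selection. Under *symmetric*
balancing selection the allelic genealogy behaves like a stretched neutral
genealogy, so nonsynonymous substitutions at the PBR should accumulate in
proportion to the divergence time of allele pairs until they saturate. Real
HLA data do something stranger: the accumulation curve rises, stalls over an
intermediate range of divergences, then rises again. `pbrhet` implements the
full analysis chain used to diagnose this pattern and to attribute it to
allelic lineages whose PBR substitution rate has slowed down.

## The statistics

For every unordered pair of alleles in a codon alignment, substitutions are
partitioned by the unweighted Nei–Gojobori pathway method (counts, no
multiple-hit correction):

* `K_S` — synonymous substitutions over the entire gene,
* `K_N` — nonsynonymous substitutions outside the PBR,
* `K_B` — nonsynonymous substitutions at the PBR codons,
* `m = K_S + K_N` — substitutions at putatively neutral sites, the
  divergence-time proxy.

`K_B(m)`, the mean `K_B` among pairs sharing the same `m`, is compared with
a saturating expectation `E[K_B(m)] = B(1 − e^{−am})` by a Z test. Pairwise
divergence times come from `d = (K_S + K_N/f)/(L_S + L_N)` and `T = d/2μ`,
with `f` the functional constraint (mean non-PBR dN/dS across pairs) and
`μ = 10⁻⁹`/site/year. PBR amino-acid changes are mapped by Fitch parsimony
onto a phylogeny built from non-PBR sites only (imported newick, or a
built-in NJ fallback on pairwise HKY maximum-likelihood distances with
bootstrap supports); branches whose PBR event count falls outside a 95%
count-calibrated band around the PBR/non-PBR clock line are flagged as
fast or slow lineages, and a branch-wise Poisson simulator
(`K_i ~ Poisson(μT_i)`, slow = λ/10, fast = 10λ) checks that such lineages
reproduce the observed stall of the accumulation curve.

Putative recombinant alleles are removed beforehand by an exact binomial
test of regional substitution density (splice recombinants concentrate
differences in the exchanged region).

## Worked example

Everything is testable without downloads via the synthetic-data module,
which generates codon alignments over a lineage-structured allelic
genealogy with separate PBR / non-PBR substitution processes and ground
truth:

```python
from pbrhet.synthetic_data import SynthConfig, generate_dataset
from pbrhet.pair_stats import (
    all_pair_counts, functional_constraint, DivergenceParams, divergence_time,
)
from pbrhet.kbm_curve import compute_kbm, fit_expected, z_test_bins

aln, truth = generate_dataset(SynthConfig(n_alleles=16, seed=4))
pairs = all_pair_counts(aln)
f, n_used, n_excluded = functional_constraint(pairs)
deepest = max(pairs, key=lambda p: p.m)
d, T = divergence_time(deepest, DivergenceParams(f=f, mu=1e-9))
bins = compute_kbm(pairs)
model = fit_expected(bins, n_fit=len(bins))
z_test_bins(bins, model)
```

This prints (via the obvious format strings):

```
alleles: 16  pairs: 120  f = 0.743
deepest pair AL001-AL012: K_S=18.5 K_N=43.5 K_B=30.0 m=62  d=0.1225  T=61.3 My
expected curve: B=49.6, a=0.0157
  m=  0  K_B(m)=  1.5  expected=  0.0  n=2
  m=  3  K_B(m)=  4.0  expected=  2.3  n=2
  m= 62  K_B(m)= 29.9  expected= 30.9  n=3
```

Read it as: the functional constraint at non-PBR sites is 0.74 (moderate
purifying selection); the deepest pair diverged ~61 My ago at a neutral
divergence of 0.12/site; the `K_B(m)` curve rises from ~1.5 substitutions
for recently diverged pairs to ~30 near saturation, tracking the fitted
expectation — this synthetic run is rate-homogeneous, so no plateau.

The same stages are available from a shell via the `pbrhet` command
(`synth`, `pairs`, `filter`, `kbm`, `tree`, `ratehet`, `simulate`, `all`);
`pbrhet all --config run.yaml` writes per-stage TSVs, a run log and a
summary JSON. To re-analyze real alleles, point `fasta:` at a codon
alignment from the IMGT/HLA database, set `mask: drb1-27` (the built-in
27-codon DRB1 PBR mask) with the appropriate `frame_offset`, and name the
outgroup alleles for rooting.

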