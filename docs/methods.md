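# Methods

## Model and procedure

`boltscan` analyses pooled-sequencing data from a biparental F2 under a
single-locus dominant/recessive model with incomplete penetrance. The
assumptions are:

- One causal biallelic locus; the resistance allele *br* is strictly
  recessive, and a recessive homozygote expresses resistance with
  probability `penetrance_resistant` (default 26/95 ≈ 0.274); every
  carrier of the dominant allele bolts. Phenotype is binary — partial
  bolting is treated as bolting and is not modelled, since it is governed
  by factors unlinked to the locus.
- The resistant pool contains *every* resistant plant (they are all
  recessive homozygotes, so the pool is fixed for the resistant-parent
  haplotype across the linked block); the bolting pool is a large simple
  random sample of bolting plants and is polymorphic at every
  cross-specific site, with expected allele frequency 0.5 at unlinked
  sites.
- Sites where both parents carry the same non-reference allele
  ("reference-divergent" sites) are monomorphic in *both* pools; the
  candidate filter's heterozygous-in-the-bolting-pool condition excludes
  them.

The analysis chain: classify both pools per site from allele depths →
flag candidates (bolting pool HET, resistant pool homozygous, joint
coverage ≥ `min_joint_coverage`) → count candidates out of bolting-HET
sites in sliding windows → locate the peak and the maximal contiguous
runs of candidate sites. The longest run is the mapped interval; its
1-based inclusive boundaries are the outermost supporting sites
(length = end − start + 1; flanking non-monomorphic sites are reported
separately as the recombination-bounded uncertainty).

## Simulator

Each F2 plant receives two gametes; each gamete draws
k ~ Poisson(`crossover_lambda_per_bp` × scaffold length) crossover
positions uniformly per scaffold and alternates parental origin from a
fair random start. Genotypes at catalog sites follow from the two
parental-origin mosaics; pooled sequencing draws per-site depth
d ~ Poisson(mean depth) and alt count ~ Binomial(d, f(1−e) + (1−f)e)
where f is the true pooled alternate frequency and e the per-base miscall
rate. Identical config + seed ⇒ byte-identical exports.

What the generator does *not* emulate: read-level artifacts (mapping
ambiguity, indel realignment, duplicates), sub-pool library structure,
length-polymorphic indels (all sites are biallelic SNPs; the scan treats
short indels and SNPs identically as biallelic sites), linked selection,
or polygenic penetrance modifiers. Passing tests therefore demonstrate
the statistical logic of the scan under idealized sampling, not
robustness to alignment artifacts in real data.

## Parameter defaults

| parameter | default | rationale |
|---|---|---|
| scaffolds | 2 × 5 Mb | desk-scale stand-in for a scaffold-fragmented genome |
| `snp_density` | 1e-3 /bp | one cross-specific site per kb, enough sites per 200 kb window |
| `ref_divergent_fraction` | 0.3 | a substantial minority of polymorphic sites reflect shared divergence from the reference assembly |
| `penetrance_resistant` | 26/95 | the observed resistant fraction among recessive homozygotes |
| `n_f2`, `n_b_pool` | 410, 297 | study-size F2 and bolting pool; the resistant pool is whatever the penetrance yields (~28 expected) |
| `mean_depth_br`, `mean_depth_b` | 60×, 30× | pool coverages on the order of the deep/shallow pool design |
| `error_rate` | 0.005 | produces occasional non-zero minor counts at fixed sites, exercising the classifier band |
| `crossover_lambda_per_bp` | 2e-7 | mean 1 crossover per gamete per 5 Mb scaffold — a handful of recombinants flanking the locus in a ~26-plant pool |
| `min_joint_coverage` | 50 | joint-depth floor for a site to be considered |
| `min_pool_depth` | 10 | per-pool floor below which a pool is NO_CALL (vetoes candidacy); avoids zero-depth frequency artifacts |
| `het_band` | (0.15, 0.85) | open alt-frequency interval called polymorphic |
| `window_bp`, `step_bp` | 200 kb, 100 kb | scan resolution; every interior site falls in exactly 2 windows |
| `min_region_sites` | 20 | guards against error-driven short monomorphic runs |

## Numerical and design choices

- **Coordinates** are 1-based inclusive throughout the library; BED output
  converts to 0-based half-open. The interval-length convention
  end − start + 1 is fixed by requiring that boundaries 4,991,549 and
  5,094,401 span 102,853 bp.
- **Chi-square tails** use the regularized upper incomplete gamma function
  Q(df/2, x/2); tested against direct quadrature of the density to 1e-6.
- **Penetrance intervals** are exact Clopper–Pearson (beta quantiles),
  hence conservative; the study data carry no interval, so the method is
  a package choice.
- **Pairwise rate comparisons** use Pearson 2×2 chi-square without
  continuity correction (a flag enables it) and Holm adjustment by
  default (conservative without independence assumptions; Bonferroni and
  Benjamini–Hochberg available). Degenerate tables with an empty
  phenotype column are reported as statistic 0, p = 1.
- **Peak ties** are broken lexicographically by (scaffold, start); all
  tied windows are reported.
- **Pool classification** is a deliberate, transparent replacement for
  running a diploid genotype caller on pooled DNA: the band (0.15, 0.85)
  maps pooled frequencies to HOM/HET states and is configurable; setting
  it close to (0, 1), or using the scanner's `exact` region mode, tightens
  monomorphism toward "frequency exactly 0 or 1".
- **Region mode** defaults to `by_call` because with any nonzero
  sequencing error a truly fixed site rarely shows an observed frequency
  of exactly 0 or 1 at finite depth, so `exact` mode finds almost no
  contiguous runs on realistic data.

## Known limitations

- With the default band, sites whose true resistant-pool frequency lies
  between the band's upper edge and 1 (one to a few recombinant
  haplotypes) are still called homozygous. The detected monomorphic block
  around the causal locus is therefore wider than the innermost
  recombination breakpoints, and near its edges occasional
  heterozygous-called sites fragment it into several adjacent regions —
  all on the causal scaffold, with the longest one containing the causal
  site (verified over seeded runs). Tightening `het_band` toward (0, 1)
  trades this width for sensitivity to sequencing error.
- Double crossovers between adjacent markers are undetectable in the
  marker module by construction.
- Only the standard nuclear genetic code is supported in `effects`;
  start-codon validity is not enforced (gene models may be partial).
- Problem sizes in the test-suite simulations (10^4 plants for
  segregation frequencies, 200 seeds for the penetrance Monte-Carlo,
  20 end-to-end desk-scale runs) are the package's chosen desk scale; the
  statistics they check are scale-free.
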