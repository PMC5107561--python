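# boltscan

Mapping-by-sequencing (bulked-segregant analysis, BSA-seq) of a recessive,
incompletely penetrant locus from phenotype-pooled F2 whole-genome
sequencing — modelled on the genetics of post-winter bolting resistance in
sugar beet (*Beta vulgaris*).

## The problem

Biennial beets bolt (elongate a flowering stem) after winter vernalization;
"never-bolting" plants carry a recessive resistance allele *br* at a major
locus. In an F2 cross the locus segregates 1:2:1, but only a minority of
recessive homozygotes actually express resistance (incomplete penetrance).
Pooling the DNA of all resistant plants and of a large random sample of
bolting plants, sequencing both pools, and comparing pooled allele
frequencies localises the locus: resistant plants are all recessive
homozygotes, so the resistant pool is *monomorphic* across the linked
block, while the bolting pool stays polymorphic at every cross-specific
site genome-wide.

`boltscan` implements that analysis end to end, plus a generator of
synthetic datasets with exactly this statistical structure:

- **simcross** — F2 cross simulator: Poisson-crossover gametes, binary
  phenotype with penetrance *p* for recessive homozygotes, phenotype
  pools, Poisson/binomial pooled read depths with sequencing error, and
  plain-text export (VCF with per-pool `AD` depths, TSV tables, YAML
  provenance).
- **poolcalls** — per-pool genotype classification from allele depths
  (frequency-band rule) and the candidate filter: heterozygous in the
  bolting pool, homozygous in the resistant pool, joint coverage ≥ 50×.
- **scanner** — the sliding-window statistic (count of resistant-pool
  monomorphic sites out of bolting-pool polymorphic sites; 200 kb windows,
  100 kb step), peak finding, the per-site allele-frequency track, and
  maximal contiguous monomorphic-region detection with recombination
  flanks.
- **genestats** — 1:2:1 segregation chi-square, genotype→phenotype
  prediction accuracy, exact-binomial penetrance estimation
  (Clopper–Pearson), F3 family bolting-rate summaries, and pairwise
  Pearson chi-square comparisons with Holm/Bonferroni/BH adjustment.
- **markers** — codominant marker (A/H/B) locus verification, crossover
  breakpoint detection, and flank refinement around a focal marker.
- **effects** — CDS variant application, translation, and consequence
  calling (synonymous … frameshift), including truncation descriptions
  such as "203 instead of 633 aa".
- **cli_io / cli** — format readers/writers and the `boltscan` command
  (`simulate`, `call`, `scan`, `region`, `stats`, `markers`, `effects`).

## Worked example

```python
from boltscan import simcross, poolcalls, scanner, cli_io

cfg = simcross.CrossSimConfig(seed=1)          # 2 x 5 Mb, 410 plants, penetrance 26/95
ds = simcross.simulate_dataset(cfg)
calls = poolcalls.filter_candidates(cli_io.to_pooled_sites(ds))
peak = scanner.find_peak(scanner.score_windows(calls, cfg.scaffold_lengths))
top = scanner.find_monomorphic_regions(calls)[0]
print(len(ds.br_ids), peak.best.scaffold, peak.best.start, peak.best.end)
print(top.scaffold, top.start, top.end, top.length_bp)
```

prints

```
20 sca01 2000001 2200000
sca01 2160590 3117540 956951
```

— this run produced 20 resistant plants; the window scan peaks on the
causal scaffold around the simulated locus at 2.5 Mb, and the longest
monomorphic region (957 kb here; width is set by where recombinant
haplotypes accumulate) contains the causal position. The same pipeline on
the command line:

```sh
boltscan simulate --seed 1 --out sim/
boltscan call sim/variants.vcf --out calls.tsv
boltscan scan sim/variants.vcf --out scores.tsv
boltscan region sim/variants.vcf --out regions.tsv
```

For the locus statistics from a phenotype table
(`plant_id  phenotype  causal_genotype`):

```sh
boltscan stats sim/phenotypes.tsv --out stats.json
```

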