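# poolsweep

Pooled-sequencing (Pool-seq) population-genomics toolkit for detecting and
characterising hard selective sweeps, plus probit dose–response analysis of
insecticide bioassays. It reimplements, as a tested reusable pipeline, a
workflow of:

- windowed nucleotide diversity (π), Watterson's θ, and Tajima's *D* from
  Popoolation2-style `sync` allele counts, with uniform-coverage
  subsampling (target 50×, max 100×);
- delineation of low-diversity sweep regions, bootstrap confidence
  intervals of the mean Tajima's *D*, and empirical 1% tails;
- pairwise F<sub>ST</sub> under two estimators (classical heterozygosity
  ratio and a pool-size–corrected identity/ANOVA moment estimator),
  top-1% outlier SNPs, and multilocus recomputation excluding a region;
- PCA-based SNP outlier scanning (z-scores against K components,
  Mahalanobis distances, χ²(K) p-values, Benjamini–Hochberg q-values);
- coding-consequence screening of segregating variants (synonymous /
  nonsynonymous, BLOSUM62 conservativeness, per-pool alternate read
  fractions);
- probit LC50 fits on log10 dose with Fieller 95% confidence limits and
  CI-overlap population comparisons;
- a synthetic-data generator that emulates the pooled design (3 pools of
  100 diploids, neutral-SFS background, planted sweep core + population-
  specific extension, a fixed nonsynonymous SNP, differentiated outlier
  SNPs, ~50× usable coverage with sequencing error) and writes truth
  tables for validation.

## Formats

- **sync** (Popoolation2 dialect): tab-separated
  `chrom  pos  ref  A:T:C:G:N:del [...]`, one count sextuplet per pool.
  `N`/`del` are parsed but excluded from every statistic.
- GFF3 (gene/mRNA/CDS) annotations, FASTA references, TSV reports.
- Coordinates are 1-based inclusive throughout; windows are
  `[k·w+1, (k+1)·w]`.

## CLI

```sh
poolsweep simulate  --out sim/ --seed 1            # synthetic sync+GFF3+FASTA+truth
poolsweep diversity --sync sim/pools.sync --n-pops 3 --out div/
poolsweep sweep     --windows pop0 div/diversity_pop0.tsv --out regions.tsv
poolsweep fst       --sync sim/pools.sync --n-pops 3 --out fst/
poolsweep pca       --sync sim/pools.sync --n-pops 3 --out pca.tsv
poolsweep screen    --sync sim/pools.sync --n-pops 3 --gff sim/genes.gff3 \
                    --fasta sim/reference.fasta --region scaffold_1:1-50000 \
                    --out variants.tsv
poolsweep probit    --csv assays.csv --out probit.tsv
poolsweep all       --config config.yaml --out run/ --seed 1
```

`poolsweep all` runs every stage from one YAML config (see
`tests/test_cli.py` for a worked example), expands the global seed into
fixed per-stage seeds, and writes a `manifest.json` of SHA-256 checksums;
identical config + seed reproduce byte-identical outputs.

Assay CSVs for `probit` have columns
`population,concentration,n_exposed,n_dead` (concentration in ppm,
replicate rows allowed).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: estimator-oracle
equivalence (exhaustive pair counting for π; brute-force codon translation
for consequence calls), neutral calibration (Tajima's *D*, PCA p-value
uniformity, BH false-discovery control), sweep boundary recovery on planted
sweeps, F<sub>ST</sub> bias on moment-matched island-model grids, probit
LC50 bias/coverage, and end-to-end determinism.

## Notes and deliberate simplifications

- Tajima's *D* uses the classic constants with n = subsampled coverage;
  no pooled-data correction is applied. With finite pools (2n = 200) the
  read sample slightly under-represents rare variants, biasing *D*
  positive; the neutral-calibration test uses a large pool to isolate the
  neutral sampling model.
- The generative model of `synthetic_data` is a stand-in (the emulated
  study is empirical): neutral-SFS frequencies, Beta drift perturbation,
  Poisson depth, binomial read sampling, uniform miscall errors.
- Negative F<sub>ST</sub> estimates are reported raw; `--clamp-zero`
  implements the "effectively zero" reading for summaries.
- "Conservative" amino-acid changes default to BLOSUM62 score ≥ 0
  (configurable).
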