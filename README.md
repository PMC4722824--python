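# scenabc

Population-divergence scenario comparison by approximate Bayesian
computation (ABC), the full battery of population-genetic summary
statistics it rests on, and an avian tetrahedral color-space analysis of
reflectance spectra — built around a four-group cloud-forest hummingbird
study system, with a synthetic-data generator standing in for the field
data.

## What it does

* **popdata** — data model and I/O: FASTA alignments, GenePop diploid
  microsatellite genotypes, and a 3-column individual→population→group
  map TSV, combined into a validated `MultilocusDataset`.
* **sumstats** — TN93 distances, haplotype/gene diversity, nucleotide
  diversity, segregating sites, Tajima's D and Fu's Fs with simulation
  p-values, mismatch distributions under the sudden-expansion model (SSD,
  raggedness, parametric bootstrap), microsatellite diversity (A, He, Ho,
  allele-size variance, rarefied allelic richness), Weir–Cockerham θ,
  N_ST, hierarchical AMOVA with permutation tests, and the ordered
  48-statistic summary vector used by the ABC machinery.
* **coalsim** — backward-time structured coalescent for merge/admixture
  scenarios (presets `Sc1`, `Sc2`, `Sc3`), HKY sequence mutation and a
  generalized stepwise model for microsatellites, uniform priors with
  ordering constraints, reproducible reference tables, and
  generation-time / mutation-rate arithmetic.
* **abc** — MAD-standardized rejection, multinomial-logistic model choice
  with delta-method CIs, local-linear-regression parameter posteriors
  (logit-bounded to the prior), POD Type I/II error rates, and PCA-based
  posterior-predictive model checking.
* **colorspec** — LOESS spectrum smoothing, dual-window hue extraction,
  quantum catches for an idealized tetrachromat, tetrahedral coordinates
  (X, Y, Z, hue angles, chroma, r_max, r_achieved), and convex-hull color
  volumes with exact (half-space) or Monte-Carlo overlap.
* **synthdata** — truth-annotated synthetic fixtures: a joint
  mtDNA + microsatellite dataset at the study's sample sizes (751 bp;
  19/70/37/27 sequences; 126 genotyped individuals at 8 loci) and two-peak
  reflectance spectra (UV ≈ 420 nm; long-wave 715 vs 780 nm groups).
* **pipeline** — a single JSON config driving stats → reference table →
  model choice → estimation → PODs → checking → color, with a manifest of
  seeds, hashes and runtimes.

## CLI

```sh
scenabc fixture popgen --seed 3 --out fx/            # synthetic dataset
scenabc fixture spectra --seed 3 --out fx/           # synthetic spectra
scenabc stats --fasta fx/sequences.fasta --genepop fx/genotypes.gen \
    --map fx/popmap.tsv --perms 1000 --seed 1 --out stats.csv
scenabc refbuild --n 10000 --seed 7 --out ref.csv
scenabc choose --ref ref.csv --fasta ... --genepop ... --map ... \
    --delta 0.01 --out choice.json
scenabc estimate --ref ref.csv --scenario Sc1 ... --out params.json
scenabc pods --ref ref.csv --n-pods 500 --out pods.json
scenabc color --spectra fx/spectra.csv --groups fx/groups.tsv \
    --span 0.25 --out color.csv
scenabc run --config run.json                        # full pipeline
```

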