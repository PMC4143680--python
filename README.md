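# pathkin

Pathway-specific genetic relationship matrix (PSGRM) screening on pedigrees.

`pathkin` tests whether the variants in or near the genes of a pathway
explain a share of a quantitative trait's heritability beyond the pedigree's
expected polygenic background. For each pathway it:

1. maps gene symbols to genomic windows (longest isoform ± 5 kb),
2. collects all biallelic SNVs in those windows from a VCF,
3. estimates an empirical kinship matrix **E** (the PSGRM) for every sample
   pair with the robust heterozygote-concordance / opposite-homozygote
   estimator (negative estimates retained; PSD repair is explicit),
4. adds **2E·h²gp** as a second variance component to the polygenic model
   **Ω = σ²(2Φ·h²r + 2E·h²gp + I·e²)** (Φ = pedigree kinship), fits both
   models by maximum likelihood (fixed effects: sex, age, smoking,
   optional founder-projected principal components), and
5. tests h²gp with a one-degree-of-freedom boundary LRT referred to a
   50:50 mixture of χ²₁ and a point mass at zero.

A synthetic-data module (multi-generation pedigrees, gene dropping across a
rare/common MAF spectrum, phenotypes with known variance fractions) makes the
entire pipeline testable without any external dataset.

## Command line

Every subcommand writes a JSON manifest (version, config hash, input
checksums, seed) next to its outputs.

```bash
# generate a synthetic study (PED, VCF, GMT, transcript table, phenotypes)
pathkin simulate --out simdir --seed 42 --families 20 --generations 3 \
    --pathways 20 --h2gp 0.15 --causal-pathway 0

# map gene sets to windows (longest isoform +/- flank)
pathkin regions --gmt simdir/sim.gmt --genes simdir/sim_genes.tsv \
    --flank 5000 --out regions.bed

# founder PCA on LD-pruned common variants, projected to all samples
pathkin pca --vcf simdir/sim.vcf --ped simdir/sim.ped --k 5 --r2-max 0.1 \
    --out pcs.tsv

# per-pathway robust kinship matrices
pathkin grm --vcf simdir/sim.vcf --regions regions.bed --ped simdir/sim.ped \
    --min-pair-variants 50 --out grms/pathway

# the screen itself: one row per pathway, sorted by p
pathkin screen --vcf simdir/sim.vcf --ped simdir/sim.ped \
    --pheno simdir/sim_pheno.tsv --gmt simdir/sim.gmt \
    --genes simdir/sim_genes.tsv --covars sex,age,smoke --pcs pcs.tsv \
    --maf-below 1.0 --out results.tsv

# QQ table + inflation lambda; optional kinship-deviation summary
pathkin diag --results results.tsv --out diag/
```

`--maf-below 0.05` (or `0.01`) restricts the PSGRM to variants with MAF
strictly below the threshold; `1.0` means no filter.

## Layout

| module | contents |
| --- | --- |
| `pathkin.pedigree` | PED parsing, expected kinship Φ (tabular recursion), kinship I/O |
| `pathkin.regions` | GMT parsing, gene windows, VCF extraction, MAF filter, `GenotypeMatrix` |
| `pathkin.kernel` | pairwise counts, robust kinship, PSD kernel repair (`bend`/`clip`/`raw`) |
| `pathkin.pca` | LD pruning, founder PCA, projection to relatives |
| `pathkin.vc` | variance-component ML fits, boundary LRT, pathway screen |
| `pathkin.diagnostics` | kinship-deviation summaries, QQ/λ report |
| `pathkin.simulate` | synthetic pedigrees, gene dropping, phenotypes, file writers |
| `pathkin.experiments` | replicated calibration/recovery/power experiments |
| `pathkin.cli` | `pathkin` entry point wiring it all together |
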