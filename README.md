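# riqtl

Systems-genetics toolkit for two-founder recombinant-inbred (RI) mouse
panels. It covers the full analysis chain from per-animal records to
prioritized candidate genes:

- **`riqtl.simulate`** — synthetic RI genotypes (founder mosaics with the
  sib-mating map expansion R = 4r/(1+6r)), strain phenotypes with planted
  QTL effects and a chosen heritability, and paired eQTL/GWAS summary
  statistics with a known causal slope — ground truth for validating every
  downstream stage.
- **`riqtl.phenotypes`** — strain-level trait derivation: Kaplan–Meier
  median survival with censoring, daily survival rates, body-weight-loss
  trajectories (grams and percent), paired baseline/post echo deltas, and
  the 2Z+8 affine normalization (mean 8, SD 2).
- **`riqtl.qtl`** — Haley–Knott single-marker regression scans
  (LRS = n·ln(RSS0/RSS1), LOD = LRS/4.605), permutation genome-wide
  thresholds, an EMMA-style mixed-model scan with a kinship random effect,
  and LOD-drop support intervals.
- **`riqtl.scoring`** — weighted 8-criterion candidate-gene scoring
  (six 1-point evidence criteria; functional relevance and MR significance
  worth 2 each; selection at ≥30% of the 10-point maximum), interval gene
  queries, cis-eQTL classification, DEG flagging.
- **`riqtl.mr`** — two-sample Mendelian randomization: allele
  harmonization, Wald ratio (single instrument), fixed-effects IVW
  (multiple instruments), gene × outcome significance tables.
- **`riqtl.enrichment`** — hypergeometric over-representation analysis
  with a pre-test minimum-overlap filter and Benjamini–Hochberg FDR.
- **`riqtl.pipeline` / `riqtl.cli`** — end-to-end orchestration with
  deterministic seeds and a plain-text artifact manifest.

## CLI

The `riqtl` entry point exposes one subcommand per stage:

```sh
# simulate an RI panel with one planted QTL (chr:pos_cM:effect)
riqtl simulate --n-strains 60 --qtl 2:25:1.0 --h2 0.5 --seed 1 --out sim/

# genome scan with a 10,000-permutation genome-wide threshold
riqtl scan --geno sim/genotypes.geno.tsv --pheno traits.tsv \
           --trait trait --method hk --perms 10000 --alpha 0.05 \
           --seed 1 --out scan.tsv

# 2-LOD support interval around the peak
riqtl interval --scan scan.tsv --chromosome 2 --drop 2 --out interval.json

# score candidate genes (bundled example evidence tables: bwloss | echo)
riqtl score --evidence bwloss --out scorecards.tsv

# two-sample MR over every gene x outcome pair
riqtl mr --exposure eqtl.tsv --outcome gwas.tsv --out mr.tsv

# over-representation analysis against a GMT file
riqtl enrich --genes genes.txt --gmt categories.gmt --out enrichment.tsv

# everything end to end from a YAML config (or built-in synthetic demo)
riqtl run --out demo_out/
```

Genotype files use a GeneNetwork-style TSV dialect (`#chromosome` /
`#position_mb` / `#position_cm` header lines, then one row per strain with
`B/D/H/U` or `0/1/0.5/NA` cells). All outputs are TSV/JSON; `manifest.json`
records the config, seeds, and artifact checksums, and a rerun with the
same config is byte-identical.

## Bundled data

`src/riqtl/data/candidates_{bwloss,echo}.tsv` are small example evidence
tables (criterion flags plus heart expression TPM for 22 and 9 genes) used
by the demo pipeline, the test suite, and the acceptance report.
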