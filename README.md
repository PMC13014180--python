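# sulcnet

Sulcal phenotype networks (SPNs) and their statistical analysis chain:

- **`sulcnet.spn`** — per-subject SPNs (40×40 correlation matrices of five
  standardized sulcal shape phenotypes), the eigen-fold index (PC1 of a mean
  control SPN, ordering sulci along the linear-to-complex axis), Fisher-Z
  sulcal complexity scores, cross-reference scoring, SPN similarity and
  bipartite clustering.
- **`sulcnet.effects`** — per-sulcus standardized case-control effects
  (OLS with configurable covariates, Bonferroni/nominal flags) and the
  linear/complex contraction test (REML random-intercept mixed model with
  one-sided Wald p values).
- **`sulcnet.spatial`** — spin-permutation spatial nulls (uniform rotations
  of a spherical parcellation with hemisphere mirroring), cross-syndrome
  similarity matrices, and permutation-validated PCA of effect maps.
- **`sulcnet.gwas`** — GWAS phenotype preparation (±5 SD outlier exclusion,
  Blom rank-inverse-normal transform, covariate residualization), Nyholt
  effective-test arithmetic and significance thresholds, a per-variant OLS
  association scan, greedy r² clumping, and positional 10 kb SNP-to-gene
  mapping.
- **`sulcnet.fetal`** — fetal expression module discovery (within-timepoint
  Z-scoring, k-means sweep with elbow selection, degree-weighted
  prototypes), transcriptome co-expression ranking and preranked GSEA with
  permutation p and FDR q.
- **`sulcnet.synthetic`** — seeded generators for every input (cohort
  phenotype tables with planted effect maps and axis contraction, spherical
  parcellations, LD-blocked genotypes with planted causal SNPs, expression
  cubes with planted modules and GMT gene sets), each returning its ground
  truth for recovery testing.
- **`sulcnet.io` / `sulcnet.workflow` / `sulcnet.cli`** — TSV/GMT/BED/JSON
  readers and writers with provenance headers, validated run configuration,
  and three end-to-end workflows (`cohort`, `gwas`, `modules`).

## CLI

The console script `sulcnet` groups subcommands by stage:

```bash
sulcnet simulate cohort --n-cases 100 --n-controls 100 --seed 7 --out run/
sulcnet simulate parcellation --n-sulci 40 --seed 1 --out parc.tsv
sulcnet effects map --phenotypes run/phenotypes.tsv --out effects.tsv
sulcnet spatial spin --a map_a.tsv --b map_b.tsv --parcellation parc.tsv \
    --spins 10000 --seed 0
sulcnet gwas thresholds --meff 34
sulcnet modules fit --expression expr.tsv --gene-sets sets.gmt --out out/
sulcnet run --workflow cohort --seed 1 --out run_dir/
```

## Conventions worth knowing

- All matrices and maps follow the canonical 40-sulcus ordering in
  `sulcnet._atlas.CANONICAL_SULCI` (20 bilateral pairs, left block first).
- Complexity scoring excludes each sulcus's self-correlation entry by
  default (`include_diagonal=True` restores the 40-entry variant); the
  pipeline anchors the eigen-fold index so the complex pole is positive.
- Fisher-Z clips |r| at 1 − 1e-12; standard deviations use n − 1; genomic
  positions are 1-based inclusive internally (BED converted on read);
  permutation p values use the add-one estimator.
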