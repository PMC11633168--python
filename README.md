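# urobiome

A tested, reusable pipeline for low-biomass (urinary) microbiome analysis:

- **Decontamination** — a three-step contaminant-removal procedure driven by
  mock-community controls and PCR concentrations: cohort-wide flags
  (concentration correlation, a frequency-model p-value, rarity, mock
  presence, low read counts), plate-specific flags from each 96-well plate's
  mock, then removal of non-bacterial taxa with renormalization and a
  per-sample contaminated-fraction report.
- **Community metrics** — Shannon/Simpson diversity, Bray–Curtis and
  root-Jensen–Shannon distances, PCoA, and one-factor PERMANOVA (with an
  exact-enumeration mode for small n).
- **Urotyping** — PAM (k-medoids) clustering on root-JSD distances,
  cluster-number selection by the Calinski–Harabasz index, and
  LDA-effect-size marker ranking with per-cluster dominant taxa and Welch
  enrichment tests.
- **Host factors** — univariable distance-based redundancy analysis (dbRDA)
  with permutation tests, Benjamini–Hochberg screening, Spearman
  collinearity pruning, category-wise variation partitioning (Ezekiel
  adjusted R²), and feature–phenotype correlation tables.
- **Sex analysis** — two-class LDA-effect-size markers and a
  random-forest sex classifier reported with a Mann–Whitney AUC and Gini
  importances.
- **mGWAS** — Hardy–Weinberg exact tests, variant QC, genotype principal
  components, a dual association scan (residualized log10-abundance linear
  model for taxa >50% prevalent; presence/absence logistic model for
  10–50%), genome-wide hit calling at 5×10⁻⁸, and genotype×environment
  interaction tests.
- **Synthetic cohorts** — a Dirichlet-multinomial generator with latent
  community types, sex structure, hormone-like phenotypes,
  concentration-dependent contaminants with per-plate mock controls,
  genotypes, and planted genetic effects — all recorded in a truth object
  so every stage can be validated by parameter recovery.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for
the metric axioms, and `tests/test_acceptance.py`, which checks the
pipeline's recovery/calibration behavior on synthetic cohorts (dual-route
oracle equivalences, decontamination sensitivity, urotype recovery, GWAS
type-I error and power, classifier behavior, determinism).

## CLI

```sh
urobiome simulate  --seed 1 --out cohort/ --n-study 600 --n-taxa 100 --n-variants 1000
urobiome decontam  --profiles cohort/profiles.tsv --samples cohort/samples.tsv --out decon/
urobiome diversity --profiles decon/cleaned.tsv --out div/ --metric bray_curtis
urobiome permanova --profiles decon/cleaned.tsv --samples cohort/samples.tsv --group sex
urobiome urotype   --profiles decon/cleaned.tsv --out uro/
urobiome factors   --profiles decon/cleaned.tsv --samples cohort/samples.tsv --out fac/
urobiome sexdiff   --profiles decon/cleaned.tsv --samples cohort/samples.tsv --out sexd/
urobiome mgwas     --profiles decon/cleaned.tsv --samples cohort/samples.tsv --vcf cohort/genotypes.vcf --out gwas/
```

Profile tables are MetaPhlAn-style TSVs (rank-prefixed lineages in column
1, samples across; percent or fractional dialect auto-detected), sample
sheets are TSVs with `sample_id`/`role`/`plate_id`/phenotype columns, and
genotypes are biallelic VCF v4.x.

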