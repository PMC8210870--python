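# eradiff

Compositional analysis pipeline for finding gut-microbiota taxa that
discriminate two hospitalization eras in a longitudinally sampled cohort.
Stages:

1. **feature_table** — genus-level count-table IO, depth/abundance filtering
   (samples < 500 reads, taxa < 0.01% of reads), clr transform, Aitchison
   distance.
2. **ordination** — PCA, one-way PERMANOVA (pseudo-F, R², seeded label
   permutations, optional exhaustive enumeration), group-dispersion
   homogeneity test in principal-coordinate space, chemotherapy week binning.
3. **splsda** — sparse PLS-DA with per-component keepX selection
   (default: 50 most discriminant taxa on component 1), leave-one-out
   selection stability, and Mann–Whitney AUROC (apparent and cross-validated).
4. **exposure** — daily binary antibiotic exposure series for 7 antibacterial
   classes over admission → day-before-collection, summarized by an
   unnormalized decaying weighted sum (most recent day at weight `decay⁰`);
   exposure-score PCA axes as regression covariates.
5. **differential** — per-taxon OLS of clr abundance on era + collection day +
   two exposure PCA axes, Benjamini–Hochberg correction, volcano selection
   (|β| > 2, q < 0.05, strict), and a leave-one-patient-out robustness screen.
6. **synthetic_cohort** — ground-truthed logistic-normal–multinomial cohort
   generator (patient-level era assignment, twice-weekly sampling,
   negative-binomial depths, policy-driven antibiotic courses) used to test
   every stage end-to-end.
7. **pipeline** / **cli** — deterministic orchestration with per-stage
   sub-seeds and a JSON report.

## CLI

```sh
# generate a synthetic cohort (counts.tsv, metadata.tsv, exposures.tsv, truth.json)
eradiff simulate --config cfg.json --seed 1 --out sim/

# full pipeline
eradiff run --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --exposures sim/exposures.tsv --keep 50 --permutations 999 \
    --seed 1 --out out/

# individual stages
eradiff permanova --counts ... --metadata ... --permutations 999 --seed 1
eradiff dispersion --counts ... --metadata ... --by week
eradiff splsda --counts ... --metadata ... --keep 50 --out out/
eradiff exposure --metadata ... --exposures ... --decay 2 --out out/
eradiff differential --counts ... --metadata ... --exposures ... \
    --candidates stable_taxa.txt --out out/
```

Input dialects: the count table is TSV, either sample-major or taxa-major
(BIOM-style export with a `#OTU ID` header, auto-detected); metadata TSV
needs `sample_id, patient_id, era, admission_day, collection_day` with era
in `{pre, covid}` and day 0 = first day of chemotherapy; exposures are
long-format TSV `patient_id, day, antibiotic_class` over the 7 canonical
class names (see `eradiff.exposure.ANTIBIOTIC_CLASSES`).

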