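# germstrata

Temporal stratification, rate estimation and cellular lineage
reconstruction for germline de novo mutations (DNMs) in multi-sibling
pedigrees.

Given per-mutation, per-individual, per-tissue allele counts from deeply
sequenced two-parent pedigrees, the package:

- **filters** candidate DNMs (region masks, reciprocal-cross screens,
  Poisson depth ceiling, parental-support or unrelated-error-rate screens,
  minimum candidate VAF) and, separately, candidate parental very-early
  embryonic (VEE) mosaics;
- **classifies** each mutation event into one of four temporal strata of
  the germline — VEE (mosaic ~25% of reads in one offspring), EE
  (constitutive in offspring, 2–20% mosaic in a parent's soma), peri-PGC
  (shared by ≥2 siblings, <1.6% of cells in parental soma), and late
  post-PGC (constitutive, single offspring) — using a binomial
  log-likelihood contrast, exact parental-mosaicism tests and haplotype
  occupancy from read-pair phasing;
- **estimates** mutation rates per generation, per year and per cell
  division under an explicit germline cellular demography (Drost & Lee
  division counts), with exact Poisson intervals, a linear VEE germline
  transmission model, stage-specific per-division rates, a mixed-model
  parental-age effect and a bootstrap over-dispersion test;
- **compares** seven-category mutation spectra (CpG-split transitions)
  with a chi-squared test;
- **reconstructs** parental embryonic cell lineages by iteratively merging
  shared mutations whose carrier sets co-occur more often than expected
  under independence, with randomisation-based concordance validation;
- **simulates** pedigrees, mutation truth tables and read counts with the
  same statistical structure, so every stage is testable end to end
  without external data.

## Command line

```sh
# simulate a 2-pedigree cohort and write pedigree/truth/call tables
germstrata simulate --config cfg.yaml --seed 1 --out sim/

# filter -> classify -> rates -> spectra -> lineages
germstrata filter   --calls sim/calls.tsv --pedigree sim/pedigree.tsv \
                    --mode error-rate --out retained.tsv --ledger ledger.tsv
germstrata classify --calls sim/calls.tsv --retained retained.tsv \
                    --pedigree sim/pedigree.tsv --out strata.tsv
germstrata rates    --strata strata.tsv --pedigree sim/pedigree.tsv \
                    --demography mouse --out rates.json
germstrata spectra  --events strata.tsv --out spectrum.tsv
germstrata lineages --strata strata.tsv --pedigree sim/pedigree.tsv \
                    --validate 10000 --seed 1 --out lineages.json

# or the full pipeline in one step
germstrata run --calls sim/calls.tsv --pedigree sim/pedigree.tsv \
               --demography mouse --out results/
```

Call tables are long-format TSV (`chrom pos ref alt individual tissue
ref_reads alt_reads`); pedigrees are TSV (`id sex role pedigree mother
father litter parental_age_weeks tier`). `--demography` accepts `mouse`,
`human` or a TSV of demography fields.

## Layout

| module | contents |
| --- | --- |
| `germstrata.pedigree` | domain types, MNV merging |
| `germstrata.simulate` | pedigree/germline/read-count simulator |
| `germstrata.filtering` | candidate DNM and parental-VEE filter stacks |
| `germstrata.classify` | temporal-strata classifier and power calculations |
| `germstrata.rates` | rate sets, demographies, age effect, dispersion tests |
| `germstrata.spectra` | spectrum profiles and chi-squared comparison |
| `germstrata.lineage` | lineage agglomeration and randomisation validation |
| `germstrata.io`, `germstrata.pipeline`, `germstrata.cli` | tables, driver, CLI |
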