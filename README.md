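# alltriage

Whole-exome variant triage for small leukemia cohorts.

When a handful of acute lymphoblastic leukemia (ALL) patients are
exome-sequenced without matched healthy tissue, somatic and germline
variants cannot be separated directly. `alltriage` implements the
pragmatic alternative used in small-cohort precision-oncology studies:
reduce the call set with a filter cascade, then rank what remains by
how much is already known about it clinically and mechanistically. It
is aimed at bioinformaticians analysing small annotated cohorts (here,
a 9-patient / 7-control ALL cohort from a predominantly Hispanic
border-region population) against catalogue snapshots standing in for
GnomAD, the COSMIC Cancer Mutation Census (CMC), OncoKB and a
targetable-pathway reference.

## What it computes

**Filter cascade.** Starting from annotated VCFs, keep coding
(non-synonymous and truncating) variants; remove any allele carried by
a healthy control; remove alleles with population allele frequency
strictly above 5% in the matched reference population (default:
Latino/Admixed American, `LAT`). Alleles absent from the frequency
catalogue are kept — absence is treated as rarity.

**Tier classification.** Each surviving amino-acid change is ranked
from three CMC-style evidence factors — (1) recurrent mutation in a
Cancer Gene Census driver, (2) pathogenic in ClinVar, (3) positive
selection by dN/dS:

| rank | rule |
|---|---|
| Tier 1 | factors 1 and 2 |
| Tier 2 | any other pair of factors |
| Tier 3 | exactly one factor |
| Other | no factor |
| Tier X | the residue position carries Tier 1–3 entries, but this specific change is uncatalogued or labeled "other" |

Genes are independently assigned an OncoKB-style clinical-evidence
level (1 = FDA-recognized biomarker … 4 = compelling biological
evidence; minimum across diagnostic/prognostic/therapeutic categories)
and mapped to targetable pathways.

**Cohort statistics.** A patients × variants carrier matrix (carrier =
dosage ≥ 1), aggregation of all changes at one residue (e.g. every
substitution at KRAS codon 12, "G12X"), and carrier percentages
stratified by ethnicity or disease status, with fold differences and
2×2 counts between two strata.

**Ancestry.** Genotypes are intersected with a common-sites list,
pairwise distances are computed as 1 − IBS (identity by state) over
pairwise-complete loci, embedded by classical (Torgerson) MDS, and
each query sample is assigned the nearest reference-population
centroid in the first two dimensions.

**Synthetic data.** Deterministic generators for cohort/control VCFs
with planted variants and a cascade-survival truth table, reference
genotype panels with divergent populations, and a packaged fixture
encoding the published patient–variant assignments of the borderland
ALL cohort.

## Worked example

```python
import tempfile
from pathlib import Path
from alltriage import borderland_fixture, RunConfig, run_pipeline

work = Path(tempfile.mkdtemp())
fx = borderland_fixture(work / "fixture")
result = run_pipeline(RunConfig(
    cohort_vcfs=fx.patient_vcfs, control_vcfs=fx.control_vcfs,
    population_af=fx.population_af, mutation_census=fx.mutation_census,
    clinical_levels=fx.clinical_levels, pathways=fx.pathways,
    metadata=fx.metadata, out_dir=work / "out",
    groups=[("KRAS", 12)], stratify_by="status",
))
print(result.trace.as_dict())
freq = result.frequencies
print(freq[freq["stratum"] == "all"].head(3).to_string(index=False))
```

prints

```
{'restrict_coding': {'n_in': 17, 'n_removed': 1, 'n_out': 16},
 'subtract_controls': {'n_in': 16, 'n_removed': 1, 'n_out': 15},
 'filter_population_af': {'n_in': 15, 'n_removed': 1, 'n_out': 14}}
        key stratum  n_carriers  n_total  percent
 ATM E2366*     all           1        9  11.1111
DECOYEQ G9R     all           9        9 100.0000
 DNMT3A A1G     all           1        9  11.1111
```

The trace shows each cascade stage removing exactly one decoy (a
non-coding variant, an allele shared with controls, an allele at 20%
population frequency) while an allele at exactly 5% survives the
strict threshold. In `result.frequencies`, NOTCH2 C19W is carried by
5 of 9 patients, and KRAS G12A and STAT5B N642H by 1 of 9 each;
`result.level_report` groups the classified variants by clinical level
(Level 1: ROS1, ATM, KRAS; Level 2: DNMT3A, TET2, WT1; Level 3:
STAT5B, SUZ12, PTEN, NOTCH2, SOCS1) with their tiers and
new-onset/relapse carrier splits.

The same pipeline is scriptable from the shell:

```sh
triage fixture --out-dir fx
triage run --config fx/config.yaml      # or filter/classify/summarize/ancestry stepwise
```

Carrier counts from an external cohort (e.g. a dbGaP
controlled-access dataset) can be compared stratum-against-stratum via
`alltriage.cohort_stats.load_external_frequencies` and
`compare_strata`; no external genotype data ships with the package.

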