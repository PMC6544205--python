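# ukbkit

Biobank-scale phenotype extracts arrive as an awkward trio of files: a
tab-delimited data table whose columns are named by numeric showcase field
codes (`f.21001.0.0`), a script that maps stored integer codes to category
labels, and an HTML data dictionary that has to be cross-referenced by hand
before any column can be interpreted. **ukbkit** is a Python library and
command-line tool for epidemiologists and statistical geneticists working
with UK-Biobank-style filesets: it assembles the trio into a single
analysis-ready `pandas` dataset with descriptive snake_case column names
(`body_mass_index_bmi_f21001_0_0`) and labelled categories, and layers on
top of it

- **demographic context summaries** — cross-tabulate any subset of
  participants against the rest over the primary demographic variables
  (sex, age, ethnic background, deprivation, assessment centre, BMI), as
  tidy count tables and a multi-panel bar figure;
- **ICD diagnosis queries** — code and keyword lookup against bundled
  ICD-9/ICD-10 reference tables, per-individual diagnosis retrieval,
  dataset prevalence, and diagnosis frequency stratified by a reference
  variable (continuous references are split into *N* = 10 approximately
  equal-sized rank groups);
- **genetic-metadata utilities** — column names for the headerless
  sample-QC file, relatedness counts by KING kinship degree
  (duplicate/MZ > 0.3536 ≥ 1st > 0.1768 ≥ 2nd > 0.0884 ≥ 3rd > 0.0442),
  phenotype-aware selection of a maximal unrelated subset, and
  PLINK/BGENIE phenotype, covariate and exclusion file writers;
- **synthetic fixtures** — seeded generators for filesets, KING-style
  kinship pair files, sample-QC/fam/sample sidecars with known ground
  truth, so every operation is testable without access to real data.

The unrelated-subset selection treats pairs above a kinship cutoff
(default 0.0884, the 3rd-degree boundary) as edges of a relatedness graph
restricted to phenotyped individuals; the removal set is a vertex cover of
that graph, built greedily by repeatedly deleting the most-connected
individual (deterministic lexicographic tie-break), so the retained set
contains no pair above the cutoff and no individual is removed without
covering at least one remaining pair.

## Worked example

```python
import ukbkit
from ukbkit.fixtures import default_fileset_spec, generate_fileset

# a 500-participant synthetic fileset (12 variables, 3 data codings)
spec = default_fileset_spec(500, seed=42)
generate_fileset(spec, "demo/")

ds = ukbkit.build_dataset("ukbsynth", "demo/")
print(ds.df[["eid", "sex_f31_0_0",
             "body_mass_index_bmi_f21001_0_0"]].head(3))
```

```
    eid sex_f31_0_0  body_mass_index_bmi_f21001_0_0
1000001      Female                         24.8102
1000002        Male                         26.5511
1000003        Male                         27.8358
```

The stored sex codes 0/1 have been replaced by their labels and the BMI
column carries its descriptive name with the `_f21001_0_0`
(field/instance/array) suffix. Reference queries:

```python
ukbkit.icd_code_meaning("I74")
# 'Arterial embolism and thrombosis'
ukbkit.icd_chapter_of("I74")
# ICDChapter(version='icd10', chapter=9, block_start='I00',
#            block_end='I99', description='Diseases of the circulatory system')
ukbkit.icd_prevalence(ds, "^(I2[0-5])")
# 0.184
```

so 18.4 % of the 500 synthetic participants carry at least one code in
I20–I25 (the generator draws diagnosis codes uniformly from the bundled
demonstration table — real cohorts are far less diseased). Stratified
frequency with the default WHO 2015 top-3 cause-of-death patterns:

```python
ukbkit.icd_freq_by(ds, "sex_f31_0_0")
```

```
group_label  group_n                     pattern_label  frequency
     Female      243           coronary artery disease     0.2346
     Female      243           cerebrovascular disease     0.1975
     Female      243 lower respiratory tract infection     0.2757
       Male      231           coronary artery disease     0.1472
       Male      231           cerebrovascular disease     0.1429
       Male      231 lower respiratory tract infection     0.3420
```

Each frequency is the fraction of that group's individuals with at least
one matching code; `group_n` counts participants non-missing on the
reference variable (243 + 231 < 500 because the generator injects 5 %
missingness).

The same operations are available from the shell:

```sh
ukbkit convert --stem ukbsynth --path demo/ --out ukb.tsv
ukbkit icd meaning --code I74
ukbkit gen prune --kinship rel.txt --phenotyped ids.txt --out remove.txt
```

## Bundled reference data

Both ICD chapter tables are complete. The code-level tables are a
demonstration subset (~140 codes spanning every chapter and the default
disease patterns); pass a full `code<TAB>description` TSV to
`ukbkit.icd.load_codes(version, path)` for production use. The sample-QC
schema is a versioned default (68 columns) that can be overridden with a
one-name-per-line file when the distributed layout changes.

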