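# Methods

## Fileset model

A phenotype fileset is three files sharing a stem. The `.tab` table is
tab-delimited with a `f.eid` identifier column and one column
`f.<field>.<instance>.<array>` per variable slot, where *field* is the
showcase field code, *instance* the assessment occasion and *array* the
response slot; missing values are the literal token `NA` (configurable).
The `.html` data dictionary is an HTML table whose header row contains
UDI, Count, Type and Description; UDIs have the form
`<field>-<instance>.<array>` and the `eid` row is an identifier, not a
variable. The `.r` file assigns categorical level/label vectors to
columns.

Column names are derived by *contraction*: the description is lower-cased,
every maximal run of non-alphanumeric characters (including non-ASCII
bytes) becomes one underscore, leading/trailing underscores are stripped,
and the addressing suffix `_f<field>_<instance>_<array>` is appended.
Contraction is idempotent on its own stem, and names cannot collide within
a fileset because the suffix triple is unique. A description that is empty
after stripping is an error naming the field.

### The coding-script dialect

No grammar for the `.r` file is published, and executing a script shipped
inside a data bundle is unsafe, so the parser is a textual tokenizer that
recognises exactly two constructs: paired vector declarations
`lvl.<id> <- c(...)` / `lbl.<id> <- c(...)` (vectors may span lines;
quoted strings may contain commas and backslash-escaped quotes) and
one-line column assignments that mention `$f.<field>.<i>.<a>` on the
left of `<-` and `lvl.<id>` on the right. Level/label length mismatches
and references to undeclared codings are integrity errors. Raw level
values are kept in string form and matched against the `.tab` values
textually, which sidesteps 0-vs-0.0 representation questions.

### Assembly semantics

`read_tab` streams the table in chunks (default 10,000 rows) and is
chunk-size invariant because all values are read as strings and typed
once at the end: integer → nullable `Int64`, continuous → `float64`,
date → datetime, everything else → `string`. Header columns without a
dictionary entry are retained as text with a warning; a missing `f.eid`
column or duplicate eids are fatal. `build_dataset` composes the three
parsers, renames columns, and maps coded values through their coding;
values absent from a coding are kept unchanged with a warning rather than
nulled, since silently destroying data in a QC tool is worse than passing
an unrecognised code through. Negative or otherwise unusual eids (e.g.
withdrawn participants in real extracts) pass through unmodified;
filtering is the analyst's decision. `merge_filesets` is a full outer
join on eid; on a column-name collision the first occurrence wins and
later ones are suffixed with their provenance stem.

## Demographic context

`demographic_summary` takes a per-row boolean indicator (TRUE = subset of
interest, FALSE = reference; missing indicator rows are excluded from
both groups and counted). Default variables are the instance-0 columns of
field codes 31, 21022, 21000, 189, 6142, 54 and 21001 when present — the
classic baseline demographics — chosen by suffix match so the defaults
survive renaming; any explicit list overrides them. Later instances are
deliberately ignored by default (recorded in the summary metadata).
Numeric variables are binned on shared equal-width edges over the pooled
non-missing range (default 20 bins) so subset and reference histograms
are directly comparable; categorical variables are cross-tabulated over
observed levels, retaining levels present in only one group. For every
variable, `n_subset + n_reference + missing` equals the dataset row
count. `render_context` returns the drawn numbers alongside the figure;
`fill` mode plots `n_subset / (n_subset + n_reference)` per level,
`stack` and `side_by_side` plot counts.

## ICD reference and queries

Codes are stored and matched undotted (`I251`, not `I25.1`), matching how
hospital-episode fields store them; patterns are ordinary regular
expressions, so prefix queries anchor with `^`. The default stratified-
frequency patterns are the WHO 2015 top-3 causes of death —
`^(I2[0-5])`, `^(I6[0-9])`, `^(J09|J1[0-9]|J2[0-2]|P23|U04)` — written
with ASCII hyphens (en-dash ranges are not valid regex character
classes). Diagnosis columns are discovered by the revision tag in the
contracted column name (`icd10` / `icd9`), overridable by an explicit
list. Prevalence uses all individuals in the dataset as denominator, not
only those with hospital records, and counts each individual once however
many codes match; individuals are deduplicated by eid.

Chapter resolution orders codes by (letter prefix, leading numeric part):
ICD-10 uses the first letter and first two digits, ICD-9 the optional
E/V prefix and leading digits. Blocks are inclusive on both ends. Both
chapter tables are bundled in full; code tables are a demonstration
subset covering every chapter and all codes used in the examples, with a
loader for a user-supplied full TSV — the complete corpora are not
redistributed.

`quantile_groups` assigns rank groups whose sizes differ by at most one
(larger groups first), with ties broken by stable original order so the
assignment is deterministic; missing values get no group, and labels
carry the spanned value range. It requires at least `n_groups`
non-missing values.

## Relatedness and pruning

Degree categories use the standard KING powers-of-two kinship bins,
inclusive on the lower bound: > 0.3536 duplicate/MZ, (0.1768, 0.3536]
first, (0.0884, 0.1768] second, (0.0442, 0.0884] third; the bounds are
configurable. `rel_count` optionally restricts to pairs with both members
in a given id set and also returns the (IBS0, kinship) scatter data —
the numbers behind the usual relatedness plot — rather than promising a
particular styling.

`samples_to_remove` builds a graph over phenotyped individuals with an
edge for every pair with kinship strictly above the cutoff (default
0.0884) and both members phenotyped, then repeatedly removes the node
with the most remaining edges until none remain. Ties are broken by the
lexicographically smallest id compared as strings — the only total
lexicographic order available when ids may be integers — making the
removal list fully deterministic. The greedy max-degree policy is a
heuristic: it guarantees a vertex cover (no retained pair above cutoff),
maximality of the retained set and no gratuitous removals, but not a
global minimum; tests compare it against brute-force minimum vertex
covers on structured families (star, path, disjoint pairs), where it is
exact, and bound it on random graphs of up to 12 nodes, the largest size
where subset enumeration stays cheap.

## File writers

PLINK phenotype/covariate files carry `FID IID` then the variables, one
row per individual present in the data, FID = IID = eid (the fam files of
this resource carry no family structure), missing token `NA`
(configurable, e.g. `-9`). Exclusion files are two columns FID IID.
BGENIE files have a header of variable names and exactly one row per
sample in the genotype sample order taken from a fam or Oxford sample
file — individuals absent from the data are emitted as all-missing — with
the fixed missing token `-999` required by that tool. Integer-valued
floats are written without a decimal point.

The Oxford sample reader demands the two-line header (names, then type
codes starting `0 0 0`) and types columns by their D/C/B/P codes; the fam
reader validates six columns per line and sex ∈ {0, 1, 2}, reporting the
offending line number.

## Synthetic fixtures

The generators emulate the file dialects with known ground truth:
`generate_fileset` emits a complete trio plus the expected assembled
dataset (names, labels, types, missingness); `generate_kinship` emits a
KING-style pair file from explicit edges or a random spec;
`generate_genetic_sidecars` emits a schema-conformant headerless
sample-QC table, fam and sample files agreeing on individual order. All
output is byte-identical under a fixed seed. The default fileset spec has
12 variables and 3 data codings — sex, ethnic background and assessment
centre as coded categoricals; BMI ~ N(27.4, 4.8²), age ~ U{40..69},
Townsend ~ N(0, 3²), height ~ N(168, 9²), waist ~ N(90, 13²), two
systolic-blood-pressure array slots ~ U{100..180}; two ICD-10 diagnosis
array slots drawing uniformly from the demonstration code table — with
5 % missingness per cell. These magnitudes are plausible for a baseline
assessment cohort, but the fixtures test plumbing, not biology: values
are independent across columns, diagnosis codes are uniform rather than
age- and sex-structured, and missingness is completely at random, so
passing tests certify the data handling, not epidemiological realism.

## Problem sizes and verification

The test suite and acceptance script use a 1000-individual fileset for
the round-trip check, 200 random relatedness graphs of up to 12 nodes
(where brute-force vertex-cover enumeration is feasible) plus the
structured families, 50 random 30-individual fixtures for the counting
oracles, and 20 random permutations for the BGENIE row-order contract —
sizes at which every oracle is exact and the whole surface runs in
seconds. All counting operations are verified against independent plain-
iteration scans, never against themselves.

## Known limitations

Decryption/unpacking of raw downloads, ICD-11/OPCS codes, date-of-
diagnosis logic, kinship estimation from genotypes and BGEN/BED payload
reading are out of scope. The bundled code tables are demonstration
subsets; production keyword searches need a user-supplied full table.
The sample-QC schema tracks the distributed layout by version and must
be overridden explicitly if the column count changes. The greedy pruning
can exceed the minimum removal count on adversarial graphs (bounded by
the usual greedy vertex-cover guarantees); analyses needing certified
minimal removals should solve the cover exactly.
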