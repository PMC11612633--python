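# Methods

## Biomarker catalog

The catalog is a flat table of gene–syndrome–subtype validity assertions,
stored as UTF-8 TSV (comma-delimited files are also accepted) with columns
`gene_symbol, syndrome, subtype, category, moi, classification, description,
transcripts, report_url`. The `transcripts` field is `|`-separated. The
triple (gene_symbol, syndrome, subtype) is the uniqueness key; a load that
violates it fails listing the offending rows, so a malformed catalog can
never silently shadow an assertion.

Conventions:

* Gene symbols are uppercased on load, and all downstream matching (DE
  tables, VCF annotation, panels) is case-insensitive. DE exports and VCF
  INFO tags are inconsistent about symbol case in practice.
* A gene curated for every subtype of a syndrome is stored once with the
  sentinel subtype `all`, not duplicated per subtype. This preserves the
  single provenance of the assertion; subtype queries add sentinel records
  to their result.
* Subtype labels of the form `type N` sort natural-numerically
  (`type 2 < type 10`), matching how the subtypes are named clinically.

### Shipped mini-catalog

`fixtures.build_catalog_fixture()` carries the curated facts used throughout
the tests: ten ALS gene–subtype assignments (SOD1 and C9ORF72 → type 1,
TBK1 → type 4, FUS → type 6, TARDBP → type 10, FIG4 → type 11,
ERBB4 → type 19, TUBA4A → type 22, KIF5A → type 25, DAO → all subtypes),
twelve neurological syndrome labels and seven non-neurological disease
labels. The two counts of neurological syndromes in circulation (eleven vs
the twelve enumerated labels) disagree; the fixture carries the twelve
enumerated labels and does not attempt to resolve the discrepancy.
Similarly, ALS is variously described as having 16 or 26 subtypes; only the
eight subtype labels above are documented, so only those are catalogued.
Non-ALS syndromes have no documented gene assignments here, so each carries
a single clearly synthetic placeholder record (`PANELGENE*`,
classification `placeholder`) whose only purpose is to make the syndrome
label queryable; the ALS records use `moi = unknown` and
`classification = curated` because neither field's true value is documented
for them.

## Expression classification

The tool consumes a *precomputed* DE table; it never computes fold changes
or p-values (those come from an upstream DESeq2/edgeR-style analysis). The
classification of one gene under thresholds (padj_max, lfc_min) is:

* **UP**: padj present, padj < padj_max, log₂FC ≥ lfc_min
* **DOWN**: padj present, padj < padj_max, log₂FC ≤ −lfc_min
* **NOT_SIGNIFICANT**: otherwise, including any missing/NA padj

Numerical choices:

* The fold-change boundary is **inclusive** (|log₂FC| = lfc_min counts as
  DE) and the p-value boundary is **strict** (padj = padj_max does not).
  "Fold change of at least X" is inherently ambiguous; this reading is
  declared here, enforced in one function (`classify_expression`), and
  covered by boundary tests, rather than being silently embedded in a
  filter expression.
* Defaults are padj_max = 0.01 and lfc_min = 2.0 — deliberately
  conservative screening thresholds for biomarker panels; both are plain
  CLI flags.
* Missing/NA padj (routine for low-count genes filtered by the upstream
  test) classifies as NOT_SIGNIFICANT with a logged count, never an error.
* Duplicate gene symbols in the input keep the first occurrence; the count
  dropped is logged, keeping the run deterministic and auditable.
* For the volcano y-axis, padj is floored at 1e−300 before −log₁₀, so a
  reported padj of exactly 0 still plots at a finite height (y = 300).

The panel summary lists every panel gene, flagging genes absent from the
input (`in_input = False`) instead of dropping them — an absent biomarker is
a finding, not noise. A `--significant-only` flag restricts the table to
UP/DOWN rows.

## Variant comparison

Input is a directory with `controls/` and `patients/` subfolders of VCF
v4.2+ files (plain or bgzipped), parsed with cyvcf2. Conventions:

* Multi-allelic records are split into biallelic (chrom, pos, ref, alt)
  variants. Allele representation is taken as written — no left-alignment
  or normalisation pass is applied, so the same indel written two ways
  counts as two sites. This is a documented limitation; inputs coming from
  a single caller are internally consistent.
* Classes: **SNP** = both alleles single bases in {A,C,G,T}; **INDEL** =
  plain-sequence alleles of unequal length; **OTHER** = everything else
  (equal-length multi-base substitutions, N-containing single-base pairs,
  symbolic `<...>` alleles, breakends, spanning deletions). Only the SNP
  and INDEL views are exposed as tables; OTHER is deliberately excluded
  from both.
* **Carriage**: a sample carries a variant when its genotype contains ≥ 1
  copy of that ALT allele (het or hom); a half-missing genotype such as
  `./1` carries; a fully missing genotype (`./.`) counts toward the cohort
  total but never toward carriers. A sample whose VCF simply lacks a site
  is a non-carrier — the per-sample-VCF convention.
* Sample identity comes from VCF header sample columns; a sample name
  appearing in two files (or in both cohorts) is an error rather than a
  silent merge.
* **Gene assignment** is a coordinate lookup against user-supplied gene
  regions (BED4: chrom, start, end, gene). BED is 0-based half-open and is
  converted to 1-based inclusive intervals to match VCF positions. With
  nested or overlapping regions the smallest interval wins, then the
  lexicographically first symbol — a deterministic tie-break. When the
  VCFs are already annotated, `--gene-tag INFO_TAG` reads the symbol from
  that tag instead.
* The comparison table has one row per distinct (chrom, pos, ref, alt) of
  the requested class that falls in a panel gene and has ≥ 1 carrier in
  either cohort, ordered by (gene, chrom, pos, alt); identical variants
  seen in both cohorts are one row. `status` is `patient_only` /
  `control_only` / `shared` from the two carrier counts. The REF column is
  the reference-genome allele, which is how the three-way
  reference/controls/patients comparison is realised.

Out of scope by design: variant calling, genotype likelihoods, phasing,
consequence annotation, population frequencies, and association statistics
between the cohorts — the table reports counts, not tests.

## Synthetic fixtures

The generators exist so that every stage has an exact, machine-readable
oracle (`FixtureManifest`): planted catalog facts, planted DE rows with
their expected class, and planted variants with their exact carrier sets.
All generators are deterministic under a seed.

* **DE tables**: planted rows are written verbatim; background genes draw
  log₂FC ~ Normal(0, 0.5) and padj ~ Uniform(0.2, 1), so they can never be
  significant under any padj_max ≤ 0.2 — background can never contaminate
  a planted expectation. These distributions are invented test scaffolding,
  not a model of real DE output (real tables have correlated padj/log₂FC
  and heavy tails); passing tests demonstrate correct filtering logic, not
  statistical performance on real data.
* **VCF cohorts**: a toy 2-chromosome genome (chr1 1 Mb, chr2 0.8 Mb,
  declared as contigs so files validate in standard parsers) with
  single-sample VCFs. Planted variants get genotype `0/1` in exactly the
  named carriers; background SNPs are scattered at 2×10⁻⁵ per bp but only
  *outside* gene regions, so they exercise parsing and filtering without
  ever entering a comparison table. Every record in every generated VCF is
  listed in the manifest.
* **case-study-shape preset** (`neurovar simulate`): emulates the structure
  of a published ALS patients-vs-controls analysis — 3 controls, 4 patients,
  23 SNPs planted across the 7 SNP-bearing biomarker genes (4+4+4+3+3+3+2),
  zero indels, FUS/TARDBP/SOD1 regions left variant-free, and a 20 000-gene
  DE table in which exactly one of a 21-gene biomarker panel (TUBA4A,
  log₂FC 3.1, padj 0.004) is differentially expressed at thresholds
  (padj < 0.05, |log₂FC| ≥ 2). Only ten ALS biomarkers are documented by
  name, so the panel is padded to 21 with clearly synthetic symbols
  (`ALSBM11`–`ALSBM21`). Cohort sizes and per-gene SNP counts are the
  package's own choices: small enough to read by eye, shaped like the
  published analysis.

## Verification strategy

* Exhaustive enumeration for `classify_variant` (every REF/ALT pair up to
  length 3) and independent brute-force re-statements of the DE rule,
  checked property-based (hypothesis) including the boundary values.
* Structural properties: UP/DOWN/NS partition the table; relaxing
  thresholds is monotone; negating all fold changes swaps UP and DOWN;
  subtype panels are subsets of syndrome panels; SNP and INDEL views are
  disjoint; swapping the cohort directories transposes the table.
* End-to-end planted recovery: across 50 random seeds the comparison
  tables and DE call sets must equal the manifests exactly (2 controls /
  3 patients, 8 SNPs + 3 indels per fixture — sizes chosen to keep the
  whole suite around ten seconds while still drawing varied carrier
  patterns).

Passing fixtures demonstrate that the filtering, classification, counting
and I/O contracts are exact. They say nothing about upstream read
alignment, variant calling or DE testing, which this tool consumes but does
not perform.

## Reproducibility

Identical config + inputs give byte-identical TSV/JSON outputs (stable row
ordering everywhere); rendered images are exempt from the byte-level
contract. Each CLI stage writes a JSON sidecar recording inputs,
thresholds, package version and row counts.
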