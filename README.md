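# methylight

A toolkit for the computational side of bisulfite-PCR methylation assays:
in-silico bisulfite conversion, methylation-specific primer/probe
validation, clone-sequencing QC, MethyLight relative-copy-number
quantification, and ROC cutoff calibration.

## Who this is for

Labs running (or designing) methylation-specific PCR and MethyLight assays
for CpG-island biomarkers — the motivating case is methylated *p16*
(*CDKN2A*) as a progression marker for epithelial dysplasia — and anyone
who needs the arithmetic around such assays to be explicit, tested and
reproducible rather than spreadsheet folklore.

## The model

**Bisulfite conversion.** Treatment converts unmethylated cytosine to
uracil (thymine after PCR) while 5-methylcytosine is protected. Applied to
double-stranded DNA it yields two *non-complementary* single strands
(C≡G → U/T≠G), each with two idealised outcomes (all CpGs methylated /
none), so one genomic region has four possible templates. An assay must
commit to one strand and one methylation state; its CpG-derived bases are
what make it methylation-specific. The toolkit places published oligos on
all four templates, derives amplicon intervals in TSS-relative coordinates
(1-based, inclusive, no position 0), and renders a specificity verdict.

**Clone QC.** A sequenced clone of a bisulfite amplicon is scored
positionally against the unconverted reference: retained C at CpG sites
measures methylation; converted T at non-CpG sites measures bisulfite
efficiency. Sample-level percentages pool counts across clones.

**Quantification.** MethyLight Ct values are collapsed by replicate
averaging, turned into relative copy numbers RCN = 2^(−ΔCt) with
ΔCt = Ct(target) − Ct(reference gene), and standardized to a fully
methylated positive control. Batch controls are validated first: an
amplifying negative control voids the run.

**Diagnostics.** Standardized RCNs are calibrated against a binary gold
standard: full ROC curve, trapezoidal AUC (= Mann–Whitney probability,
ties half), Youden-index cutoff, and 2×2 association (odds ratio with
Woolf CI; chi-square or Fisher test). "Accuracy" is the Youden index,
sensitivity + specificity − 1.

## Worked example

The package ships the three published assay definitions (the 70-bp
antisense-strand and 115-bp sense-strand methylated-*p16* designs plus the
COL2A1 reference) and can synthesise a region realizing them, plus a full
synthetic cohort:

```sh
methylight simulate --seed 7 --outdir fixtures
methylight quantify --ct fixtures/ct.tsv --out rcn.tsv
methylight roc --rcn rcn.tsv --labels fixtures/labels.tsv \
               --out roc.tsv --summary summary.json
methylight clone-qc --clones fixtures/clones.fa \
                    --reference fixtures/region.fa --sample demo --out clones.json
```

prints

```
wrote region.fa, clones.fa, ct.tsv, labels.tsv to fixtures
quantified 104 samples -> rcn.tsv
AUC 1.000; Youden cutoff 0.2668 (sens 1.000, spec 1.000, accuracy 1.000)
demo: 16 clones, CpG retention 95.5%, non-CpG conversion 95.0% -> fully-methylated
```

The simulated cohort (44 gold-positive, 58 gold-negative samples plus RKO
and MGC803 controls) separates positives (RCN ≈ 0.7) from negatives
(RCN ≈ 0.02) by about 5 cycles of ΔCt, so the ROC is near-perfect and the
Youden cutoff lands between the two groups. The clone report pools
16 × (CpG and non-CpG) sites: retention ≈ the simulated 95% methylation,
conversion ≈ the simulated 95% efficiency, hence the fully-methylated call.

Checking the published designs against a synthetic region that embeds them:

```sh
python -c "from methylight.bisulfite_core import write_region
from methylight.synthetic_fixtures import demo_region
write_region(demo_region(seed=0), 'p16.fa')"
methylight design-check --region p16.fa --tss 60 --report design.tsv
```

```
p16-ML-70bp: methylation-specific amplicon=+301~+370
p16-ML-115bp: methylation-specific amplicon=+157~+272
COL2A1-reference: not-specific amplicon=not-placeable
```

Both methylated-*p16* assays hit only the methylated template of their
target strand, with every CpG-derived base mismatching the unmethylated
template. The 115-bp-named assay spans +157~+272 — 116 bp by inclusive
arithmetic; the report carries both the computed and the nominal length.
The COL2A1 assay targets a different gene, so on the *p16* region it is
correctly not placeable (on its own region, `reference_region()`, it is
methylation-neutral).

## Layout

| module | contents |
| --- | --- |
| `bisulfite_core` | conversion model, four templates, sequence primitives, FASTA I/O |
| `assay_design` | oligo parsing, placement, amplicon/TSS arithmetic, specificity reports |
| `clone_qc` | clone scoring, pooled sample reports, methylation calls |
| `methylight_quant` | Ct tables, 2^(−ΔCt) quantification, control validation |
| `diagnostics` | ROC/AUC, Youden cutoff, odds ratios, association tests |
| `synthetic_fixtures` | seeded generators for regions, clones and Ct tables |
| `cli` | `methylight` command with one subcommand per step |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
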