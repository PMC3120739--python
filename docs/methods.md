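# Methods

## Bisulfite conversion model

Conversion is idealised and deterministic: under the *unmethylated*
assumption every cytosine becomes thymine; under the *methylated*
assumption a cytosine is retained iff its next base is G (CpG context).
Both strands are converted independently — the antisense template is the
conversion of the reverse complement — which is what breaks strand
complementarity and forces every assay to commit to one strand. Converted
sequences are written with T rather than U, matching PCR products and
Sanger reads.

Choices at the edges:

* **Terminal cytosine.** A C at the last position of a region has unknown
  CpG context (its 3' neighbour lies outside the region). It is treated as
  non-CpG — converted — with a warning. This is conservative: it can turn
  a true CpG into an apparent conversion, but never invents methylation.
* **Ambiguity codes** (N, Y, R, …) are rejected with the offending
  position, not guessed. The templates this toolkit reasons about are
  fully resolved.
* Non-CpG methylation (CHG/CHH) and incomplete chemical conversion are
  not sequence-level phenomena here; stochastic conversion failure lives
  in the clone simulator only.

## Oligo annotation and placement

Oligos use the mixed-case publication dialect: lowercase for
conversion-invariant bases, uppercase C/G for CpG-derived discriminating
bases; an explicit index list is accepted for plain-case oligos.
Published annotations sometimes uppercase the G member of a CpG (the
complement of the template's cytosine, typical for reverse primers), so
discriminating positions are normalised in scan frame to the C of each
CpG — only the C differs between methylated and unmethylated templates.

Each oligo is searched on a template as a gap-free scan: forward primers
and probes as printed, reverse primers as reverse complement. An
`opposite` flag covers oligos printed for the other face of the amplicon
(TaqMan probes may bind either strand; a printed oligo containing
lowercase `c` that could not survive conversion on the assayed strand is
the tell-tale). The default mismatch tolerance for a "hit" is 0; best
hits at any mismatch count are always reported so near-specific designs
remain visible.

**Specificity verdict.** An assay is *methylation-specific* iff all three
oligos match the methylated target-strand template exactly and, at those
same positions, every discriminating base mismatches the unmethylated
template. A zero-discrimination assay with identical placement on both
templates is *methylation-neutral* (expected for the reference assay);
anything else is *not-specific*.

## Coordinates

TSS-relative, 1-based, inclusive at both ends, with no position 0 (+1 is
the first transcribed base, −1 immediately upstream). Interval length
and overlap collapse the missing zero, so a span crossing the TSS loses
one relative to naive subtraction, and (+238, +307) is exactly 70 bp.
Amplicon intervals run 5'-end to 5'-end of the two primers (the standard
qPCR convention). When a computed length disagrees with an assay's
published name — the "115-bp" design computes to 116 bp from its printed
(+157, +272) coordinates — both numbers are reported; the discrepancy is
not silently resolved in either direction. Cross-strand overlap is
computed on genomic coordinates only; heteroduplexes are not modelled.

## Clone QC

Scoring is positional and gap-free; a clone whose length differs from the
reference is rejected rather than mis-scored (the intended inputs are
fixed-length amplicon inserts — no indel alignment in this version). At
reference CpG cytosines, clone C counts as retained and T as converted;
at non-CpG cytosines, T counts as converted and C as a conversion
failure. Any other base at a cytosine position is tallied separately
(`other_at_cpg` / `other_at_noncpg`) and enters neither numerator —
how such bases should enter the denominators is genuinely ambiguous, so
they are reported rather than absorbed.

Sample percentages are computed from **pooled counts** across clones (not
a mean of per-clone percentages) and rounded half-up to one decimal; this
is the arithmetic that makes 223/224 → 99.6 and 548/704 → 77.8.

Calls: pooled CpG retention ≥ 90% → fully-methylated, ≤ 10% →
unmethylated, else partially-methylated. Samples below the conversion-
efficiency QC floor (default 70% non-CpG conversion) are *flagged, not
excluded*: clone sets with conversion in the high 70s remain
interpretable when CpG retention is near-total, and silently dropping
them would bias toward clean chemistry. All three thresholds are
configurable.

## Quantification

RCN = E^(−ΔCt) with ΔCt = Ct(target) − Ct(reference) and amplification
efficiency E defaulting to 2.0 (the pure comparative-Ct model; no
efficiency correction is applied by default, but E is a parameter).
Replicates are collapsed by averaging detected Ct values — deliberately
not by averaging RCNs, which is a different estimator. Not-detected is an
explicit state, never encoded as Ct 45; a not-detected target gives RCN 0
with a flag so downstream classification treats it as negative, while a
not-detected reference invalidates the sample. The cycle ceiling defaults
to 45 (the assays' thermal profile); replicate spreads above 1.5 cycles
are flagged as a toolkit-level warning (no published rule exists for
discordant duplicates, so the flag never rejects data).

Batch validation before any quantification: the run is rejected if the
negative control's methylation target amplifies more than 5 cycles below
the ceiling (contamination signature — the wet-lab UNG carry-over system
is represented solely by this check) or if the positive control fails to
amplify. Standardization divides each raw RCN by the positive control's
raw RCN, so the positive control reads exactly 1.0 in every valid batch.

## Diagnostics

Classification rule: score ≥ cutoff ⇒ test-positive (≥ rather than >
matters under ties and is stated everywhere it is used). The ROC contains
one point per distinct observed score plus both boundary points; interior
cutoffs are represented by midpoints between adjacent distinct scores — a
dataset-independent representation that reproduces the same confusion
matrix as thresholding at the upper score. AUC is the trapezoid over
(1 − specificity, sensitivity) with points ordered along the curve, which
equals the Mann–Whitney probability with ties counted half (asserted to
1e-12 against `scipy.stats.mannwhitneyu` in the tests).

The operating cutoff maximises the Youden index J = sensitivity +
specificity − 1 ("accuracy" throughout); ties break toward higher
specificity, then higher cutoff — the more conservative rule for a
biomarker where false positives trigger intervention.

2×2 association: OR = ad/bc with a Woolf log-normal 95% CI; a zero cell
triggers the Haldane–Anscombe 0.5 correction, flagged. Woolf is a toolkit
choice — published CIs for the motivating tables were produced by an
unstated method that Woolf arithmetic does not reproduce, so only OR
points are treated as reproducible. The association p-value uses
chi-square without continuity correction when the large-sample
approximation is trustworthy (all expected counts ≥ 5 and no empty
observed cell) and the two-sided Fisher exact test otherwise; the method
name is always returned with the p-value. All tests are two-sided.

## Synthetic data

What the generators emulate, and what they do not: they reproduce the
*statistical structure* of assay data — CpG-dense sequence, per-site
Bernoulli retention/conversion in clones, duplicate-well Ct values with a
methylation-dependent ΔCt shift — not sequencing error profiles, PCR
amplification curves, DNA degradation or inter-run drift. Tests passing
on these fixtures validate the arithmetic and the decision logic, not the
wet-lab robustness of any assay.

Defaults define one synthetic study and are not tuned per test:

| parameter | default | rationale |
| --- | --- | --- |
| n_pos / n_neg | 44 / 58 | the motivating cohort's gold-standard split (n = 102) |
| replicates | 2 | duplicate wells, averaged |
| ct_reference_mean | 28.0 cycles | mid-range qPCR signal for ~10 ng input |
| delta_ct_positive | 0.4 cycles | standardized RCN ≈ 0.76 for positives, matching the reported positive median (~0.78) |
| delta_ct_shift | 5.2 cycles | negatives at RCN ≈ 0.02, matching the reported negative median |
| ct_noise_sd | 0.5 cycles | typical duplicate-well scatter |
| max_cycles | 45 | assay thermal profile; later signals become not-detected |
| n_clones | 16 | published clone-set size |
| retention_prob / conversion_efficiency | 0.95 / 0.95 | heavily methylated sample with good chemistry |
| island_length / cpg_density | 500 bp / 0.10 | CpG-island-like density (~10× genome background) |

One integer seed drives everything through spawned, per-artifact RNG
streams (region / clones / Ct), so artifacts regenerate independently yet
reproducibly; identical spec + seed yields byte-identical files (floats
are written with fixed formatting).

The island generator plants every CpG deliberately (single-base fills
never create one), with the per-step CG probability q = d/(1−d) chosen so
the expected per-position CpG density is d; densities ≥ 0.5 are
geometrically infeasible and rejected. `island_with_c_counts` builds
references with an exact cytosine census (default 14 CpG + 44 non-CpG
cytosines per clone-length unit, the published clone layout) from
shuffled CG/CA/CT tokens. `clone_set_with_pooled_counts` places an exact
number of retention/conversion events uniformly over (clone, site) pairs,
for fixtures whose pooled counts — not just rates — are specified.

`build_assay_region` solves for an unconverted region realizing published
oligos: each scan character constrains the pre-conversion strand (A/G fix
the base; C forces a CpG; T allows original T or a converted non-CpG C,
resolved to T inside assay windows), constraints from both strands are
intersected per position, unconstrained positions are filled randomly,
and the result is verified by re-converting. The default `demo_region`
places the 115-bp sense assay at its published (+157, +272) coordinates;
the 70-bp antisense assay is placed downstream at (+301, +370) because on
a synthetic region the two assays' constraint sets collide over the bases
they share on the true genome (the true exon-1 sequence is published only
as a figure image, so a configurable synthetic region is shipped instead
of asserting it).

## Known limitations

* No indel-tolerant clone alignment; no read mapping — inputs are
  clone/amplicon sequences, not sequencer output.
* No thermodynamic primer scoring, primer-dimer prediction or genome-wide
  off-target search: the toolkit validates given designs, it does not
  design primers.
* No absolute quantification (standard curves) or fluorescence-curve
  processing; Ct values are taken as given.
* Odds-ratio CIs are Woolf-only; exact or score intervals are out of
  scope.
* The unmethylated-specific (MSP-u style) primer set of the motivating
  study is not published and therefore not shipped.
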