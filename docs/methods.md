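# Methods

## The triage model

The pipeline operates on single alternate alleles carrying upstream
functional annotations (gene symbol, consequence term, compact
protein-change token). It assumes annotation is given and trustworthy:
consequence calling, transcript selection and protein-change
nomenclature are the annotator's responsibility, consumed from a
pipe-delimited INFO field (`ANN`, sub-fields
`gene|consequence|protein_change`, one entry per alt allele).
Multi-allelic records are split on read; phased and unphased genotypes
are treated identically; a half-called genotype contributes its known
alleles. When an annotator emits more entries than alt alleles, the
first per-allele entry is kept and alternates are logged.

### Filter cascade

Three predicates applied in order, each with an audited in/removed/out
count:

1. **Coding restriction.** The default coding set is missense,
   stop gain/loss, start loss, in-frame indel, frameshift and splice
   acceptor/donor — amino-acid-changing classes plus the truncating
   classes that appear among clinically relevant leukemia variants.
   Unannotated variants fail this stage.
2. **Control subtraction.** A cohort allele is removed if any healthy
   control carries it (dosage ≥ 1). No control-frequency threshold is
   applied: with 7 controls, a single carrier is already ≥ 7% of the
   control sample, and the cascade's intent is to be liberal toward
   rare germline variants, not to model control error rates.
3. **Population-frequency filter.** An allele is removed if its
   catalogue frequency in the configured population (default `LAT`,
   Latino/Admixed American) is *strictly* above the threshold
   (default 0.05, i.e. "more than 5%"); equality survives, and alleles
   absent from the catalogue are kept. Absence-means-rare is a
   deliberate bias: a filter that dropped uncatalogued alleles would
   discard exactly the rare variants the cascade exists to find.

Matching is allele-level (`chrom, pos, ref, alt`) by default. Because
frequency databases are allelic while "position" wording is common in
study descriptions, a `match_mode="position"` option removes a variant
when *any* allele at the site matches (controls: any control-carried
allele at the site; frequencies: the site's most common catalogued
allele). The two non-coding-stage predicates are independent, so the
cascade is order-independent across stages 2 and 3, monotone, and
idempotent — all three are property-tested.

### Tier rules

The three census evidence factors are booleans per catalogued change.
The rule set — Tier 1 = factors 1∧2; Tier 2 = any other pair; Tier 3 =
exactly one; Other = none — overlaps textually ("any two" includes
1∧2); precedence resolves it: the Tier 1 rule is checked first, so a
change meeting factors 1 and 2 is never Tier 2 regardless of factor 3.
This is the only reading under which both rules are simultaneously
satisfiable, and it makes the map total over all 8 combinations
(exhaustively tested) and monotone: adding a factor never weakens the
rank.

Tier X is position-level: a change qualifies when its residue position
holds at least one Tier 1–3 census record while the change itself has
no exact census entry, has an exact entry labeled "other", or is a
frameshift (frameshifts never match exact substitution entries but can
match by position). Positions whose only census entries are themselves
"other"-ranked do not confer Tier X. A reference-residue conflict
between query and catalogue at the same position (e.g. isoform
numbering drift) is logged and demoted to a position match rather than
trusted as exact. Changes with no exact or position evidence are
Unranked.

Clinical levels collapse the diagnostic/prognostic/therapeutic
categories to a single 1–4 scale by taking the minimum (strongest)
level across categories, reporting which categories attain it;
drug-resistance sub-levels are out of scope. Pathway mapping is plain
membership lookup; a gene may belong to several pathways.

### Cohort statistics

Frequencies are carrier frequencies (individuals with dosage ≥ 1), not
allele frequencies — small-cohort reporting counts patients. The
carrier matrix takes its sample list from the metadata sheet, so
patients with no surviving variant contribute all-false rows and every
denominator is the full cohort. Residue-level aggregation ("G12X")
unions all changes at a (gene, position), including nonsense and
frameshift changes at that position. Strata comparisons return the
fold ratio of percentages plus the raw 2×2 counts; a zero denominator
is flagged undefined rather than raised, and no hypothesis test is
attached — with cohort denominators of 9 the percentages are
descriptive, and the 2×2 counts are exposed for users who want an
exact test externally. Counts for an external comparison cohort are
accepted only as a user-supplied table (`load_external_frequencies`):
the relevant consortium dataset is controlled-access and cannot be
redistributed.

### Ancestry

The genetic distance is d = 1 − IBS on dosage vectors, IBS being the
mean over pairwise-complete loci of (2 − |g_i − g_j|)/2 — the
conventional choice for genotype MDS; Euclidean distance on
standardized dosages would serve equally and the distance function is
the single place to swap it. Missing genotypes are handled by
pairwise-complete averaging, not imputation; a sample pair with no
shared typed locus is an error rather than a guess.

Classical (Torgerson) MDS double-centers the squared distances
(B = −½ J D² J), eigendecomposes B, and scales the top-k eigenvectors
by √eigenvalue. Negative eigenvalues — possible because 1 − IBS need
not be Euclidean — are truncated at zero with a warning. Column signs
follow a fixed convention (largest-magnitude loading positive) so
repeated runs are identical; the embedding is otherwise defined only
up to rigid motion, which the tests respect by comparing through
Procrustes alignment. Population assignment is nearest reference
centroid in the first two dimensions (k configurable); exact ties
break lexicographically by label and are flagged ambiguous. The
implementation is cross-checked in the tests against an independent
principal-coordinates routine from scikit-bio.

## Synthetic data: what it emulates, what it does not

The random cohort generator emulates the *logical* structure of a
small exome cohort after annotation: per-sample VCFs, planted
clinically relevant variants private to named patients, and background
coding variants that are shared with controls and/or common in the
reference population with configurable probabilities (defaults 0.3 /
0.3, giving each cascade stage real work on roughly a third of the
background). Each variant's expected fate is recorded in a truth
table, so cascade correctness is testable as exact set equality. The
reference-panel generator draws dosages Binomial(2, f) per locus with
population frequencies either explicit or offset ±d/2 around a shared
base (uniform on [0.3, 0.7]) so that two divergent populations sit a
frequency gap of d apart; the default study condition for assignment
tests is d = 0.5 over 500 loci with 50 + 50 reference and 20 query
samples.

Not emulated: linkage disequilibrium, sequencing or genotyping error,
allele-frequency spectra, admixed individuals, indel representation
quirks, or transcript-dependent annotation ambiguity. Passing tests
therefore demonstrate the correctness of the filtering/classification
logic and the MDS machinery under clean inputs, not robustness of
variant calling or ancestry inference on real exomes — real panels
with subtle structure will separate far less cleanly than a 0.5
frequency gap.

The packaged cohort fixture encodes the published 9-patient borderland
ALL description: per-patient variant assignments, the Table-1 sample
sheet (4 new-onset, 5 relapse, all Hispanic), catalogue snapshots
reproducing the published tier/level/pathway calls, and four decoy
variants exercising each cascade stage plus the 5% boundary. Patient 6
carries no reported variant and is deliberately present with an empty
record set so denominators stay at 9. Three reconstructions are
flagged in the fixture manifest: the exact amino-acid changes for
DNMT3A, TET2, SUZ12 and PTEN are not printed in the source text, so a
clearly synthetic placeholder (`A1G`, with a Tier 3 census entry at
the same residue to force the published Tier X call) stands in and is
excluded from exact-change assertions; the ATM truncation is encoded
as E2366\*; and census factor combinations are chosen to be consistent
with each published tier, since the underlying factor values are not
printed.

## Numerical and design choices

- Synthetic genomic coordinates are a stable hash of (gene, change):
  one pseudo-contig per gene, position = 3·residue − 2. Stability
  across processes matters (VCFs and catalogues must agree), hence
  MD5, not Python's salted `hash`.
- Generated VCFs are emitted as text with fixed formatting and no
  timestamps, so identical seeds give byte-identical files; all VCFs
  are read back through pysam/htslib.
- Pipeline outputs are written atomically (temp file + rename) and the
  run manifest records config and catalogue SHA-256 digests plus
  per-stage counts; reruns on identical inputs are byte-identical.
- Duplicate catalogue keys are load errors, not last-wins: silent
  overrides in an evidence table are worse than a failed load.
- Tolerances: MDS configuration recovery is asserted to Procrustes
  disparity < 1e-8; the scikit-bio cross-check to 1e-8; assignment
  accuracy ≥ 95% at the stated simulation settings; all discrete
  counts exactly.
- Problem sizes in the test and acceptance paths (500 background
  variants, 500 loci, 100 reference samples, 1,000 random cohorts of
  12 variants for the cascade properties) keep the whole suite in the
  tens of seconds while leaving each stage non-trivially exercised.

## Known limitations

- Tier matching keys on (gene, residue, alt); transcript isoform
  differences between annotator and census are detected only via the
  reference-residue conflict warning.
- The control subtraction has no allele-frequency semantics within
  controls; one control carrier removes a variant.
- Position-mode frequency filtering summarizes a site by its most
  common catalogued allele, which is a coarse stand-in for true
  site-level frequency.
- Somatic/germline status is never inferred; the cascade's output is
  a mixture by design.
- Carrier-frequency comparisons are descriptive; no multiple-testing
  or small-sample inference is provided.
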