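# Methods

## Scope and data model

The package starts from identified-peptide tables (TSV; one row per
N-terminal peptide with sequence, protein accession, 1-based start
position, α-amine modification and two log2 SILAC ratios) and protein
databases (FASTA). Mass-spectrum processing and search-engine scoring are
upstream of this pipeline and out of scope. Coordinates are 1-based and
inclusive throughout, numbering residues from the initiator Met. Missing
ratios are explicit (empty TSV cell / `None`), never coerced to 0; peptides
lacking a ratio are triaged normally but excluded from null fitting and
reported as *unclassifiable* rather than silently called bystander.
Modification tokens are exactly `acetyl`, `d3-acetyl`, `free`; anything
else is a hard parse error, and `free` is rejected at triage because the
N-terminomics chemistry guarantees in-vitro trideuteroacetylation of every
free α-amine.

## Triage

Start position ∈ {1, 2} with an acetyl or trideuteroacetyl α-amine →
annotated protein start; position > 2 with trideuteroacetyl → proteolytic
neo-N-terminus; position > 2 with in-vivo acetyl → alternative translation
initiation. Percentages are rounded half-away-from-zero to integers, and
the raw fractions are always reported alongside, because rounded
percentages need not sum to 100 (e.g. 45/800 = 5.625% prints as 6%).
Peptides matching several database entries are all recorded; the reported
entry is the alphabetically first description (case-insensitive, ties
case-sensitive), the rest are listed as isoforms.

## Empirical null and efficiency classification

Each ratio axis of the annotated N-termini is summarised by a robust
normal. The estimator is Huber's joint location/scale M-estimation
(`statsmodels.robust.scale.Huber`) with tuning constant c = 1.345,
initialised at the median and the normalized MAD (×1.4826); both estimates
are consistent for (mean, sd) at the normal, and the location attains ~95%
normal efficiency. The choice of a Huber M-estimator over trimming is a
design decision: it is the standard resistant estimator for a sample
expected to contain a small fraction of genuinely shifted members (some
"annotated" termini may themselves be slowly degraded). If the MAD
degenerates to zero (majority-tied data) the scale falls back to the
sample sd of the central 90% with a warning.

All ratios are corrected by subtracting the fitted locations; the null is
refitted on the corrected annotated pairs for reporting (its locations are
then ~0 by construction) and classification runs against that corrected
null, which makes every call invariant to a global shift of either raw
axis.

The decision region is rectangular by default: efficient iff inside the
central two-sided interval μ ± z_{(1+coverage)/2}·σ on **both** axes,
boundaries inclusive, coverage 0.98. The source study describes one 98%
probability interval per axis but plots a 2-D acceptance area; because the
fit is two univariate normals, the rectangle is the direct reading, and an
elliptical alternative (χ²₂ quantile on the standardised squared distance,
joint coverage 0.98) is provided behind `region="ellipse"`. Ratios are
oriented later/earlier time point, so positive values mean accumulation;
reports record this orientation. No multiple-testing correction is applied:
the method is a fixed-coverage interval, not a per-site test.

## Cleavage-site annotation

The observed neo-N-terminal peptide starts at the P1′ residue; the site's
P1 is start − 1. Windows are P_n…P1 / P1′…P_n′ strings (default n = 10)
padded with `-` past either terminus; stripping the padding reproduces the
protein substring, which is property-tested. Tetrapeptide motif scanning
reports P1 at the motif's last residue and requires a bond C-terminal to
P1. Point mutations validate the observed residue before substituting and
name the position on mismatch, which catches off-by-one numbering errors;
mutation lists are invertible. Reference-compilation matching is exact on
(accession, P1).

Pairwise percent identity/similarity uses a global alignment
(Biopython `PairwiseAligner`, BLOSUM62, gap open −10, extend −0.5);
identity = identical columns / alignment length × 100, similarity
additionally counts substitutions with positive BLOSUM62 score. The
denominator convention (full alignment length, gaps included) is a design
decision and is printed with every report; ±1 percentage point should be
allowed when comparing against figures computed with other alignment
defaults.

## Assay quantification

Hydrolysis extent is mean(product peaks)/(mean(product peaks) + precursor);
the arithmetic mean assumes the product fragments are equimolar and ignores
differential UV response (documented limitation). Densitometric percent
cleavage is 100·cleaved/(cleaved + precursor); whether a gel analysis uses
product-over-total-lane instead is assay-dependent, and both surfaces are
exposed. E50 (enzyme concentration at 50% cleavage) is estimated by linear
interpolation of fraction against log2 concentration between the bracketing
points — assumption-free and matched to serial 2-fold dilution designs —
with no extrapolation: a curve that never crosses 0.5 is an error. An
optional single-parameter saturating model f([E]) = 1 − 2^(−[E]/E50)
(f(E50) = ½ exactly) is fitted by least squares in log-E50 space; it is
also the generator used for synthetic progression curves. On noiseless
model curves the fit recovers E50 to 10⁻⁶ relative; under 2% additive
fraction noise on a 9-point dilution series the median recovery error is
~2% (individual replicates can reach ~12%, so fold-efficiency ratios from
single noisy curves carry ~5–10% uncertainty).

## Upstream-TIS proteoforms

Candidates are in-frame codons upstream of the annotated ATG (frame defined
by the dbTIS) whose codon belongs to a configurable start set, with no
in-frame stop strictly between candidate and dbTIS. The default set is the
nine single-substitution neighbours of ATG; observed starts two edits away
(e.g. TGG) are supported by passing an extended set, and every report names
the set used. The initiator codon of a non-AUG start is decoded as Met
(initiator-tRNA behaviour). Proteoform masses use average (not
monoisotopic) residue masses, since the kDa-scale deltas these predictions
are compared against are gel-apparent masses. Disruption mutants replace a
start codon with a deterministic lexicographically-first codon ≥ 2
substitutions from ATG, outside the start set and not a stop; knocking out
the dbTIS itself is guarded behind an explicit flag and re-annotates to the
next in-frame downstream ATG.

## Synthetic experiments

The generator emulates the study design: 541 stable annotated N-termini
(start 1–2, mixed acetyl/trideuteroacetyl) with ratio pairs drawn from
N(−0.003, 0.1451) and N(0.009, 0.1871); 9 fast (k ∈ [0.5, 5] min⁻¹) and 28
slow (k ∈ [0.001, 0.02] min⁻¹) substrates observed at 10/30/60 min, each
contributing a trideuteroacetylated neo-N-terminus whose expected ratios
follow the first-order model log2[(1 − e^{−k t_late})/(1 − e^{−k t_early})]
plus the per-axis null mean (a deliberate global shift so the correction
step has real work to do) plus additive Gaussian noise with sd equal to
the null sds. Noise additive on the log2 scale is equivalent to
multiplicative lognormal noise on the raw intensity scale. Substrate
proteins carry the IEAD tetrapeptide planted so its last residue is the
P1 position. Config construction validates that the slowest-separating
bystander expectation on axis a is ≥ 5 noise-sd from the null mean, so
bystanders are essentially never missed. All randomness flows from one
integer seed through a single generator; identical config + seed gives
byte-identical output files.

What the generator does **not** emulate: missed cleavages, ratio
compression, arginine–proline conversion, peptide-level interference,
non-normal ratio tails, or any correlation between the two ratio axes.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to every artefact of real
LC-MS/MS data.

### Calibration of planted-class recovery

A planted *efficient* substrate has expected corrected ratios ≈ (0, 0) and
noise equal to the null sd, so its ratio pair is distributed exactly like a
null draw and lands inside the joint rectangular region with probability
0.98² = 0.9604 (the axes are independent in the generator). Recovery of
all 9 planted efficient events in one experiment is therefore itself a
stochastic event with probability ≈ 0.9604⁹ ≈ 0.69; across 100 seeds about
69 ± 5 experiments show perfect 9/28 recovery, and the per-event efficient
recall converges to 0.9604. Bystanders sit ≥ 5 sd outside the interval on
axis a and are recovered essentially always. The test suite asserts the
per-event calibration and the one-sided bystander guarantee; perfect
per-experiment recovery at a ≥ 99% seed rate is mathematically
incompatible with noise equal to the null sd at 98% coverage.

## Problem sizes

Default test and analysis runs use the study-scale design (541 + 37 rows),
10⁶-draw Monte-Carlo calibration checks, 100-seed recovery sweeps, and
9-point dilution series; these sizes keep every estimator comfortably in
its asymptotic regime while completing in seconds.

## Known limitations

- The classifier assumes independent per-axis normals; correlated axes
  would make the rectangular region's joint coverage differ from
  coverage².
- E50 interpolation requires a monotone progression curve; noisy curves
  need monotone smoothing first (the analysis driver uses a running max).
- Percent identity depends on alignment parameters; only the documented
  BLOSUM62/−10/−0.5 convention is tested.
- The uTIS scan treats the transcript as given; splice variants and leader
  truncations must be supplied as separate records.
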