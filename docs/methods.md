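# Methods

## Library designs and enumeration

A library design is a 10-slot template; each slot carries the set of
residues the synthesis allows there. The phosphorylated position
("position 0") is the fifth residue and admits Ser and/or Thr; flanking
slots are labelled −4…−1 and +1…+5. Internally all positions are 0-based
slot indices; signed labels are the user-facing convention because every
readout is reported relative to the phosphosite.

The built-in presets are five designs: four N-terminal
libraries (`x1_1`…`x1_4`), each fixing Ala at one of −4…−1 and
randomizing the other three N-terminal slots over the 14-residue
alphabet A/E/F/G/H/K/L/P/Q/R/S/T/V/Y (Leu only, no Ile, to avoid
isobaric search ambiguity), followed by pS/pT and AAAAK; and one
C-terminal library randomizing +1…+3 over A/D/E/F/G/K/L/N/P/Q/R/S/T/V
with an AAAA N-terminus and Ala-Lys C-terminus. Each enumerates
14³ × 2 = 5,488 phosphopeptides; the N-terminal union is
(14⁴ − 13⁴) × 2 = 19,710 (all N-terminal 4-mers containing at least one
Ala, times two phospho residues), and adding the C-terminal library
contributes 5,488 − 2 (the two all-Ala forms are shared), 25,196 total.

Monoisotopic masses are residue-mass sums (pyteomics standard table)
plus water, plus HPO₃ (79.96633 Da) for a phospho form; comparisons use
a 1e-4 Da tolerance. Isokinetic mixtures are validated to sum to 100 %
(tolerance 1e-6) over exactly the design's randomized alphabet.
Reported percentages (e.g. the 7 % uniform-incorporation expectation of
a 14-residue slot) round half-up to integers.

## PLDMS simulator

The ground-truth model assigns each peptide a first-order rate
k = k₀ · exp(Σ_pos w(label, residue) + τ·1[pThr]); the conversion
probability after time t is p = 1 − exp(−t·k). `simulate_treatment`
solves for t by bisection so the pool-average conversion matches a
target fraction (default 0.40, the midpoint of the 30–50 % stopping
window used in the assay), then draws per-peptide Bernoulli outcomes.
First-order kinetics is the simplest mechanism consistent with a global
stopping rule; none of the analysis modules assume it.

`sample_pool` draws randomized slots i.i.d. from a validated
composition and the phospho residue 50/50 pS/pT. The experiment wrapper
collapses the sampled pool to unique sequences before treatment: a
synthesis produces each sequence in many copies, and the MS readout
resolves whether a sequence's dephosphorylated form appears, not the
fate of single molecules. Without this collapse, a sequence's apparent
conversion would be driven by its abundance (any-copy aggregation),
confounding composition with preference.

Emitted PSM tables contain the phospho form for intact species, the
non-phospho form for converted species in treated samples, and five
injected error classes: truncated 9-mers (rate 0.03), sequences mutated
outside the design alphabet (0.05), phosphate localized off the
synthesized slot (0.10 — deliberately the largest class, as
mislocalization dominates real search errors), non-phospho records in
the untreated reference (0.05), and within-alphabet mis-assignments
(0.01) that still match a theoretical sequence and are therefore
invisible to empirical classification — they are what bounds the
realized FDR after filtering. Scores are Gaussian, correct at 45 ± 8
and erroneous at 25 ± 8 on a Mascot-like scale; the resulting 5 %-FDR
cutoffs land near 30, comparable to real ion-score cutoffs. Detection
probability (0.95) and a residual phospho-form probability for
converted species (0.05) are free parameters of the simulation, not
claims about the data. All randomness flows from one seed through
deterministic per-stage substreams.

## Empirical PSM filtering

Classification precedence is length → sequence membership → phosphate
placement; a design-matching non-phospho record is correct in a treated
sample and wrong ("missing phospho") in the untreated reference. A
record failing its own design but matching another design of the union
is flagged cross-library and excluded from that library's FDR curve
rather than silently kept. FDR(s) = FP/(TP+FP) over records with score
≥ s at the distinct observed scores; the cutoff is the smallest score
with FDR ≤ α (default 0.05), inclusive at ties so the filter is
monotone in α. Curves and cutoffs are computed per (library, treatment)
pair. Counting uses records; unique-sequence counts are reported
alongside.

## Peptide-level preference statistics

The counting unit is the unique (sequence, phospho residue) pair — PSM
multiplicity reflects abundance, not conversion — with a PSM-weighted
mode available. A sequence is dephosphorylated in a treated sample iff
its non-phospho form was identified there.

The preference matrix divides each (position, residue) cell's
dephosphorylation rate by the average library rate, so 1 means no
preference; the n_total-weighted mean of cell rates at any position
equals the library rate identically. Per-cell Fisher tests compare the
cell against all other residues at the position (dephosphorylated vs
not), BH-adjusted across the grid. Only randomized slots enter the
grids; the S/T identity at position 0 is analyzed separately by the
two-sided pThr-vs-pSer Fisher test (default contrast: dephosphorylated
vs not; an untreated-background contrast is selectable).

The differential PP1c/PP2Ac matrix is the cell-wise ratio of
dephosphorylated counts, normalized by the grid median to absorb global
rate differences between the enzymes. The median is taken in log space:
identical to the plain median for an odd number of defined cells, the
geometric mean of the middle pair otherwise — this makes swapping the
two phosphatases an exact cell-wise reciprocal. Per-cell Fisher tests
use this residue vs the summed counts of all other residues at the
position, PP1 vs PP2; cells with normalized fold change > 1.2 (or
< 1/1.2) and BH-adjusted p < 0.01 are flagged. Charge-combination
tables bin sequences by the count (0, 1, ≥2) of a residue of interest
at −4…−1 and Fisher-test each class against the zero class.

GRAVY is the mean Kyte–Doolittle hydropathy index.

## Phosphoproteome generator

Defaults emulate the assay conditions: 92 % pSer / 7.5 % pThr / 0.5 %
pTyr; flanks drawn from average proteome residue frequencies with a
2 % chance of terminal padding ("_"); 85 % class I sites (localization
probability > 0.75, Beta-skewed toward 1); three TMT batches with one
channel each for untreated, PP1c- and PP2Ac-treated material (unused
channels of a 6-plex are not simulated). Base abundances are log-normal
(log2 mean 20, sd 2); batch shifts (sd 0.3 in log2) and channel noise
(sd 0.3) are additive in log2. Sensitivity patterns default to 30 %
both / 17 % PP1-only / 15 % PP2A-only; per-site sensitivity
probabilities are tilted on the logit scale by window content (defaults:
Arg at −3 +0.8 and Lys at −1 +0.5 for PP1c, Glu at −2 +0.5 for PP2Ac,
and +0.7 for a pThr center for both — the planted pThr preference).
Sensitive sites carry a log2 effect of −2 ± 0.4. Missingness follows a
logistic detection curve on log2 intensity (midpoint 17, scale 0.8),
i.e. left-censored MNAR — exactly the regime the down-shifted
imputation targets. Reverse and contaminant rows (1 % each) exercise
the nuisance filters.

What the generator does **not** emulate: peptide-to-site roll-up,
isobaric interference, correlated effects within proteins, and real
motif composition beyond the planted coefficients. Passing recovery
tests therefore demonstrate correctness of the inference chain under
this statistical structure, not performance on any particular real
dataset.

## Proteome inference chain

Preprocessing: drop reverse/contaminant rows; keep localization
probability strictly > 0.75; divide each row's channels by the row's
within-batch median intensity (the row-wise operation that removes
per-batch level while preserving the treated/untreated contrast); log2;
keep rows with ≥3 valid values in at least one condition group.
Imputation draws missing entries per column from
Normal(mean − 1.8·sd, (0.3·sd)²) of the column's observed values.

The differential test is SAM-style: d = Δmean / (pooled SE + s0) with
s0 = 0.1; the null distribution pools d over group-label permutations
(250 requested; for 3v3 all distinct splits are used). The identity
assignment and its complement reproduce the observed statistics exactly
and would impose an FDR floor of 2/n_perm (10 % for 3v3, making a 1 %
FDR unreachable); they are excluded from the null. For each candidate
threshold the estimated FDR is the mean permuted exceedance count over
the observed count, and q-values are monotonized (cumulative minimum
from the most extreme statistic) so significance sets are nested.
Setting s0 = 0 reproduces the classical two-sample t ranking.

Clustering: one-way ANOVA across the three conditions, BH at 1 % (the
level matching the pairwise tests; the clustering admits too many null
rows at 5 %), row z-transform, agglomerative clustering with Euclidean
distance. Ward linkage is the default: on z-profiles it separates the
both / PP1-only / PP2A-only response patterns cleanly, whereas average
linkage chains them into one dominant cluster; average and complete
remain selectable. The Perseus-style k-means pre-binning ("300
clusters, 10 iterations") is deliberately not reproduced.

Sensitivity classes use either the significance flag, a strict
log2 fold change < −1, or both. Positional fold-change matrices divide
each residue's relative abundance (count over total non-padding count
at the position, −5…+5) in the sensitive set by that in the insensitive
set; cells with raw counts < 25 in either set are masked. The direct
PP1c-vs-PP2Ac comparison divides the two fold changes and Fisher-tests
the sensitive-set counts per cell (residue vs rest of the position, PP1
vs PP2A), BH across cells, flagged at adjusted p < 0.01; the ambiguous
alternative construction (sensitive vs insensitive within one enzyme)
is available as the per-matrix cell tests. Frequency matrices are
per-position residue probabilities exported in a PSSM-compatible tab
layout.

Motif flags on an 11-mer window: RxxpS iff Arg at −3 (strict), plus the
count of Arg/Lys at −5…−1 as the relaxed basic-upstream variant.
Overlap reports count dissociated interactors, those with ≥1 regulated
p-site, the RxxpS and other-basic classes, with half-up integer
percentages.

## Imaging quantification

Background is the mean gray value of a user-chosen empty region,
subtracted and clipped at 0. Segmentation thresholds automatically
(Otsu) with a manual override — reproducibility over interactivity —
then median-filters (radius 2 px), fills holes, and separates touching
cells by watershed seeded at distance-transform maxima (replacing
manual seed correction deterministically). The periphery ring is the
cell mask minus its erosion with a 15 × 15 px square structuring
element (mirroring a 15-px minimum filter; a disk option exists — the
exact element shape used interactively is not recoverable, so it is
configurable). The enrichment factor
f = (m₂(t₁)/m₁(t₁)) / (m₂(t₀)/m₁(t₀)) is a ratio of within-frame
ratios, hence invariant to global illumination scaling; cells whose
eroded core is empty or whose denominators vanish are reported and
excluded. Group comparisons are pairwise two-sided rank-sum
(Mann–Whitney) tests with BH adjustment.

## Problem sizes and numerical choices

Recovery checks run at the scales where the statistics they probe are
informative: 100,000 sampled peptides (≈56,000 unique species over a
4-slot randomized test design) for peptide-level recovery, 20,000 sites
for proteome positional recovery, 3,000 sites for cluster-pattern
recovery, pooled 5 × 2,000-site null pipelines for FDR calibration, and
200 × 5,000-peptide null pools for Fisher-calibration (Kolmogorov–
Smirnov against U(0,1)). Monte Carlo envelopes are 3 binomial standard
errors. Bisection for the incubation time runs 200 halvings from an
adaptively grown bracket. Fisher tests with a zero margin report p = 1
and an undefined odds ratio rather than failing. BH adjustment is
step-up with NaN pass-through (masked cells carry no p-value).

## Known limitations

- The simulators share the package's own positional-effect formalism;
  recovery tests demonstrate internal consistency of the chain, and the
  spiked error models are stylized (Gaussian scores, independent error
  classes).
- The s0 permutation FDR with 3 + 3 samples rests on 18 informative
  splits; q-value resolution below ~1/18 per threshold comes only from
  pooling across rows.
- Sequence windows are treated as exact 11-mers; longer or alternative
  window conventions must be mapped before import.
- The imaging pipeline assumes a single channel and pre-aligned frame
  pairs.
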