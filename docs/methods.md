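# Methods

## Candidate extraction model

A gene's candidate 5′ UTR is the intergenic interval between it and its
upstream neighbor on the coding strand: for a plus-strand gene the region
between the previous gene's end and its own start; for a minus-strand gene
the region between its own end and the next gene's start, reverse-complemented.
Coordinates are stored 0-based half-open internally; all user-facing positions
(motif spans, restriction hits) are 1-based inclusive.

Filters never delete candidates — each adds a flag (`opposing_orientation`,
`overlap`, `too_short`, `too_long`, `no_transcript`, `restriction_site`) and
`surviving()` is the flag-free view. This makes attrition counts exactly
reproducible from the attrition table and keeps filters idempotent.

Decisions where the design was genuinely open:

- **Length bounds are inclusive**: the filter removes strictly below 60 bp and
  strictly above 170 bp, so 60 and 170 are retained.
- **Opposing orientation** means the candidate's upstream flanking gene lies on
  the opposite strand; in a divergent pair both genes' candidates (the same
  DNA read from either strand) are flagged.
- **Replicon ends**: on a linear replicon a gene with no upstream neighbor on
  its coding side (first plus-strand gene, last minus-strand gene) yields no
  candidate; `circular=True` wraps the region around the origin instead.
- **Restriction scanning is double-stranded** — type-IIS sites act in either
  orientation during Golden-Gate assembly — and reports every overlapping
  occurrence of GGTCTC (BsaI), CGTCTC (BsmBI), GAAGAC (BbsI) and their
  reverse complements.
- The transcriptome merge requires *presence* in the count table only; no
  minimum count is imposed (a zero-count gene passes, a missing one does not).

## Library design

Selection is a deterministic function of the survivor set: tranche 1 takes the
`tranche1_size` (350) shortest candidates with gene-id tiebreak; tranche 2
bins the remainder by `floor(log10(read count))` (counts in (0,1) bin at −1,
nonpositive counts are unbinnable and skipped) and takes the `per_decade`
(50) highest-count members per bin, bins in ascending order, without
backfilling under-filled bins; the concatenation is truncated at the cap
(500). Raising the cap therefore never removes a previously selected
candidate.

Inserts longer than 98 bp keep their 3′-most 98 bases (the end adjacent to
the start codon carries the RBS and core promoter-proximal signal). Each
oligo is `pad + left_flank + insert + right_flank` (pad configurable to the
3′ side): the pad is drawn base-by-base from a seeded generator and redrawn
(at most 100 times) whenever the assembled oligo contains a type-IIS site
touching the pad. Sites wholly inside the flanks are the intended cloning
sites and are kept. The shipped default flanks are documented placeholders
with correct BsaI geometry — one plus-strand site in the left flank, one
minus-strand site in the right, each with a 4-nt fusion overhang; real
entry-vector flanks are supplied through the config. Per-oligo pads come
from independent streams spawned from the library seed, so the library is
reproducible as a whole and per oligo.

## Fluorescence normalization and classification

The chain is: media-background subtraction per channel (FI), mCherry/GFP
ratio (RFU, using genomic GFP as a biomass proxy), phase timepointing on the
smoothed OD600, then the differential-activity ratio
RFU(t_mid-exponential)/RFU(t_stationary) classified with strict thresholds
(ratio < 0.7 stationary-biased, > 1.3 exponential-biased, bounds inclusive
to unbiased; both thresholds configurable).

Numerical choices:

- **Negative FI is retained, not clamped**, and flagged; clamping would bias
  ratios for weak promoters.
- **GFP positivity floor** ε = 1e−9 signal units: timepoints with FI(GFP) ≤ ε
  are masked (NaN) rather than divided through.
- **Phase RFU values are 3-sample windowed means** (NaN-aware) centered on the
  sample nearest the phase timepoint; window 1 gives a point estimate.
- **Phase detection**: t_mid-exponential is the time of maximum
  central-difference slope (`numpy.gradient`) of the smoothed OD;
  t_stationary is the earliest time attaining the maximum smoothed OD. The
  slope search is confined to times up to the stationary onset (first
  attainment of 95 % of the OD range). The restriction matters when noise
  scales with signal: absolute noise then peaks on the stationary plateau,
  where the true slope is zero, and an unrestricted argmax over
  slope-of-noise can jump to the plateau or the series edge. Mid-exponential
  growth by definition precedes stationary phase, so the restriction loses
  nothing on clean data (verified exact on noise-free logistics across
  r ∈ [0.1, 1.0] h⁻¹).
- **Smoothing** is Savitzky–Golay (`scipy.signal.savgol_filter`). The
  general-purpose `smooth_series` default is window 11 / polyorder 3; the
  pipeline's OD-phase-detection default is window 21 (5.25 h at 15-min
  sampling), because at 11 points the residual slope noise under 5 %
  multiplicative noise (~0.06 OD/h) is comparable to a typical maximum
  growth slope (rK/4 ≈ 0.125 OD/h at r = 0.5 h⁻¹, K = 1), which makes
  timepointing unreliable; 21 points suppress it while leaving noise-free
  inflection recovery exact. Both are configurable.
- **Detectability** is operationalized as stationary RFU exceeding the
  background strain's late-stationary RFU mean by more than k = 3 standard
  deviations; the background statistics use all samples at or after the
  background's stationary timepoint (at least the last 10 samples).
- Curves that never visibly plateau take the final timepoint as
  t_stationary, with a warning.

## What the synthetic data emulate — and what they do not

Biomass follows a logistic OD(t) = K/(1 + e^(−r(t−t0))) with defaults
K = 1.0 OD, r = 0.5 h⁻¹, t0 = 10 h, sampled every 15 min over 36 h. GFP is
proportional to biomass (50 000 AU/OD) with a shared linear
fluorophore-accumulation drift (0.02 h⁻¹) after stationary onset that
multiplies both channels identically — so the mCherry/GFP ratio stays flat in
late stationary phase, which is the property the normalization exploits.
mCherry is constructed as RFU_true(t) × FI(GFP), where RFU_true is a plateau
at `true_ratio × strength` through mid-exponential phase, a linear ramp, and
a plateau at `strength` (the stationary RFU level) from before stationary
onset; noise-free, the full pipeline recovers `true_ratio` to machine
precision. Gaussian noise is applied per point with SD equal to a fixed
fraction of the clean signal (default 2 %), independently per channel and
per media-control well.

The emulated cohort mirrors the characterized study design: 33 sorted strains
of which 25 are active — 12 stationary-biased (true ratios drawn in
[0.35, 0.60]), 10 unbiased ([0.85, 1.15]), 3 exponential-biased
([1.45, 1.90]) — and 8 inactive, plus a reporter-free background strain.
Active strengths are log-spaced over [0.005, 0.61], two orders of magnitude,
with the strongest strain stationary-biased. The media background level is
50 AU: with noise proportional to each well's signal, a large background
would add noise *unrelated* to the reporter signal and push the weakest
strains' effective noise far above the nominal fraction, so the background
is kept small relative to the weakest signals the cohort contains.

Not emulated: lag-phase artifacts, evaporation and edge effects, plasmid
copy-number enrichment in stationary phase (a systematic bias the ratio
cannot remove), cross-talk between fluorophores, diauxic or non-logistic
growth, and well-to-well growth-parameter variation beyond the seeded noise.
Passing tests therefore show the *computational* chain is correct and robust
to measurement noise, not that real cohorts will split 12/10/3.

Genome simulation places fixed-length (300 bp) random genes with prescribed
gap lengths and strand patterns, screens intergenic sequence free of
accidental type-IIS sites (unless one is deliberately planted), and emits a
ground-truth table of every expected candidate and its flags; parsing the
GenBank back and extracting candidates must reproduce it exactly. Read-count
tables draw uniform counts within each requested decade and omit a
configurable fraction of genes to exercise the transcriptome filter.

## Problem sizes

The shipped analysis and the reproduction script use a 761-gene replicon
(760 candidates, 722 with counts — matching the survivor count the selection
rule was designed around), a 33-strain cohort at 2 % noise, and a 200-strain
recovery experiment at 5 % noise (8 cohorts of 25 actives). These sizes keep
a full run to a few seconds while exercising every code path at the same
constants the design rules encode.

## Known limitations

- The mine→design file round-trip carries candidates through FASTA/TSV; an
  overlap-flagged candidate's empty sequence is represented as a single `N`
  placeholder record in FASTA and restored as empty on load.
- Quadrant gating uses fixed closed AU intervals; no density-based or
  adaptive gating.
- `detect_active` assumes the background strain was grown on the same plate
  under the same media; no plate-effect correction is attempted.
- The two printed threshold conventions for phase bias (0.7/1.3 vs 75 %/125 %)
  differ slightly; the implementation uses 0.7/1.3, configurable.
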