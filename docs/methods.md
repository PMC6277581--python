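# Methods

This note documents the models behind `fxscreen`: what the synthetic
signal generators emulate, how the analysis operates on those signals,
the defaults and why they were chosen, and what the passing test suite
does and does not demonstrate about real instrument data.

## Repeat categories and the cohort table

Categories are fixed intervals of the CGG count: NL 5–44, IM/GZ 45–54,
PM 55–199, FM ≥ 200.  Counts of 1–4 (below the conventional normal
floor) are mapped to NL with a `below_normal_floor` flag: the screen
distinguishes expanded from non-expanded, and a very short allele melts
even earlier than a normal one.

The packaged reference cohort stores each genotype verbatim.  Parsing
conventions:

- Female rows list two primary alleles; additional entries are treated
  as somatic mosaic components, assigned a combined mass fraction of 0.4
  split equally (the table gives no per-species quantification; 0.4
  keeps mosaic species visible in both melt and ladder signals while
  letting the primary alleles dominate).
- A range entry `a-b` denotes an unresolved expansion smear and is
  represented by its lower bound (the category is unaffected: every
  smear in the table lies entirely above 200).
- One male row lists two alleles.  A male carries one X, so the record
  is kept with a `sex_allele_mismatch` flag and the first allele is
  treated as the amplifiable species; the second entry is preserved in
  the raw string but not simulated.  This is the only reading under
  which the row's recorded NL status and negative screen call are
  internally consistent.

## Melt-curve model

Each repeat species contributes a decreasing logistic transition

    F(T) = B + Σᵢ A·wᵢ·s(mass) / (1 + exp((T − Tm(nᵢ) − J)/w)),

on the 65–95 °C, 0.5 °C acquisition grid (61 points), with baseline
B = 100, amplitude A = 1000, transition width w = 0.8 °C, component
weights wᵢ (primary alleles split the non-mosaic fraction equally), and
a saturating template-mass response s(m) = m/(m + 10 ng).

**Tm response.**  Tm(n) = tm_sat − (tm_sat − tm_min)·exp(−n/τ), strictly
increasing and saturating for large expansions.  Defaults
tm_min = 80.908 °C, tm_sat = 93.2 °C, τ = 35 repeats were calibrated
jointly so that:

1. an 8-repeat allele melts at 83.42 °C (the one absolute Tm anchor the
   assay's validation data provide);
2. the 44/45-repeat NL–IM/GZ boundary is maximally separated from the
   top of the normal range given (1) — the separation
   Tm(46) − Tm(40) ≈ 0.62 °C is near its maximum over τ at this anchor;
3. the saturation plateau stays ≥ 1.8 °C below the top of the
   acquisition window, where the peak estimator is still linear (see
   *Numerical choices*).

**Noise.**  One Tm jitter draw per well (a run-level thermal shift
applied to all transitions), with SD 0.11 °C at ≥ 25 ng/µL rising
linearly in 1/concentration to 0.53 °C at 8 ng/µL — the two replicate
SDs observed for the assay — and capped at 0.6 °C: position error is
physically bounded by the transition width, and an uncapped 1/c
extrapolation to ~1 ng/µL would predict several degrees.  White baseline
noise and a random linear drift (SD 1 fluorescence unit) complete the
model.  All stochastic generators demand an explicit seed and are
bit-reproducible.

**Flat profiles.**  Template mass controls amplitude through s(m); under
the default analysis floors a single-allele well falls below the peak
floor at ≲ 2.5 ng of template, matching the assay's behaviour of
analyzable profiles down to ~3 ng and flat ones below.  The cohort run
annotates the two low-yield samples (8 ng/µL and 1 ng/µL); all other
samples default to 25 ng/µL, a mid-range dried-blood-spot yield.

## Melt analysis

- Savitzky–Golay smoothing (window 7 points = 3 °C, order 2) of the
  fluorescence, then central differences at the grid points (one-sided
  at the ends) give −dF/dT.
- Peaks must exceed an absolute height floor (60 signal/°C, the
  flat-profile criterion) and a relative prominence floor (10 % of the
  profile maximum).  Prominence is evaluated with the profile padded to
  zero at both ends: without padding the prominence of a peak near the
  95 °C edge would be measured against the still-elevated truncated
  ramp.  The absolute floor deliberately does not apply to prominence —
  the sech²-shaped tails of neighbouring transitions leave shallow
  valleys, and a female's expanded peak must not be rejected because her
  normal allele melts 3 °C earlier.
- The last-peak Tm is refined to sub-grid resolution by a 3-point
  parabola.
- Boundary calibration takes the min and max last-peak Tm of the four
  46–54-repeat control wells of the same run (per-run extremes, not
  pooled replicates).  Classification applies a fixed guard margin,
  default 0.3 °C, beyond the band; the in-band zone is indeterminate and
  reflexes to sizing.  The margin operationalises "clearly beyond the
  boundary"; raising it can only move decided calls to indeterminate.
- Retest policy: template volumes 2, 5, 7.5 µL tried in order; first
  non-flat profile is classified; QC failure only after all volumes.

## Electropherogram models and sizing

**TP-PCR ladder.**  Peak for repeat position k at `100 + 3k` bp (the
absolute register is an assay calibration constant; only the 3-bp
spacing and the count carry meaning), Gaussian peaks of σ = 0.6 bp,
amplitude decaying geometrically at 0.985 per period.  Each successive
longer species contributes at half the amplitude of the previous one —
short templates amplify preferentially — which guarantees a detectable
step at every species boundary.  Species ends are called at amplitude
drops to ≤ 50 % sustained for ≥ 3 periods (or a silent gap of ≥ 10
periods); the final peak ends the largest resolvable species.  Any peak
at or beyond position 200 raises the FM flag, and such species are
reported as "> 200", never as a point estimate: the geometric decay
buries the ladder long before, e.g., a 900-repeat allele's true end, so
a point estimate there would be fiction.  Two or more expanded (≥ 55)
species set the mosaic flag.

**Regular PCR.**  One Gaussian amplicon per species at
`209 + 3n − 12` bp; the −12 bp (−4 repeat) mobility offset reproduces
the consistent ~4-repeat under-call of the conversion formula
`(bp − 209)/3` for GC-rich amplicons, corrected by +4 after rounding.
Species at ≥ 200 repeats yield no product (dropout), which is why a
male trace with no peak or a female trace with one peak is flagged as
suspected dropout — a single amplicon cannot distinguish a homozygous
normal female from a carrier of a non-amplifiable full mutation.

## Numerical choices

- Derivatives are reported at grid points, not midpoints.
- The smoothing filter uses `nearest` edge padding; the default
  polynomial edge interpolation distorts the final half-window badly
  enough to erase a transition melting near the top of the ramp.
- Sub-grid refinement is computed on the *unsmoothed* derivative
  (re-centred on the local raw maximum): smoothing biases the parabola
  vertex increasingly above ~92.5 °C, which both compressed and inflated
  replicate Tm SDs depending on where a genotype melts.  On noiseless
  curves the refined Tm agrees with the analytic Tm(n) to < 0.01 °C
  across 5–600 repeats, well inside the half-grid-step tolerance.
- Ladder peak floor is 0.005 of the trace maximum; with the 0.985 decay
  a 250-repeat single-allele ladder stays countable peak-for-peak.
- Equal-length alleles (homozygous females) merge into one ladder
  species and one melt transition; they are inherently unresolvable and
  reported as a single size.

## What the generators do not emulate

PCR stutter, AGG-interruption structure, CpG methylation, dye chemistry
and size-standard recalibration, instrument-specific raw formats,
non-logistic melt baselines, and amplitude competition between alleles
beyond the fixed short-template bias.  Passing tests therefore
demonstrate the correctness and internal consistency of the analysis
logic under the stated signal model — not performance on raw Rotor-Gene
or CE instrument files.

## Problem sizes in the test suite

The suite runs the full 151-sample cohort screen (all melt wells plus
reflex ladders), ladder round-trips for every repeat count 1–250,
100 jittered calibration repeats, and 1000-replicate jitter-recovery
checks; the acceptance script uses the complete cohort and 10-replicate
reproducibility batches, mirroring the reference study's design.  The
n = 10 replicate SD is itself a noisy estimator (sampling error roughly
±50 %), which is the tolerance applied to it.

## Known limitations

- The IM/GZ band is calibrated from simulated controls whose repeat
  counts (46, 48, 52, 54) stand in for the reference control DNAs; real
  control lines have their own exact sizes.
- Classification of genotypes whose largest allele lies within 45–54
  repeats is intentionally indeterminate — they melt inside the control
  band — and resolves only through reflex sizing.
- A normal allele within ~2 °C of a barely-expanded one can merge into a
  single melt peak and downgrade an expanded call to indeterminate (the
  reflex still sizes it correctly); this mirrors the physical resolution
  limit of melt analysis.
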