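# fxscreen

Two-tier screening for *FMR1* CGG-repeat expansions — the cause of
fragile X syndrome — built around triplet-primed PCR (TP-PCR) melt curve
analysis with reflex capillary-electrophoresis (CE) repeat sizing.  The
package is aimed at people developing or evaluating expansion-screening
pipelines: it implements the complete analysis layer (derivative
transform, melt-peak calling, boundary calibration, classification,
ladder counting, amplicon size conversion, cohort orchestration) and a
synthetic-signal layer that emulates dried-blood-spot assay behaviour so
everything can be exercised and tested without instrument data.

## The screen

The *FMR1* 5′-UTR CGG repeat is classified by count: normal (NL, 5–44),
intermediate/gray zone (IM/GZ, 45–54), premutation (PM, 55–199) and full
mutation (FM, ≥ 200).  TP-PCR amplifies into the repeat from many
internal positions, so the product pool's melting temperature tracks the
*largest* repeat species present, in males and females alike:

> Tm(normal) < Tm(premutation) < Tm(full mutation)

**Tier 1 (melt screen).** Fluorescence is acquired over 65–95 °C in
0.5 °C steps and transformed to −dF/dT.  The decision statistic is the
*last-peak Tm* — the highest-temperature peak above the prominence floor.
Four IM/GZ boundary-control DNAs (46–54 repeats) are melted in every run;
their last-peak Tms span the decision band `[lower_tm, upper_tm]`.  With
guard margin *m* (default 0.3 °C):

- `tm > upper_tm + m` → **expanded**
- `tm < lower_tm − m` → **non-expanded**
- otherwise → **indeterminate**, reflexed to sizing

Flat profiles (insufficient template) are retested at escalating template
volumes (2 → 5 → 7.5 µL) before being declared QC failures.

**Tier 2 (reflex CE sizing).** Expanded and indeterminate samples are
sized from the TP-PCR CE ladder: one peak per repeat at 3-bp spacing, so
the repeat count is literally the peak count.  Species boundaries are
sustained ≥ 50 % amplitude drops; any ladder signal at or beyond the
200-repeat position is reported as “> 200” (full mutation).  Regular
(repeat-spanning) PCR sizes an amplicon as `repeats = (bp − 209) / 3`,
which under-calls by ~4 repeats due to GC-driven anomalous mobility
(corrected after rounding) and drops out entirely for large expansions.

A packaged reference cohort of 151 previously genotyped dried-blood-spot
samples (75 male, 76 female; 7 PM and 8 FM carriers) drives the
end-to-end tests.

## Worked example

```python
import fxscreen as fx

cohort = fx.load_reference_cohort()
records, summary = fx.run_screen(cohort, seed=1)
print(summary.n_positive, summary.n_positive_male, summary.n_positive_female)
# 15 3 12                    # expansion-positive calls (male, female)
print(summary.n_negative, summary.n_discordant)
# 136 0                      # negatives; zero discordance with known status
print(summary.n_pm, summary.n_fm)
# 7 8                        # reflex sizing: premutations, full mutations
print(summary.n_homozygous_normal_females, summary.n_normal_females)
# 43 64                      # normal females a regular-PCR-first strategy must reflex
```

Fifteen of 151 samples (~10 %) melt above the control band and proceed to
sizing; a regular-PCR first tier would instead have to reflex the 43 of
64 normal females (~67 %) whose two alleles are indistinguishable — that
asymmetry is the case for melt-based first-tier screening.

The same run from the shell:

```bash
fxscreen run --seed 1 --out report.tsv --summary summary.json
# 15 expanded (3M, 12F), 136 non-expanded, 0 indeterminate, 0 QC failures;
# 0 discordant with known status
```

Single-sample sizing:

```python
trace = fx.simulate_tppcr_trace(cohort["154"].genotype)   # FM mosaic female
call = fx.count_ladder(trace)
print(call.allele_sizes, call.fm_flag, call.mosaic_flag, call.category.name)
# [28, 110] True True FM    # short alleles, ladder past 200 repeats, mosaic
```

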