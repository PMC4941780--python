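# Packaged data dictionary

## table1_specimens.csv

One row per specimen x body-mass estimate.  Specimens with two published
mass estimates appear twice, sharing `taxon`/`specimen_label` and
distinguished by `mass_label`; the pair counts once per estimate in all
analyses (34 non-avian analysis rows).

| column | units | description |
| --- | --- | --- |
| taxon | - | binomial (genus + species or qualifier) |
| specimen_label | - | museum/collection number where published (may be blank) |
| source_ref | - | literature source of the measurements |
| group | - | `nonavian` or `avialan` |
| life_stage | - | `adult`, `juvenile`, or `embryo` |
| wing_length_m | m | single-wing length: humerus + ulna + metacarpal II + longest primary |
| span_m | m | wingspan, 2.1 x wing length (body included) |
| mass_method | - | `femur_CF`, `humerus_Liu`, `humerus_Fe`, or `literature` |
| mass_label | - | short key for the estimate (CF / Liu / Fe / lit-low / lit-high) |
| mass_kg | kg | body-mass estimate |
| area_m2 | m^2 | wing planform area as printed (rounded to 2 decimals) |
| loading_N_m2 | N/m^2 | wing loading = 9.8 x mass / unrounded area; authoritative for recovering area |
| feathers_estimated | - | True when primary length was inferred from relatives |
| paravian | - | True for paravians (including avialans) |

Known transcription artefacts in the source table, preserved as printed:
the *Sinornithoides* row's span, area, and loading are mutually
inconsistent, and the smaller *Sinosauropteryx* row's span is off the
2.1 x rule beyond rounding.  `SpecimenRecord.consistency_issues()` flags
both; regression calibration excludes flagged rows.

## table2_extant_validation.csv

Extant-bird ground-truth rows for the weight-support equation.  Range
cells (pigeon mass/frequency, bw) are split into `*_lo` / `*_hi`; point
values have lo == hi.  `bw_clXX_*` columns hold the published body-weight
support at lift coefficient XX/10; blank where not published.  Wing length
is deliberately absent (unpublished); it is back-solved by
`validation.backsolve_wing_length`.

## table3_reference_bw.csv

Published body-weight-support fractions per specimen under the three
wingbeat-frequency estimators (`bw_ALL`, `bw_GF`, `bw_MOD`), at the 90 deg
flap angle and two centre-of-mass speeds (0.6, 1.5 m/s).  Dual-value
cells in the source (two mass estimates) are split into separate rows via
`mass_label`, lighter estimate first in the source's notation.
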