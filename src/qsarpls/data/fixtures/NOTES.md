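# Fixture transcription notes

These CSVs transcribe published CXCR2-antagonist activity tables verbatim; the
values below document where the printed numbers are not internally consistent.
Loaders attach a `self_consistent` flag (recomputed pIC50 agrees with the
printed pIC50 within ±0.01 at 2-dp rounding under the printed unit); numeric
tests use only self-consistent rows.

## cxcr2_activities.csv

* **Acylsulfonamide series (compounds 1-25, µM):** several printed pIC50 values
  disagree with -log10(IC50) by 0.01-0.05 (e.g. 0.07 µM → 7.15 computed vs 7.14
  printed; 0.06 µM → 7.22 vs 7.19; 0.02 µM → 7.70 vs 7.72/7.62).  Printed values
  kept; rows flagged inconsistent where they disagree.
* **Cyclobutenedione series (26-58):** the unit header reads nM, but rows 26-46
  are only self-consistent if the IC50 column is in µM (0.005 "nM" → printed
  pIC50 8.3 = -log10(5e-9 mol/L)).  The printed unit is kept in the file; these
  rows flag as inconsistent under it.
* **Diphenylurea series (59-75):** compound 75 prints pIC50 7.49 but
  -log10(39e-9) = 7.41.  All other rows are self-consistent.
* **Triazolethiol (83-110), nicotinamide N-oxide (76-82), bicyclic (111-126):**
  self-consistent throughout.
* A seventh published series is omitted: in the extracted text its table rows
  merge two compounds per line with a single shared IC50 cell and cannot be
  transcribed unambiguously.

## test_set_predictions.csv

Residual convention: residual = predicted - experimental.  All rows satisfy it
within ±0.01 except compound 47, whose printed residuals are off by 0.03-0.04
against its printed experimental/predicted pair (0.62 vs computed 0.66 for PLS,
0.52 vs 0.56 for GA-PLS, -0.57 vs -0.54 for SMLR).
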