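# Prebiotic presets.
#
# grams_per_mmol are average formula weights (g/mmol): a GF(n) fructan chain
# weighs 180.156 + 162.141*n g/mol.  scFOS is kestose (GF2), kestotetraose
# (GF3) and kestopentaose (GF4) in equal mass thirds by default; inulin is a
# degree-of-polymerization-10 average polymer.  horizon_hours amortizes a
# once-daily dose; gdw_scale is the per-gram-dry-weight normalization.
# Exact gram-to-flux calibration differs between model collections, so every
# number here is overridable from a user preset file.
#
# "fructan-toy" targets the bundled toy models, calibrated so that a dose of
# d grams maps to a fructan uptake bound of d flux units (which keeps the
# toy arithmetic transparent).
fructan-toy:
  components:
    - exchange: EX_fru_lu
      mass_fraction: 1.0
      grams_per_mmol: 1.0
  horizon_hours: 1.0

inulin:
  components:
    - exchange: EX_inulin_lu
      mass_fraction: 1.0
      grams_per_mmol: 1.80156
  horizon_hours: 24.0

scfos:
  components:
    - exchange: EX_kestose_lu
      mass_fraction: 0.3333333333333333
      grams_per_mmol: 0.50444
    - exchange: EX_kestotetraose_lu
      mass_fraction: 0.3333333333333333
      grams_per_mmol: 0.66658
    - exchange: EX_kestopentaose_lu
      mass_fraction: 0.3333333333333334
      grams_per_mmol: 0.82872
  horizon_hours: 24.0
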