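"""DSB burden arithmetic: from oligo fractions to per-cell break frequencies.

Every number here is a deterministic conversion: oligo-count fractions into
percent of DNA broken (with the mapping strain's reduced DSB efficiency),
fold-suppression relative to genome average and to typical coding sequence,
and per-cell break expectations.
"""
from tymap import DsbCalibration, burden_metrics, oligo_fraction_to_dsb_percent

# the regression slope/intercept relating oligo counts to % DNA broken come
# from external calibration (see examples/dsb_calibration.yaml); slope 1 /
# intercept 0 passes an already-calibrated percentage straight through
calib = DsbCalibration(slope=1.0, intercept=0.0, efficiency=0.8)

for label, frac in (("dmc1", 2.0), ("sae2", 0.85)):
    out = oligo_fraction_to_dsb_percent(frac, calib)
    print(f"{label}: {out['uncorrected']}% of DNA broken in the mapping "
          f"strain -> {out['corrected']}% after the 80% efficiency correction")

out = burden_metrics(
    ty_genome_frac=1.5,        # % of the genome that is Ty-internal sequence
    ty_oligo_frac=0.1,         # % of oligos mapping to Ty-internal sequence
    orf_oligo_frac=11.5,       # % of oligos in coding sequence
    orf_genome_frac=69.4,      # % of the genome that is coding
    per_dna_frac=0.3,          # % DNA broken inside one element
    ty_ltr_oligo_frac=0.28,    # % of oligos in Ty or solo-LTR sequence
)
print(f"\nfold suppression vs genome average: "
      f"{out['fold_suppression']:.0f}-fold")
print(f"fold colder than a typical ORF:     "
      f"{out['orf_relative_fold']:.2f}-fold")
print(f"cells breaking one element (0.3% DNA x 4 chromatids): "
      f"{out['cell_frac']:.1f}%")
print(f"expected Ty/LTR DSBs per cell (160 DSBs x 0.28%): "
      f"{out['expected_dsbs_per_cell']:.2f}"
      f" -> one cell in {out['one_in_n_cells']:.1f}")
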