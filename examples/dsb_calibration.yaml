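# DSB calibration — user-supplied from external regression of Spo11-oligo
# counts against directly measured DSB frequencies.  The slope and intercept
# below are placeholders (identity): replace them with your own calibration
# before converting oligo fractions to percent DNA broken.
slope: 1.0
intercept: 0.0
efficiency: 0.8          # DSB efficiency of the oligo-mapping strain vs wild type
chromatids_per_cell: 4
dsbs_per_cell: 160.0
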