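# Published sex-specific sample-median cut-offs for the ultrasound
# muscle mass and quality scores. 'low' cut-offs score a point when the
# value is strictly below; 'high' when strictly above.
rfma_low:       # cm^2
  male: 3.48
  female: 2.62
rfmt_low:       # cm
  male: 0.89
  female: 1.06
mit_low:        # % of ROI
  male: 45.88
  female: 43.92
fatit_high:     # % of ROI
  male: 39.41
  female: 40.27
pennation_low:  # degrees
  male: 5.76
  female: 4.78
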