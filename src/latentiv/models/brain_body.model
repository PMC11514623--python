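# Brain/body nutritional-investment trade-off model.
#
# Two latent constructs: "nutritional investment in brain tissues"
# (indicated by estimated total intracranial volume, cerebrum and
# cerebellum volumes) and "nutritional investment in lean body tissues"
# (indicated by summed organ volumes and skeletal muscle mass).  Height
# adjusts for body size; the brain latent carries hypothesised negative
# causal paths to the body latent and to measured fat mass.
#
# The first indicator on each =~ line is the scaling indicator (loading
# fixed to 1): TIV for the brain latent, organs for the body latent.
#
# Rescale divisors bring the indicator variances to a common order of
# magnitude before fitting; volumes in the thousands of cm^3 are divided
# by 100, the smaller cerebellum and height (cm) by 10.  Estimates are
# reported on both the analysis and the original scale.
rescale: TIV=100 cerebrum=100 cerebellum=10 organs=100 height=10

brain =~ TIV + cerebrum + cerebellum
body =~ organs + SM

brain ~ height
body ~ brain + height
fat ~ brain + height
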