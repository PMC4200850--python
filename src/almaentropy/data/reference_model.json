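{
  "intercept": 1.139556,
  "coef": {
    "quality": -0.403994,
    "sx": 0.199322,
    "au": 0.434889,
    "ot": -0.020189,
    "te": -0.00166
  },
  "cutoff": 0.5,
  "link": "logistic",
  "meta": {
    "source": "published ALMA-entropy linear discriminant coefficients",
    "N": 2661,
    "Rc": 0.72,
    "chi2": 1913.007,
    "note": "probabilities from this fixed model use a logistic link as a documented approximation; only the score is exact"
  }
}
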