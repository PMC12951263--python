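[
  {
    "marker": "GSMD",
    "scale": "log",
    "ga_domain_days": [35, 100],
    "median_coeffs": [-1.19854466, 0.11055133, -0.00057306],
    "sd_coeffs": [0.30],
    "provenance": "synthetic plausible approximation (lognormal gestational-sac growth ~1 mm/day from day 30); not the published Rempen chart"
  },
  {
    "marker": "YSMD",
    "scale": "log",
    "ga_domain_days": [35, 100],
    "median_coeffs": [0.83661303, 0.01556591, -4.507e-05],
    "sd_coeffs": [0.22],
    "provenance": "synthetic plausible approximation (yolk sac 4-7 mm, slow first-trimester growth); not the published Grisolia chart"
  },
  {
    "marker": "CRL",
    "scale": "log",
    "ga_domain_days": [35, 100],
    "median_coeffs": [-3.36635198, 0.14814524, -0.00070779],
    "sd_coeffs": [0.25],
    "provenance": "synthetic plausible approximation of the Robinson dating relation GA = 8.052*sqrt(CRL) + 23.73; not the published Robinson & Fleming chart"
  },
  {
    "marker": "HR",
    "scale": "natural",
    "ga_domain_days": [35, 100],
    "median_coeffs": [-105.54545455, 7.74646465, -0.05353535],
    "sd_coeffs": [14.0],
    "provenance": "synthetic plausible approximation (embryonic heart rate peaking ~170 bpm near 9 weeks); not the published Papaioannou chart"
  }
]
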