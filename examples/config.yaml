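# Full-pipeline configuration for `chemocal run --config examples/config.yaml`.
# Every stochastic stage derives from `seed`; identical configs give
# byte-identical outputs.

seed: 20230727

design:
  center: 9.0        # ug/mL; levels are center +/- {0,1,2}*step -> 1,5,9,13,17
  step: 4.0
  scheme: odd_even   # or an explicit list of calibration sample ids

# Gaussian-band pure-component surrogates: [center_nm, sigma_nm, height AU*mL/ug]
components:
  - name: favipiravir
    bands: [[323, 20, 0.055], [245, 14, 0.020]]
  - name: remdesivir
    bands: [[246, 16, 0.065], [278, 14, 0.030]]

noise:
  noise_sd: 0.002        # AU, homoscedastic instrument noise
  baseline_offset: 0.0   # AU
  baseline_slope: 0.0    # AU/nm

# Included wavelength intervals; drop an interval to exclude a noise region,
# e.g. [[240, 400]] to discard 220-239 nm.
mask: [[220, 400]]

methods: [cls, pcr, pls]

cv:
  max_latent: 8
  rule: one_se_like_fratio   # or global_min

plasma:
  enabled: true
  level: 1.0       # nominal interferent level
  jitter: 0.2      # +/-20% per-sample level variation
  interferent:
    name: plasma_background
    bands: [[265, 45, 0.050], [228, 12, 0.040]]

merit:
  accuracy_levels: [4, 8, 16]  # ug/mL, within the 1-17 calibrated range
  reps: 3
  days: 3

# Analytical eco-scale penalty itemizations (example reconstructions).
greenness:
  cls:
    "ethanol >10 mL (amount 2 x hazard 2)": 8
    "acetonitrile <10 mL (plasma prep)": 4
    "occupational hazard": 3
    "waste 1-10 mL untreated": 6
  pcr:
    "ethanol >10 mL (amount 2 x hazard 2)": 8
    "acetonitrile <10 mL (plasma prep)": 4
    "occupational hazard": 1
    "waste 1-10 mL untreated": 6
  pls:
    "ethanol >10 mL (amount 2 x hazard 2)": 8
    "acetonitrile <10 mL (plasma prep)": 4
    "occupational hazard": 3
    "waste 1-10 mL untreated": 6
    "energy (software workstation)": 1
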