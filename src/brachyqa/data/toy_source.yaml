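name: toy
description: 'Analytic toy source: g_L == 1 and F == 1 everywhere; for tests and identities.'
active_length_cm: 0.36
dose_rate_constant: 1.109
radial_dose:
  r_cm: [0.05, 50.0]
  g: [1.0, 1.0]
anisotropy:
  r_cm: [0.05, 50.0]
  theta_deg: [0.0, 180.0]
  F:
  - [1.0, 1.0]
  - [1.0, 1.0]
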