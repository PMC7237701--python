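name: ir192-generic
description: Representative Ir-192 HDR stepping-source table (synthetic fixture with physically plausible
  magnitudes; not manufacturer consensus data).
active_length_cm: 0.36
dose_rate_constant: 1.109
radial_dose:
  r_cm: [0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0]
  g: [0.988, 0.99, 0.996, 0.999, 1.0, 1.002, 1.004, 1.005, 1.002, 0.995, 0.985, 0.95, 0.903]
anisotropy:
  r_cm: [0.25, 0.5, 1.0, 2.0, 3.0, 5.0]
  theta_deg: [0.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0, 110.0, 120.0, 130.0,
    140.0, 150.0, 160.0, 170.0, 175.0, 180.0]
  F:
  - [0.6, 0.6027, 0.6109, 0.6424, 0.6912, 0.7524, 0.8195, 0.8851, 0.942, 0.9829, 1.0, 0.9815, 0.9374,
    0.8759, 0.805, 0.7326, 0.6665, 0.6138, 0.5797, 0.571, 0.568]
  - [0.63, 0.6325, 0.6401, 0.6692, 0.7144, 0.771, 0.833, 0.8937, 0.9464, 0.9842, 1.0, 0.9829, 0.9421,
    0.8852, 0.8196, 0.7527, 0.6916, 0.6427, 0.6113, 0.6031, 0.6004]
  - [0.66, 0.6623, 0.6692, 0.696, 0.7376, 0.7896, 0.8465, 0.9024, 0.9507, 0.9854, 1.0, 0.9843, 0.9468,
    0.8945, 0.8343, 0.7727, 0.7166, 0.6717, 0.6428, 0.6353, 0.6328]
  - [0.69, 0.6921, 0.6984, 0.7228, 0.7607, 0.8081, 0.8601, 0.911, 0.9551, 0.9867, 1.0, 0.9857, 0.9515,
    0.9039, 0.8489, 0.7928, 0.7416, 0.7007, 0.6743, 0.6675, 0.6652]
  - [0.71, 0.712, 0.7179, 0.7407, 0.7762, 0.8205, 0.8691, 0.9167, 0.958, 0.9876, 1.0, 0.9866, 0.9546,
    0.9101, 0.8586, 0.8061, 0.7582, 0.72, 0.6953, 0.6889, 0.6868]
  - [0.73, 0.7318, 0.7373, 0.7586, 0.7916, 0.8329, 0.8781, 0.9225, 0.9609, 0.9884, 1.0, 0.9875, 0.9577,
    0.9163, 0.8684, 0.8195, 0.7749, 0.7393, 0.7163, 0.7104, 0.7084]
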