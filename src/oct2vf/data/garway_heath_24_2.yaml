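convention: right-eye, TSNIT disc angles
points:
- point: 0
  x_deg: -9.0
  y_deg: 21.0
  sector: superior
  disc_angle_deg: 280.65
- point: 1
  x_deg: -3.0
  y_deg: 21.0
  sector: superior
  disc_angle_deg: 289.22
- point: 2
  x_deg: 3.0
  y_deg: 21.0
  sector: superior
  disc_angle_deg: 298.77
- point: 3
  x_deg: 9.0
  y_deg: 21.0
  sector: superior
  disc_angle_deg: 307.96
- point: 4
  x_deg: -15.0
  y_deg: 15.0
  sector: superior-nasal
  disc_angle_deg: 268.64
- point: 5
  x_deg: -9.0
  y_deg: 15.0
  sector: superior
  disc_angle_deg: 276.32
- point: 6
  x_deg: -3.0
  y_deg: 15.0
  sector: superior
  disc_angle_deg: 287.39
- point: 7
  x_deg: 3.0
  y_deg: 15.0
  sector: superior
  disc_angle_deg: 300.68
- point: 8
  x_deg: 9.0
  y_deg: 15.0
  sector: central
  disc_angle_deg: 312.86
- point: 9
  x_deg: 15.0
  y_deg: 15.0
  sector: central
  disc_angle_deg: 322.06
- point: 10
  x_deg: -21.0
  y_deg: 9.0
  sector: superior-nasal
  disc_angle_deg: 257.02
- point: 11
  x_deg: -15.0
  y_deg: 9.0
  sector: superior-nasal
  disc_angle_deg: 261.12
- point: 12
  x_deg: -9.0
  y_deg: 9.0
  sector: superior-nasal
  disc_angle_deg: 268.64
- point: 13
  x_deg: -3.0
  y_deg: 9.0
  sector: superior
  disc_angle_deg: 283.33
- point: 14
  x_deg: 3.0
  y_deg: 9.0
  sector: superior
  disc_angle_deg: 305.02
- point: 15
  x_deg: 9.0
  y_deg: 9.0
  sector: central
  disc_angle_deg: 322.06
- point: 16
  x_deg: 15.0
  y_deg: 9.0
  sector: central
  disc_angle_deg: 331.87
- point: 17
  x_deg: 21.0
  y_deg: 9.0
  sector: temporal
  disc_angle_deg: 219.42
- point: 18
  x_deg: -27.0
  y_deg: 3.0
  sector: superior-nasal
  disc_angle_deg: 248.25
- point: 19
  x_deg: -21.0
  y_deg: 3.0
  sector: superior-nasal
  disc_angle_deg: 249.17
- point: 20
  x_deg: -15.0
  y_deg: 3.0
  sector: superior-nasal
  disc_angle_deg: 250.82
- point: 21
  x_deg: -9.0
  y_deg: 3.0
  sector: superior-nasal
  disc_angle_deg: 254.52
- point: 22
  x_deg: -3.0
  y_deg: 3.0
  sector: superior-nasal
  disc_angle_deg: 268.64
- point: 23
  x_deg: 3.0
  y_deg: 3.0
  sector: central
  disc_angle_deg: 322.06
- point: 24
  x_deg: 9.0
  y_deg: 3.0
  sector: central
  disc_angle_deg: 341.42
- point: 25
  x_deg: 21.0
  y_deg: 3.0
  sector: temporal
  disc_angle_deg: 198.6
- point: 26
  x_deg: -27.0
  y_deg: -3.0
  sector: inferior-nasal
  disc_angle_deg: 111.75
- point: 27
  x_deg: -21.0
  y_deg: -3.0
  sector: inferior-nasal
  disc_angle_deg: 110.83
- point: 28
  x_deg: -15.0
  y_deg: -3.0
  sector: inferior-nasal
  disc_angle_deg: 109.18
- point: 29
  x_deg: -9.0
  y_deg: -3.0
  sector: inferior-nasal
  disc_angle_deg: 105.48
- point: 30
  x_deg: -3.0
  y_deg: -3.0
  sector: inferior-nasal
  disc_angle_deg: 91.36
- point: 31
  x_deg: 3.0
  y_deg: -3.0
  sector: central
  disc_angle_deg: 37.94
- point: 32
  x_deg: 9.0
  y_deg: -3.0
  sector: central
  disc_angle_deg: 18.58
- point: 33
  x_deg: 21.0
  y_deg: -3.0
  sector: temporal
  disc_angle_deg: 161.4
- point: 34
  x_deg: -21.0
  y_deg: -9.0
  sector: inferior-nasal
  disc_angle_deg: 102.98
- point: 35
  x_deg: -15.0
  y_deg: -9.0
  sector: inferior-nasal
  disc_angle_deg: 98.88
- point: 36
  x_deg: -9.0
  y_deg: -9.0
  sector: inferior-nasal
  disc_angle_deg: 91.36
- point: 37
  x_deg: -3.0
  y_deg: -9.0
  sector: inferior
  disc_angle_deg: 76.67
- point: 38
  x_deg: 3.0
  y_deg: -9.0
  sector: inferior
  disc_angle_deg: 54.98
- point: 39
  x_deg: 9.0
  y_deg: -9.0
  sector: central
  disc_angle_deg: 37.94
- point: 40
  x_deg: 15.0
  y_deg: -9.0
  sector: central
  disc_angle_deg: 28.13
- point: 41
  x_deg: 21.0
  y_deg: -9.0
  sector: temporal
  disc_angle_deg: 140.58
- point: 42
  x_deg: -15.0
  y_deg: -15.0
  sector: inferior-nasal
  disc_angle_deg: 91.36
- point: 43
  x_deg: -9.0
  y_deg: -15.0
  sector: inferior-nasal
  disc_angle_deg: 83.68
- point: 44
  x_deg: -3.0
  y_deg: -15.0
  sector: inferior
  disc_angle_deg: 72.61
- point: 45
  x_deg: 3.0
  y_deg: -15.0
  sector: inferior
  disc_angle_deg: 59.32
- point: 46
  x_deg: 9.0
  y_deg: -15.0
  sector: inferior
  disc_angle_deg: 47.14
- point: 47
  x_deg: 15.0
  y_deg: -15.0
  sector: central
  disc_angle_deg: 37.94
- point: 48
  x_deg: -9.0
  y_deg: -21.0
  sector: inferior
  disc_angle_deg: 79.35
- point: 49
  x_deg: -3.0
  y_deg: -21.0
  sector: inferior
  disc_angle_deg: 70.78
- point: 50
  x_deg: 3.0
  y_deg: -21.0
  sector: inferior
  disc_angle_deg: 61.23
- point: 51
  x_deg: 9.0
  y_deg: -21.0
  sector: inferior
  disc_angle_deg: 52.04
description: Garway-Heath style 24-2 point-to-optic-disc-sector assignment, right-eye
  convention. Encodes the published six-sector map via a retinotopic fiber-bundle
  approximation; edit freely.
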