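{
  "description": "Synthetic calibration peak table for the pseudo-acetaminophen wavenumber standard used by the cohort generator. Peak positions (cm^-1) lie inside the 800-1700 cm^-1 fingerprint window.",
  "wavenumbers_cm1": [857.9, 968.7, 1105.5, 1168.5, 1236.8, 1323.9, 1561.5, 1648.4]
}
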