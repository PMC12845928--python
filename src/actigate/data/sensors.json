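{
  "smart_device_builtin": ["Acc", "Gyr"],
  "movesense_motion": ["Acc", "Gyr", "Mag"],
  "mbientlab_metamotion": ["Acc", "Gyr", "Mag", "Bar", "Light"],
  "cosmo_switch": ["Force"],
  "retisense_insight": ["Force"],
  "gaitup_physilog5": ["Acc", "Gyr"],
  "m40_muscle_sense": ["EMG"],
  "puckjs": ["Acc", "Gyr"]
}
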