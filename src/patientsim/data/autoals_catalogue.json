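{
  "binary_events": [
    "ResponseVerbal", "ResponseGroan", "ResponseNone",
    "AirwayClear", "AirwayVomit", "AirwayBlood", "AirwayTongue",
    "BreathingNone", "BreathingSnoring", "BreathingSeeSaw",
    "BreathingEqualChestExpansion", "BreathingBibasalCrepitations",
    "BreathingWheeze", "BreathingCoarseCrepitationsAtBase",
    "BreathingPneumothoraxSymptoms", "VentilationResistance",
    "RadialPulsePalpable", "RadialPulseNonPalpable",
    "AVPU_A", "AVPU_V", "AVPU_P", "AVPU_U",
    "PupilsPinpoint", "PupilsNormal",
    "ExposureRash", "ExposurePeripherallyShutdown", "ExposureStainedUnderwear",
    "HeartRhythm0", "HeartRhythm1", "HeartRhythm2", "HeartRhythm3", "HeartRhythm4",
    "Blunder", "Failure", "Success", "Tick"
  ],
  "measurements": [
    "MeasuredHeartRate", "MeasuredRespRate", "MeasuredCapillaryGlucose",
    "MeasuredTemperature", "MeasuredMAP", "MeasuredSats", "MeasuredResps"
  ],
  "actions": [
    "AssessResponse", "AssessAirway", "AssessBreathing", "AssessCirculation",
    "AssessDisability", "AssessExposure", "AssessDefibrillator", "AssessMonitor",
    "DoNothing",
    "ABG", "AirwayManoeuvres", "GiveAtropine", "GiveAdenosine", "GiveAdrenaline",
    "GiveAmiodarone", "GiveMidazolam", "Venflon", "Yankeur", "DrawBloods",
    "BPCuffOn", "BVM", "Guedel", "NRBMask", "DefibOn", "DefibAttachPads",
    "DefibShock", "DefibCharge", "DefibChangePaceCurrentDown",
    "DefibChangePaceCurrent", "DefibEnergyDown", "DefibEnergyUp",
    "DefibChangePaceRateDown", "DefibChangePaceRateUp", "DefibPace",
    "Finish"
  ],
  "triggers": {
    "AssessResponse": ["ResponseVerbal", "ResponseGroan", "ResponseNone"],
    "AssessAirway": ["AirwayClear", "AirwayVomit", "AirwayBlood", "AirwayTongue"],
    "AssessBreathing": ["BreathingNone", "BreathingSnoring", "BreathingSeeSaw",
      "BreathingEqualChestExpansion", "BreathingBibasalCrepitations",
      "BreathingWheeze", "BreathingCoarseCrepitationsAtBase",
      "BreathingPneumothoraxSymptoms", "VentilationResistance", "MeasuredRespRate"],
    "AssessCirculation": ["RadialPulsePalpable", "RadialPulseNonPalpable", "MeasuredHeartRate"],
    "AssessDisability": ["AVPU_A", "AVPU_V", "AVPU_P", "AVPU_U",
      "PupilsPinpoint", "PupilsNormal", "MeasuredCapillaryGlucose"],
    "AssessExposure": ["ExposureRash", "ExposurePeripherallyShutdown",
      "ExposureStainedUnderwear", "MeasuredTemperature"],
    "AssessDefibrillator": [],
    "AssessMonitor": ["HeartRhythm0", "HeartRhythm1", "HeartRhythm2", "HeartRhythm3",
      "HeartRhythm4", "MeasuredHeartRate", "MeasuredMAP", "MeasuredSats", "MeasuredResps"],
    "DoNothing": [],
    "ABG": ["Blunder"],
    "AirwayManoeuvres": ["Blunder"],
    "GiveAtropine": ["Blunder"],
    "GiveAdenosine": ["Blunder"],
    "GiveAdrenaline": ["Blunder"],
    "GiveAmiodarone": ["Blunder"],
    "GiveMidazolam": ["Blunder"],
    "Venflon": ["Blunder"],
    "Yankeur": ["Blunder"],
    "DrawBloods": ["Blunder"],
    "BPCuffOn": ["Blunder"],
    "BVM": ["Blunder"],
    "Guedel": ["Blunder"],
    "NRBMask": ["Blunder"],
    "DefibOn": ["Blunder"],
    "DefibAttachPads": ["Blunder"],
    "DefibShock": ["Blunder"],
    "DefibCharge": ["Blunder"],
    "DefibChangePaceCurrentDown": ["Blunder"],
    "DefibChangePaceCurrent": ["Blunder"],
    "DefibEnergyDown": ["Blunder"],
    "DefibEnergyUp": ["Blunder"],
    "DefibChangePaceRateDown": ["Blunder"],
    "DefibChangePaceRateUp": ["Blunder"],
    "DefibPace": ["Blunder"],
    "Finish": ["Failure", "Success"]
  }
}
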