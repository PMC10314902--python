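# The 17 routinely extracted ICU clinical parameters paired with bedside chest
# radiographs, with per-item type, unit, population mean (SD), fraction of
# stays with no recorded value, and the pre-specified impute default used when
# no earlier measurement exists.  Two items (capillary refill rate and the
# Glasgow Coma Scale total) are recorded for no stay at all and are dropped
# before modelling; their defaults below are placeholders that are never used.
items:
  - name: capillary refill rate
    kind: categorical
    unit: ""
    default: 0
    categories: [0, 1]
    missing_fraction: 1.0
    mean: null
    sd: null
  - name: diastolic blood pressure
    kind: continuous
    unit: mmHg
    default: 59.0
    missing_fraction: 0.0004
    mean: 59.04
    sd: 8.87
  - name: fraction inspired oxygen
    kind: continuous
    unit: FiO2
    default: 0.21
    missing_fraction: 0.26
    mean: 0.45
    sd: 0.07
  - name: glasgow coma scale eye opening
    kind: categorical
    unit: ""
    default: 4
    categories: [1, 2, 3, 4]
    missing_fraction: 0.0
    mean: 3.51
    sd: 0.66
  - name: glasgow coma scale motor response
    kind: categorical
    unit: ""
    default: 6
    categories: [1, 2, 3, 4, 5, 6]
    missing_fraction: 0.0
    mean: 5.13
    sd: 1.52
  - name: glasgow coma scale verbal response
    kind: categorical
    unit: ""
    default: 5
    categories: [1, 2, 3, 4, 5]
    missing_fraction: 0.0
    mean: 4.35
    sd: 1.16
  - name: glasgow coma scale total
    kind: categorical
    unit: ""
    default: 15
    categories: [3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
    missing_fraction: 1.0
    mean: null
    sd: null
  - name: glucose
    kind: continuous
    unit: mg/dL
    default: 128.0
    missing_fraction: 0.0002
    mean: 128.98
    sd: 28.72
  - name: heart rate
    kind: continuous
    unit: bpm
    default: 86
    missing_fraction: 0.0
    mean: 85.15
    sd: 12.96
  - name: body height
    kind: continuous
    unit: cm
    default: 170.0
    missing_fraction: 0.977
    mean: 169.77
    sd: 9.00
  - name: mean blood pressure
    kind: continuous
    unit: mmHg
    default: 77.0
    missing_fraction: 0.0
    mean: 74.15
    sd: 8.99
  - name: oxygen saturation
    kind: continuous
    unit: "%"
    default: 98.0
    missing_fraction: 0.0
    mean: 97.69
    sd: 1.98
  - name: respiratory rate
    kind: continuous
    unit: breaths per minute
    default: 19
    missing_fraction: 0.0
    mean: 18.95
    sd: 3.73
  - name: systolic blood pressure
    kind: continuous
    unit: mmHg
    default: 118.0
    missing_fraction: 0.0004
    mean: 113.87
    sd: 14.21
  - name: temperature
    kind: continuous
    unit: degC
    default: 36.6
    missing_fraction: 0.0228
    mean: 36.90
    sd: 0.32
  - name: body weight
    kind: continuous
    unit: kg
    default: 81.0
    missing_fraction: 0.0913
    mean: 79.73
    sd: 15.05
  - name: pH
    kind: continuous
    unit: ""
    default: 7.4
    missing_fraction: 0.138
    mean: 7.37
    sd: 0.06
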