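# Default detection basis: per-channel excursion intervals (relative to
# the indoor environment) that define each excretion event, plus the
# environment baselines and the per-channel membership ramp widths.
# Unbounded upper ends are written as .inf; the "none" row is the point
# 0 (realized as a triangular neighborhood of 0 for soft membership).
environment:
  temperature_c: 22.0
  humidity_rh: 40.0
  ammonia_ppm: 0.0
channels:
  temperature:
    stool: [0.5, 2.0]
    urine: [1.8, .inf]
    both: [0.0, 1.0]
    none: [0.0, 0.0]
  humidity:
    stool: [5.0, 12.0]
    urine: [20.0, .inf]
    both: [12.0, 20.0]
    none: [0.0, 0.0]
  ammonia:
    stool: [1.0, 2.0]
    urine: [2.0, .inf]
    both: [1.0, 2.0]
    none: [0.0, 0.0]
# Ramp width (softness) of the trapezoidal membership outside each
# finite interval edge; of the order of the sensor accuracies.
softness:
  temperature: 0.3
  humidity: 3.0
  ammonia: 0.5
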