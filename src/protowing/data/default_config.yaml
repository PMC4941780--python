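# Default analysis configuration.  Constants follow the published model
# permutations; frequency models are omitted here so the pipeline
# calibrates them from the packaged reference weight-support table.
rho: 1.225
gravity: 9.8
cl_wair: 1.0
cl_flaprun: 1.2
cl_takeoff: 1.5
cl_validation: 1.6
flap_angles_deg: [50, 70, 90]
wair_speeds: [0.6, 1.5]
flaprun_start_speed: 2.0
takeoff_speeds: [3.8, 4.1, 5.1]
bw_level1: 0.06
bw_level2: 0.5
bw_takeoff: 1.0
preload_scalar: 2.4
specific_power_w_kg: 360
hindlimb_muscle_fraction: 0.30
forelimb_muscle_fraction: 0.10
extension_length_m: 0.25

# Single-predictor log-log mass allometries: log10(kg) = intercept + slope * log10(mm).
# Coefficients below are illustrative defaults in the right range for the cited
# regression families; replace them with the published values for real use.
allometry:
  femur_CF:
    predictor: femur_mm
    intercept: -6.7074
    slope: 3.0587
    citation: theropod femur-length mass regression (Christiansen & Farina 2004 family)
  humerus_Liu:
    predictor: humerus_mm
    intercept: -4.664
    slope: 2.411
    citation: extant-bird humerus-length mass regression (Liu et al. family)
  humerus_Fe:
    predictor: humerus_mm
    intercept: -4.50
    slope: 2.424
    citation: extant-bird humerus-length mass regression (Field et al. family)
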