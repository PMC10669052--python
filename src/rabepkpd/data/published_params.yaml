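# Published final-model parameter values for 10 mg oral rabeprazole
# (enteric-coated tablet, healthy Korean adults).
#
# pk: two-compartment disposition, three sequential first-order absorption
#     depots with lag time, apparent-oral (/F) parameterization.
#     Volumes L, clearances L/h, rate constants 1/h, lag time h.
#     omega2 are log-scale IIV variances; sigma is the log-additive
#     residual SD.  Gender (male=0, female=1) acts on Tlag and BSA
#     (centred at 1.73 m^2) on Ka3, both multiplicative-exponential.
# pd: sigmoid Emax with baseline linking central-compartment plasma
#     concentration (ng/mL) to gastric pH.
pk:
  tvVc: 10.31
  tvCLc: 25.65
  tvVp: 11.46
  tvCLp: 5.45
  tvKa1: 1.91
  tvKa2: 2.43
  tvKa3: 3.34
  tvTlag: 1.56
  dTlagdGender: 0.73
  dKa3dBSA: -1.11
  omega2:
    Vc: 2.04
    CLc: 0.14
    Ka1: 0.0
    Ka2: 0.0
    Ka3: 1.74
    Tlag: 0.23
  sigma: 0.37
pd:
  E0: 2.50
  Emax: 4.72
  gamma: 5.04
  EC50: 51.58
cohort:
  n_male: 24
  n_female: 21
  bsa_median_male: 1.87
  bsa_median_female: 1.58
  dose_mg: 10.0
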