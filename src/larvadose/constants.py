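"""Physical constants used throughout the package."""

#: Speed of light in vacuum [m/s].
C0 = 299_792_458.0

#: Free-space wave impedance [ohm], rounded as used in exposure assessment.
Z0 = 377.0

#: Density used for both water and larva tissue [kg/m^3].
RHO_TISSUE = 1000.0

#: Anderson-Darling threshold for the modified statistic at alpha = 0.05
#: (estimated-scale Rayleigh/exponential case).
AD_THRESHOLD = 1.341

#: Rayleigh coefficient of variation sigma/mu = sqrt(4/pi - 1).
RAYLEIGH_CV = 0.5227232008770634

#: lag-1 autocorrelation thresholds t2 by number of stirrer positions.
R1_THRESHOLDS = {8: 0.707, 64: 0.246, 256: 0.123}

#: Loaded-chamber incident RMS field strengths [V/m] defining the two
#: exposure conditions.
FIELD_LOW_EXPOSURE = 46.2
FIELD_HIGH_EXPOSURE = 182.6
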