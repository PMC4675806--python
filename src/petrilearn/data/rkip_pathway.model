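# ERK signalling pathway regulated by RKIP: 11 species, 11 mass-action
# reactions.  Topology: RKIP sequesters activated Raf1; the RKIP|Raf1 complex
# binds doubly phosphorylated ERK, whose dissociation releases Raf1, ERK and
# phosphorylated RKIP; MEKPP re-phosphorylates ERK; a phosphatase RP recycles
# RKIPP back to RKIP.
#
# SYNTHETIC FIXTURE VALUES: the rate constants and initial concentrations
# below are documented fixture choices taken from the standard kinetic model
# of this pathway in the modelling literature; they are packaged here so that
# quantitative experiments are reproducible offline.
Raf1 + RKIP -> RKIP|Raf1 @ 0.53
RKIP|Raf1 -> Raf1 + RKIP @ 0.0072
ERKPP + RKIP|Raf1 -> ERKPP|RKIP|Raf1 @ 0.625
ERKPP|RKIP|Raf1 -> ERKPP + RKIP|Raf1 @ 0.00245
ERKPP|RKIP|Raf1 -> ERK + RKIPP + Raf1 @ 0.0315
ERK + MEKPP -> ERK|MEKPP @ 0.8
ERK|MEKPP -> ERK + MEKPP @ 0.0075
ERK|MEKPP -> ERKPP + MEKPP @ 0.071
RKIPP + RP -> RKIPP|RP @ 0.92
RKIPP|RP -> RKIPP + RP @ 0.00122
RKIPP|RP -> RKIP + RP @ 0.87
[init]
ERKPP = 2.5
MEKPP = 2.5
RKIP = 2.5
RP = 2.5
Raf1 = 2.5
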