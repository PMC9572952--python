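# Degeneration-stage overrides for the annulus fibrosus (AF) and nucleus
# pulposus (NP): Young's modulus stiffens while porosity and permeability
# drop as the disc dehydrates.  Stage 0 is the (slightly different) healthy
# reference of the degeneration data set; the healthy preset itself uses
# tissues.yaml.  Poisson's ratio and skeleton bulk modulus are carried over
# unchanged from the healthy tissue table.
#
# disc_height : total disc height (CEP + NP/AF core + CEP), mm
stages:
  healthy:
    disc_height: 10.0
  stage1:
    disc_height: 8.0
    AF: {E: 2.7e6, phi0: 0.72, k0: 1.25e-19}
    NP: {E: 1.7e6, phi0: 0.68, k0: 2.20e-19}
  stage2:
    disc_height: 5.0
    AF: {E: 2.9e6, phi0: 0.62, k0: 1.00e-19}
    NP: {E: 2.0e6, phi0: 0.58, k0: 2.00e-19}
# Stage-0 rows of the degeneration data set (healthy reference of that set);
# kept for completeness and consistency checks.
stage0:
  AF: {E: 2.5e6, phi0: 0.82, k0: 1.52e-19}
  NP: {E: 1.5e6, phi0: 0.78, k0: 2.42e-19}
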