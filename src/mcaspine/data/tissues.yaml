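# Elastic and poroelastic parameters of the five tissue regions of the
# L4-L5 motion segment (healthy reference values).
#
# rho_matrix : apparent density of the solid tissue, kg/m^3
# E          : Young's modulus of the matrix, Pa
# nu         : Poisson's ratio
# Ks         : bulk modulus of the solid skeleton material, Pa
# phi0       : initial porosity
# k0         : initial intrinsic permeability, m^2
AF:
  rho_matrix: 1060.0
  E: 2.5e6
  nu: 0.20
  Ks: 3.4e9
  phi0: 0.80
  k0: 3.0e-19
NP:
  rho_matrix: 1060.0
  E: 1.5e6
  nu: 0.30
  Ks: 5.0e9
  phi0: 0.80
  k0: 3.0e-19
CEP:
  rho_matrix: 1000.0
  E: 5.0e6
  nu: 0.46
  Ks: 9.0e9
  phi0: 0.80
  k0: 7.0e-18
cortical:
  rho_matrix: 1850.0
  E: 10.0e9
  nu: 0.30
  Ks: 17.0e9
  phi0: 0.04
  k0: 1.0e-16
cancellous:
  rho_matrix: 700.0
  E: 0.1e9
  nu: 0.20
  Ks: 10.0e9
  phi0: 0.70
  k0: 1.0e-19
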