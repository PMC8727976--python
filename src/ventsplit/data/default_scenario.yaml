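# Default splitter scenario: pressure-control ventilation split between a
# compliant patient behind a 4 mm restrictor and a stiffer patient on the
# bare port.  Units are embedded in every key.
ventilator:
  peak_pressure_cmH2O: 30.0
  peep_cmH2O: 5.0
  respiratory_rate_per_min: 16
  pressure_max_time_s: 1.25
  rise_time_s: 0.0
  target_end_inspiratory_volume_L: 0.480

gas:
  specific_gas_constant_J_kgK: 265.0
  specific_heat_capacity_J_kgK: 936.0
  kinematic_viscosity_m2_s: 2.02e-5
  ambient_pressure_Pa: 101325.0
  ambient_temperature_K: 293.0

patients:
  - label: restricted
    compliance_L_cmH2O: 0.1
    resistance_inspiration_cmH2O_Ls: 13.0
    resistance_expiration_cmH2O_Ls: 12.0
    circuit:
      compliance_L_cmH2O: 0.004
      resistance_cmH2O_Ls: 22.0
    restrictor:
      diameter_mm: 4.0
      a_cmH2O_per_Lmin2: 0.01394
      b_cmH2O_per_Lmin: 0.07828
  - label: unrestricted
    compliance_L_cmH2O: 0.2
    resistance_inspiration_cmH2O_Ls: 13.0
    resistance_expiration_cmH2O_Ls: 12.0
    circuit:
      compliance_L_cmH2O: 0.004
      resistance_cmH2O_Ls: 22.0
    restrictor: null

solver:
  dt_s: 0.001
  flow_tolerance_Ls: 1.0e-9
  max_iterations: 60
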