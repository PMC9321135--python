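# Passive mixing of two miscible fluids entering side by side.
case: mix
level: 2d
geometry:
  length_um: 600
  width_um: 40
  height_um: 40         # used only at level 3d
  measurement_line_um: 500
fluid:
  density_kg_m3: 1.0    # nondimensional carrier (matched pair)
  viscosity_pa_s: 1.0e-6
  diffusivity_um2_s: 90
driving:
  u_in_mm_s: 10
  p_out_pa: 0
discretization:
  dx_um: 1
  u_lat: 0.05
solver:
  shan_chen_g: 0.8
  species_tau: 0.65     # sharp-front-stable supercritical pair, see docs
  minority_floor: 0.02
  tolerance: 1.0e-5
  max_steps: 60000
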