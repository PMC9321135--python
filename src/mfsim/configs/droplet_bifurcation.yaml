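# Droplet carried through a T-junction; top branch favored.
case: droplet
level: 2d
geometry:
  length_um: 500
  branch_length_um: 250
  width_um: 100
  height_um: 100        # used only at level 3d
fluid:
  density_kg_m3: 1000.0   # water-like carrier and droplet
  viscosity_pa_s: 1.004e-3
  surface_tension_n_m: 0.005
driving:
  u_in_mm_s: 10
  p_top_pa: 0           # lower pressure -> droplet takes the top branch
  p_bot_pa: 2.5
  p_out_pa: 0
discretization:
  dx_um: 5
solver:
  shan_chen_g: 1.1
  species_tau: 0.7    # both components; quench depth for sharp, cohesive interfaces
  tolerance: 1.0e-5
droplet:
  length_um: 200
  slip_factor: 1.28
  gap_cells: 1
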