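# Non-Newtonian (blood) flow through a straight rectangular channel.
case: flow
level: 2d
geometry:
  length_um: 500
  width_um: 100
  height_um: 100        # used only at level 3d
  measurement_line_um: 400
fluid:
  density_kg_m3: 1060
  carreau_yasuda:       # whole-blood shear-thinning fit
    mu0_pa_s: 22.0e-3
    mu_inf_pa_s: 2.2e-3
    lambda_s: 0.110
    a: 0.644
    n: 0.392
driving:
  u_in_mm_s: 10
  p_out_pa: 0
discretization:
  dx_um: 1
solver:
  tolerance: 1.0e-5
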