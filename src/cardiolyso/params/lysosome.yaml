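# Lysosomal compartment parameters
# rates in 1/ms, diffusion in pL/ms, volume in pL, NAADP in nM
j_clc: 18.0
j_tpc: 50.0
j_clc_leak: 0.0002
j_tpc_leak: 0.0001
po_max: 0.016
po_mean: 30.0
po_sd: 0.50547391726714
v_ls: 0.4
j_ls_j: 1e-06
j_ls_i: 2e-05
naadp: 1.0
release_blocked: False
uptake_blocked: False
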