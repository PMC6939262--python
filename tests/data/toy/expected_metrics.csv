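nest_id,BS,N_WPO,P_WPO,P_EPO,TAV_i,TAV_j,PAV,LAV,k_ij,f_i,f_j
N1,2,1,0.5,0.5,1.0,1.25,1.5,0.5,0.25,0.0,0.0
N2,1,1,1.0,0.0,0.5,0.625,0.5,0.0,0.0,0.0,0.25
N3,1,0,0.0,1.0,0.25,0.5,0.5,0.25,0.0,0.0,0.0
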