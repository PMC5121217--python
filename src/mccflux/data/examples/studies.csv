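label,u_m_d,A_transfer_m2,C_MCCA_undiss_gCOD_L,volume_L,C_MCC_broth_gCOD_L,HRT_d,observed_flux
synthetic-A,207.0,1.4,0.25,4.8,1.0,9.5,13.3
synthetic-B,58.0,1.4,0.6,4.8,2.0,9.0,7.8
synthetic-C,900.0,8.1,0.15,60.0,0.8,15.0,
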