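period_id,phase,t_start_d,t_end_d,volume_L,HRT_d,OLR_gCOD_L_d,Q_feed_L_d,Q_effluent_L_d,Q_recycle_L_d,ethanol_cod_fraction,inner_diameter_m
P2,II,17.0,38.0,4.8,9.0,5.8,0.5333333333333333,0.5333333333333333,9.0,0.4,0.12
P3,II,38.0,58.0,4.8,9.0,5.8,0.5333333333333333,0.5333333333333333,90.0,0.4,0.12
P4,II,58.0,74.0,4.8,9.0,5.8,0.5333333333333333,0.5333333333333333,323.0,0.4,0.12
P5,II,74.0,84.0,4.8,9.0,5.8,0.5333333333333333,0.5333333333333333,228.0,0.4,0.12
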