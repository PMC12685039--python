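# synthetic stand-in site table: ten simulated temperate-forest
# warming studies with the cross-study schema (site covariates,
# realized warming, moisture change, N2O means); generated by
# soilnflux.synthetic.make_study_table(seed=1234), not transcribed data
site_id,mat_C,map_mm,ndep,ph,soc,cn,bd,soil_temp,delta_t,wfps,delta_wfps_pct,n2o_control,n2o_warmed,rrn
SYN01,4.5,568.0,21.2,4.5,88.1,10.8,0.78,7.8,3.0,52.7,-17.551768,30.810928,32.438348,0.017607
SYN02,3.1,692.0,22.7,4.64,33.4,10.3,0.7,14.5,2.8,28.7,-7.486106,34.24533,35.955203,0.017832
SYN03,9.5,712.0,5.5,4.85,115.7,14.6,0.9,7.0,1.2,47.3,-15.783887,29.934837,23.675748,-0.174242
SYN04,7.5,714.0,15.3,4.13,33.7,18.7,1.06,10.7,3.9,29.1,-10.221732,17.363955,-5.768748,-0.341596
SYN05,4.7,769.0,17.3,4.82,99.8,13.5,1.01,8.8,2.3,26.7,-16.152828,14.85627,7.148834,-0.225565
SYN06,4.6,769.0,10.6,4.5,69.8,18.2,0.75,13.1,2.6,40.7,-19.716421,18.445422,7.575166,-0.226662
SYN07,7.5,830.0,14.0,6.07,50.5,19.5,0.97,6.3,1.0,52.6,-7.996758,5.949809,4.933807,-0.170762
SYN08,8.6,1373.0,15.6,5.59,43.4,10.7,0.79,14.5,1.8,54.1,9.144574,10.253859,10.988074,0.03978
SYN09,2.9,1414.0,24.8,4.21,109.3,13.0,0.77,12.3,3.6,51.8,5.19028,20.17012,37.935117,0.244655
SYN10,7.3,1427.0,5.1,4.55,57.8,16.2,1.16,6.8,2.3,48.7,-0.621268,26.463413,29.178198,0.044603
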