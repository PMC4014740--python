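reservoir,date,depth_m,density_1e6_cells_L,mcyst_in_ug_L,mcyst_ex_ug_L,mcyst_tot_ug_L
Flumendosa,2011-03,1.0,85,1.3,0.4,1.6
Flumendosa,2011-03,2.5,84,1.4,0.4,1.5
Flumendosa,2011-03,5.0,76,1.1,0.2,1.3
Flumendosa,2011-03,10.0,119,1.0,0.2,1.2
Mulargia,2010-03,0.0,55,2.9,0.0,2.9
Mulargia,2010-03,1.0,59,2.7,0.0,2.7
Mulargia,2010-03,2.5,59,2.0,0.0,2.0
Mulargia,2010-03,5.0,40,1.6,0.0,1.6
Mulargia,2010-03,7.5,25,2.5,0.0,2.5
Mulargia,2010-03,10.0,32,2.1,0.0,2.1
Mulargia,2010-03,15.0,26,1.7,0.0,1.7
Mulargia,2010-03,20.0,22,2.3,0.0,2.3
Mulargia,2012-03,2.5,44,1.3,0.3,1.6
Mulargia,2012-03,7.5,48,1.3,0.3,1.6
Mulargia,2012-03,10.0,52,>5.0,0.4,>5.0
Mulargia,2012-03,15.0,34,1.6,0.3,1.9
Mulargia,2012-05,7.5,42,2.7,0.2,3.0
Mulargia,2012-05,10.0,105,>5.0,0.4,>5.0
Mulargia,2012-05,15.0,81,1.7,0.3,2.0
Mulargia,2012-05,20.0,76,1.2,0.3,1.4
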