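compound,homo_ev,lumo_ev,gap_ev,dipole_magnitude,fukui_max,max_fukui_carbons,orientation_class,drf,ec50_h4iie_deci_um,ec50_qsar_deci_um,free_energy_kcal_mol,distance_total,distance_h285,distance_f318
chrysene,-5.75,-1.51,4.24,0.03,0.068,7C;12C,P,-0.02,72,9.1,-9.7,6.6,3.2,3.4
benzo[a]chrysene,-5.73,-1.50,4.24,3.30,0.062,10C,B,-2.98,200,5.4,-5.6,25.1,10.6,14.5
benzo[b]chrysene,-5.43,-1.94,3.49,1.89,0.056,8C,F,1.60,28,5.4,-6.6,22.8,9.1,13.8
benzo[c]chrysene,-5.77,-1.59,4.18,10.10,0.060,10C,F,9.75,13,5.4,-8.0,7.4,3.6,3.8
"dibenzo[b,def]chrysene",-5.11,-2.22,2.89,0.03,0.062,10C;18C,B,-0.02,140,4.2,-6.1,23.2,9.2,14.0
"dibenzo[def,p]chrysene",-5.36,-1.97,3.39,3.43,0.059,10C,B,-3.57,760,4.2,-7.8,33.0,18.4,14.6
1-methylchrysene,-5.69,-1.49,4.20,39.58,0.069,7C,F,6.79,19,7.4,-9.8,6.6,3.1,3.4
2-methylchrysene,-5.68,-1.47,4.21,61.40,0.067,7C,F,27.97,6.6,7.4,-7.1,6.3,3.0,3.3
3-methylchrysene,-5.67,-1.44,4.23,57.52,0.067,7C,F,13.66,11,7.4,-10.5,6.3,3.0,3.4
1-hydroxychrysene,-5.56,-1.43,4.14,131.50,0.070,7C,B,-33.19,870,32,-8.9,32.3,17.7,14.6
2-hydroxychrysene,-5.66,-1.49,4.17,145.70,0.069,7C,B,-51.44,590,32,-8.0,31.9,17.7,14.2
3-hydroxychrysene,-5.62,-1.48,4.14,94.04,0.059,12C,B,-58.75,1400,32,-8.1,6.7,2.9,3.8
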