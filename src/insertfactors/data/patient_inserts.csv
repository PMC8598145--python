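label,machine_id,energy_mev,applicator_cm,ssd_cm,dmax_cm,estimated_dimensions,measured_factor,calculated_factor,percent_difference
1,Varian iX,6,6,110,1.3,3.5 x 5.5 ellipse,0.884,0.892,0.9
2,Varian iX,6,6,105,1.3,3.5 x 4.5 ellipse,0.963,0.982,2.0
3,Varian iX,6,10,110,1.3,7 cm circle,0.984,0.996,1.2
4,Varian iX,6,10,105,1.3,6 x 8 ellipse,0.993,1.002,0.9
5,Varian iX,6,15,105,1.2,10 x 8 ellipse,1.007,1.008,0.1
6,Varian iX,9,6,105,1.7,3 x 4 ellipse,0.899,0.898,-0.1
7,Varian iX,9,6,110,1.8,4 cm circle,0.901,0.901,0.0
8,Varian iX,9,10,105,2.0,5 x 6 ellipse,0.980,0.995,1.5
9,Varian iX,9,10,105,2.0,5 x 8.5 ellipse,0.984,1.000,1.6
10,Varian iX,9,15,105,2.0,12 x 9 ellipse,1.008,1.006,-0.2
11,Varian iX,9,15,110,2.0,6 x 9 ellipse,0.992,1.003,1.1
12,Varian iX,9,15,110,2.0,4 x 7 ellipse,0.949,0.966,1.8
13,Varian iX,9,20,110,2.0,9 x 17 ellipse,1.006,1.002,-0.4
14,Varian iX,12,10,105,2.8,8 x 7 ellipse,0.995,1.001,0.6
15,Varian iX,12,10,110,2.4,4 x 7.5 ellipse,0.902,0.915,1.4
16,Varian iX,12,15,105,2.4,4 x 8 ellipse,0.970,0.971,0.1
17,Varian iX,12,15,105,2.7,6 x 9 ellipse,1.000,1.007,0.7
18,Varian iX,12,15,105,2.8,10 cm circle,1.002,1.006,0.4
19,Varian iX,12,20,110,2.8,5 x 17 ellipse,0.961,0.966,0.5
20,Varian iX,16,10,105,3.2,8 x 7 ellipse,0.989,1.000,1.1
21,Varian iX,16,10,110,2.8,4 x 7.5 ellipse,0.934,0.953,2.1
22,Varian iX,20,10,105,2.0,3.5 x 8 ellipse,0.974,0.992,1.8
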