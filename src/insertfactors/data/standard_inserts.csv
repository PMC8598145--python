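label,machine_id,energy_mev,applicator_cm,ssd_cm,dmax_cm,estimated_dimensions,measured_factor,calculated_factor,percent_difference
3 x 4,Varian TrueBeam,6,6,100,1.2,3 x 4,0.935,0.946,1.2
4.5 x 3.5,Varian TrueBeam,6,6,100,1.3,4.5 x 3.5,0.979,0.975,-0.4
3 x 3.5,Varian TrueBeam,6,6,100,1.1,3 x 3.5,0.924,0.936,1.3
C5,Varian TrueBeam,6,6,105,1.3,C5,0.986,0.98,-0.6
6 x 5,Varian TrueBeam,6,10,105,1.2,6 x 5,0.995,0.983,-1.2
6 x 8,Varian TrueBeam,6,10,110,1.2,6 x 8,0.986,0.984,-0.2
6 x 12,Varian TrueBeam,6,15,110,1.2,6 x 12,0.981,0.981,0.0
4 x 17,Varian TrueBeam,6,20,100,1.2,4 x 17,0.987,0.975,-1.2
4 x 17,Varian TrueBeam,6,20,110,1.2,4 x 17,0.898,0.887,-1.2
C5,Varian TrueBeam,9,6,100,2.0,C5,0.982,0.98,-0.2
4.5 x 3.5,Varian TrueBeam,9,6,105,1.8,4.5 x 3.5,0.944,0.94,-0.4
3 x 3.5,Varian TrueBeam,9,6,105,1.5,3 x 3.5,0.865,0.870,0.7
7 x 9,Varian TrueBeam,9,10,100,2.0,7 x 9,1.006,1.006,0.0
C7,Varian TrueBeam,9,10,105,2.0,C7,0.999,0.994,-0.5
C10,Varian TrueBeam,9,15,105,2.0,C10,1.006,0.999,-0.7
7 x 19,Varian TrueBeam,9,20,105,2.0,7 x 19,0.996,0.996,0.0
5 x 8,Varian TrueBeam,12,10,105,2.7,5 x 8,0.983,0.983,0.0
8 x 14,Varian TrueBeam,12,15,110,2.8,8 x 14,1.001,1.007,0.6
7 x 10,Varian TrueBeam,12,10,105,2.8,7 x 10,1.000,1.006,0.6
C7,Varian TrueBeam,12,10,100,2.8,C7,0.998,0.994,-0.4
6 x 10,Varian TrueBeam,16,10,100,2.8,6 x 10,1.005,1.001,-0.4
7 x 9,Varian TrueBeam,16,10,105,3.2,7 x 9,1.001,1.000,-0.1
7 x 14,Varian TrueBeam,16,15,100,3.2,7 x 14,1.008,1.018,1.0
9 x 19,Varian TrueBeam,16,20,100,3.2,9 x 19,1.013,1.015,0.2
6 x 8,Varian TrueBeam,20,10,105,2.0,6 x 8,1.001,0.997,-0.4
8 x 14,Varian TrueBeam,20,15,110,2.8,8 x 14,1.000,1.006,0.6
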