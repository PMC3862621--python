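cultivar,cool_temp,warm_temp,mean_percent,half_ci,optimal_flag,is_max
Princess VII,5.0,5.0,0.0,0.0,0,0
Princess VII,5.0,10.0,0.0,0.0,0,0
Princess VII,5.0,15.0,0.0,0.0,0,0
Princess VII,5.0,20.0,0.0,0.0,0,0
Princess VII,5.0,25.0,54.7,1.2,0,0
Princess VII,5.0,30.0,91.3,2.3,1,0
Princess VII,5.0,35.0,96.0,3.5,1,0
Princess VII,5.0,40.0,66.0,13.1,0,0
Princess VII,10.0,10.0,0.0,0.0,0,0
Princess VII,10.0,15.0,0.0,0.0,0,0
Princess VII,10.0,20.0,0.0,0.0,0,0
Princess VII,10.0,25.0,76.7,4.6,0,0
Princess VII,10.0,30.0,96.7,2.3,1,1
Princess VII,10.0,35.0,95.3,1.2,1,0
Princess VII,10.0,40.0,49.3,6.4,0,0
Princess VII,15.0,15.0,0.0,0.0,0,0
Princess VII,15.0,20.0,0.0,0.0,0,0
Princess VII,15.0,25.0,83.3,3.1,0,0
Princess VII,15.0,30.0,94.0,2.0,1,0
Princess VII,15.0,35.0,94.7,1.2,1,0
Princess VII,15.0,40.0,94.0,3.5,1,0
Princess VII,20.0,20.0,0.0,0.0,0,0
Princess VII,20.0,25.0,16.0,2.0,0,0
Princess VII,20.0,30.0,84.7,7.0,0,0
Princess VII,20.0,35.0,96.7,11.4,1,1
Princess VII,20.0,40.0,92.7,3.1,1,0
Princess VII,25.0,25.0,36.0,2.0,0,0
Princess VII,25.0,30.0,18.7,8.3,0,0
Princess VII,25.0,35.0,86.7,6.4,0,0
Princess VII,25.0,40.0,90.0,5.3,1,0
Princess VII,30.0,30.0,5.3,5.8,0,0
Princess VII,30.0,35.0,18.0,2.0,0,0
Princess VII,30.0,40.0,16.0,12.5,0,0
Princess VII,35.0,35.0,12.7,5.8,0,0
Princess VII,35.0,40.0,34.7,6.1,0,0
Princess VII,40.0,40.0,20.0,7.2,0,0
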