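cultivar,cool_temp,warm_temp,mean_percent,half_ci,optimal_flag,is_max
Savannah,5.0,5.0,0.0,0.0,0,0
Savannah,5.0,10.0,0.0,0.0,0,0
Savannah,5.0,15.0,0.0,0.0,0,0
Savannah,5.0,20.0,24.7,4.2,0,0
Savannah,5.0,25.0,77.3,6.1,0,0
Savannah,5.0,30.0,86.0,5.3,1,0
Savannah,5.0,35.0,91.3,2.3,1,0
Savannah,5.0,40.0,82.7,13.3,1,0
Savannah,10.0,10.0,0.0,0.0,0,0
Savannah,10.0,15.0,0.0,0.0,0,0
Savannah,10.0,20.0,34.7,3.1,0,0
Savannah,10.0,25.0,83.3,4.2,0,0
Savannah,10.0,30.0,88.0,3.5,1,0
Savannah,10.0,35.0,88.7,2.3,1,0
Savannah,10.0,40.0,80.7,3.1,0,0
Savannah,15.0,15.0,0.0,0.0,0,0
Savannah,15.0,20.0,33.3,4.6,0,0
Savannah,15.0,25.0,83.3,3.1,0,0
Savannah,15.0,30.0,71.3,4.2,0,0
Savannah,15.0,35.0,92.7,1.2,1,0
Savannah,15.0,40.0,87.3,6.4,1,0
Savannah,20.0,20.0,13.7,6.4,0,0
Savannah,20.0,25.0,46.0,9.2,0,0
Savannah,20.0,30.0,81.3,4.2,0,0
Savannah,20.0,35.0,83.3,11.4,1,0
Savannah,20.0,40.0,94.0,3.5,1,1
Savannah,25.0,25.0,61.3,4.2,0,0
Savannah,25.0,30.0,42.0,13.1,0,0
Savannah,25.0,35.0,73.3,4.6,0,0
Savannah,25.0,40.0,91.3,4.6,1,0
Savannah,30.0,30.0,36.7,7.0,0,0
Savannah,30.0,35.0,66.0,5.3,0,0
Savannah,30.0,40.0,40.0,3.5,0,0
Savannah,35.0,35.0,49.3,8.3,0,0
Savannah,35.0,40.0,60.0,4.0,0,0
Savannah,40.0,40.0,35.3,5.0,0,0
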