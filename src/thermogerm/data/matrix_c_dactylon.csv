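cultivar,cool_temp,warm_temp,mean_percent,half_ci,optimal_flag,is_max
C. dactylon,5.0,5.0,0.0,0.0,0,0
C. dactylon,5.0,10.0,0.0,0.0,0,0
C. dactylon,5.0,15.0,0.0,0.0,0,0
C. dactylon,5.0,20.0,0.0,0.0,0,0
C. dactylon,5.0,25.0,28.0,7.2,0,0
C. dactylon,5.0,30.0,80.7,7.0,1,0
C. dactylon,5.0,35.0,76.7,9.5,1,0
C. dactylon,5.0,40.0,21.3,4.2,0,0
C. dactylon,10.0,10.0,0.0,0.0,0,0
C. dactylon,10.0,15.0,0.0,0.0,0,0
C. dactylon,10.0,20.0,0.0,0.0,0,0
C. dactylon,10.0,25.0,36.7,3.1,0,0
C. dactylon,10.0,30.0,82.7,8.1,1,0
C. dactylon,10.0,35.0,84.7,5.0,1,0
C. dactylon,10.0,40.0,42.0,6.9,0,0
C. dactylon,15.0,15.0,0.0,0.0,0,0
C. dactylon,15.0,20.0,0.0,0.0,0,0
C. dactylon,15.0,25.0,44.0,4.0,0,0
C. dactylon,15.0,30.0,82.0,3.5,1,0
C. dactylon,15.0,35.0,87.3,8.3,1,1
C. dactylon,15.0,40.0,79.3,3.1,1,0
C. dactylon,20.0,20.0,0.0,0.0,0,0
C. dactylon,20.0,25.0,4.7,1.2,0,0
C. dactylon,20.0,30.0,59.3,8.1,0,0
C. dactylon,20.0,35.0,79.3,7.0,1,0
C. dactylon,20.0,40.0,81.3,13.3,1,0
C. dactylon,25.0,25.0,4.7,1.2,0,0
C. dactylon,25.0,30.0,5.3,1.2,0,0
C. dactylon,25.0,35.0,52.7,8.1,0,0
C. dactylon,25.0,40.0,58.7,5.0,0,0
C. dactylon,30.0,30.0,1.3,1.2,0,0
C. dactylon,30.0,35.0,1.3,1.2,0,0
C. dactylon,30.0,40.0,7.3,3.1,0,0
C. dactylon,35.0,35.0,5.3,3.1,0,0
C. dactylon,35.0,40.0,13.3,5.0,0,0
C. dactylon,40.0,40.0,3.3,2.3,0,0
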