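cultivar,cool_temp,warm_temp,replicate,germinated,seeds
Savannah,5.0,5.0,1,0,50
Savannah,5.0,5.0,2,0,50
Savannah,5.0,5.0,3,0,50
Savannah,5.0,10.0,1,0,50
Savannah,5.0,10.0,2,0,50
Savannah,5.0,10.0,3,0,50
Savannah,5.0,15.0,1,0,50
Savannah,5.0,15.0,2,0,50
Savannah,5.0,15.0,3,0,50
Savannah,5.0,20.0,1,13,50
Savannah,5.0,20.0,2,12,50
Savannah,5.0,20.0,3,12,50
Savannah,5.0,25.0,1,39,50
Savannah,5.0,25.0,2,39,50
Savannah,5.0,25.0,3,38,50
Savannah,5.0,30.0,1,43,50
Savannah,5.0,30.0,2,43,50
Savannah,5.0,30.0,3,43,50
Savannah,5.0,35.0,1,46,50
Savannah,5.0,35.0,2,46,50
Savannah,5.0,35.0,3,45,50
Savannah,5.0,40.0,1,42,50
Savannah,5.0,40.0,2,41,50
Savannah,5.0,40.0,3,41,50
Savannah,10.0,10.0,1,0,50
Savannah,10.0,10.0,2,0,50
Savannah,10.0,10.0,3,0,50
Savannah,10.0,15.0,1,0,50
Savannah,10.0,15.0,2,0,50
Savannah,10.0,15.0,3,0,50
Savannah,10.0,20.0,1,18,50
Savannah,10.0,20.0,2,17,50
Savannah,10.0,20.0,3,17,50
Savannah,10.0,25.0,1,42,50
Savannah,10.0,25.0,2,42,50
Savannah,10.0,25.0,3,41,50
Savannah,10.0,30.0,1,44,50
Savannah,10.0,30.0,2,44,50
Savannah,10.0,30.0,3,44,50
Savannah,10.0,35.0,1,45,50
Savannah,10.0,35.0,2,44,50
Savannah,10.0,35.0,3,44,50
Savannah,10.0,40.0,1,41,50
Savannah,10.0,40.0,2,40,50
Savannah,10.0,40.0,3,40,50
Savannah,15.0,15.0,1,0,50
Savannah,15.0,15.0,2,0,50
Savannah,15.0,15.0,3,0,50
Savannah,15.0,20.0,1,17,50
Savannah,15.0,20.0,2,17,50
Savannah,15.0,20.0,3,16,50
Savannah,15.0,25.0,1,42,50
Savannah,15.0,25.0,2,42,50
Savannah,15.0,25.0,3,41,50
Savannah,15.0,30.0,1,36,50
Savannah,15.0,30.0,2,36,50
Savannah,15.0,30.0,3,35,50
Savannah,15.0,35.0,1,47,50
Savannah,15.0,35.0,2,46,50
Savannah,15.0,35.0,3,46,50
Savannah,15.0,40.0,1,44,50
Savannah,15.0,40.0,2,44,50
Savannah,15.0,40.0,3,43,50
Savannah,20.0,20.0,1,7,50
Savannah,20.0,20.0,2,7,50
Savannah,20.0,20.0,3,7,50
Savannah,20.0,25.0,1,23,50
Savannah,20.0,25.0,2,23,50
Savannah,20.0,25.0,3,23,50
Savannah,20.0,30.0,1,41,50
Savannah,20.0,30.0,2,41,50
Savannah,20.0,30.0,3,40,50
Savannah,20.0,35.0,1,42,50
Savannah,20.0,35.0,2,42,50
Savannah,20.0,35.0,3,41,50
Savannah,20.0,40.0,1,47,50
Savannah,20.0,40.0,2,47,50
Savannah,20.0,40.0,3,47,50
Savannah,25.0,25.0,1,31,50
Savannah,25.0,25.0,2,31,50
Savannah,25.0,25.0,3,30,50
Savannah,25.0,30.0,1,21,50
Savannah,25.0,30.0,2,21,50
Savannah,25.0,30.0,3,21,50
Savannah,25.0,35.0,1,37,50
Savannah,25.0,35.0,2,37,50
Savannah,25.0,35.0,3,36,50
Savannah,25.0,40.0,1,46,50
Savannah,25.0,40.0,2,46,50
Savannah,25.0,40.0,3,45,50
Savannah,30.0,30.0,1,19,50
Savannah,30.0,30.0,2,18,50
Savannah,30.0,30.0,3,18,50
Savannah,30.0,35.0,1,33,50
Savannah,30.0,35.0,2,33,50
Savannah,30.0,35.0,3,33,50
Savannah,30.0,40.0,1,20,50
Savannah,30.0,40.0,2,20,50
Savannah,30.0,40.0,3,20,50
Savannah,35.0,35.0,1,25,50
Savannah,35.0,35.0,2,25,50
Savannah,35.0,35.0,3,24,50
Savannah,35.0,40.0,1,30,50
Savannah,35.0,40.0,2,30,50
Savannah,35.0,40.0,3,30,50
Savannah,40.0,40.0,1,18,50
Savannah,40.0,40.0,2,18,50
Savannah,40.0,40.0,3,17,50
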