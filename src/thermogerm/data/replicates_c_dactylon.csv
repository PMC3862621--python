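cultivar,cool_temp,warm_temp,replicate,germinated,seeds
C. dactylon,5.0,5.0,1,0,50
C. dactylon,5.0,5.0,2,0,50
C. dactylon,5.0,5.0,3,0,50
C. dactylon,5.0,10.0,1,0,50
C. dactylon,5.0,10.0,2,0,50
C. dactylon,5.0,10.0,3,0,50
C. dactylon,5.0,15.0,1,0,50
C. dactylon,5.0,15.0,2,0,50
C. dactylon,5.0,15.0,3,0,50
C. dactylon,5.0,20.0,1,0,50
C. dactylon,5.0,20.0,2,0,50
C. dactylon,5.0,20.0,3,0,50
C. dactylon,5.0,25.0,1,14,50
C. dactylon,5.0,25.0,2,14,50
C. dactylon,5.0,25.0,3,14,50
C. dactylon,5.0,30.0,1,41,50
C. dactylon,5.0,30.0,2,40,50
C. dactylon,5.0,30.0,3,40,50
C. dactylon,5.0,35.0,1,39,50
C. dactylon,5.0,35.0,2,38,50
C. dactylon,5.0,35.0,3,38,50
C. dactylon,5.0,40.0,1,11,50
C. dactylon,5.0,40.0,2,11,50
C. dactylon,5.0,40.0,3,10,50
C. dactylon,10.0,10.0,1,0,50
C. dactylon,10.0,10.0,2,0,50
C. dactylon,10.0,10.0,3,0,50
C. dactylon,10.0,15.0,1,0,50
C. dactylon,10.0,15.0,2,0,50
C. dactylon,10.0,15.0,3,0,50
C. dactylon,10.0,20.0,1,0,50
C. dactylon,10.0,20.0,2,0,50
C. dactylon,10.0,20.0,3,0,50
C. dactylon,10.0,25.0,1,19,50
C. dactylon,10.0,25.0,2,18,50
C. dactylon,10.0,25.0,3,18,50
C. dactylon,10.0,30.0,1,42,50
C. dactylon,10.0,30.0,2,41,50
C. dactylon,10.0,30.0,3,41,50
C. dactylon,10.0,35.0,1,43,50
C. dactylon,10.0,35.0,2,42,50
C. dactylon,10.0,35.0,3,42,50
C. dactylon,10.0,40.0,1,21,50
C. dactylon,10.0,40.0,2,21,50
C. dactylon,10.0,40.0,3,21,50
C. dactylon,15.0,15.0,1,0,50
C. dactylon,15.0,15.0,2,0,50
C. dactylon,15.0,15.0,3,0,50
C. dactylon,15.0,20.0,1,0,50
C. dactylon,15.0,20.0,2,0,50
C. dactylon,15.0,20.0,3,0,50
C. dactylon,15.0,25.0,1,22,50
C. dactylon,15.0,25.0,2,22,50
C. dactylon,15.0,25.0,3,22,50
C. dactylon,15.0,30.0,1,41,50
C. dactylon,15.0,30.0,2,41,50
C. dactylon,15.0,30.0,3,41,50
C. dactylon,15.0,35.0,1,44,50
C. dactylon,15.0,35.0,2,44,50
C. dactylon,15.0,35.0,3,43,50
C. dactylon,15.0,40.0,1,40,50
C. dactylon,15.0,40.0,2,40,50
C. dactylon,15.0,40.0,3,39,50
C. dactylon,20.0,20.0,1,0,50
C. dactylon,20.0,20.0,2,0,50
C. dactylon,20.0,20.0,3,0,50
C. dactylon,20.0,25.0,1,3,50
C. dactylon,20.0,25.0,2,2,50
C. dactylon,20.0,25.0,3,2,50
C. dactylon,20.0,30.0,1,30,50
C. dactylon,20.0,30.0,2,30,50
C. dactylon,20.0,30.0,3,29,50
C. dactylon,20.0,35.0,1,40,50
C. dactylon,20.0,35.0,2,40,50
C. dactylon,20.0,35.0,3,39,50
C. dactylon,20.0,40.0,1,41,50
C. dactylon,20.0,40.0,2,41,50
C. dactylon,20.0,40.0,3,40,50
C. dactylon,25.0,25.0,1,3,50
C. dactylon,25.0,25.0,2,2,50
C. dactylon,25.0,25.0,3,2,50
C. dactylon,25.0,30.0,1,3,50
C. dactylon,25.0,30.0,2,3,50
C. dactylon,25.0,30.0,3,2,50
C. dactylon,25.0,35.0,1,27,50
C. dactylon,25.0,35.0,2,26,50
C. dactylon,25.0,35.0,3,26,50
C. dactylon,25.0,40.0,1,30,50
C. dactylon,25.0,40.0,2,29,50
C. dactylon,25.0,40.0,3,29,50
C. dactylon,30.0,30.0,1,1,50
C. dactylon,30.0,30.0,2,1,50
C. dactylon,30.0,30.0,3,0,50
C. dactylon,30.0,35.0,1,1,50
C. dactylon,30.0,35.0,2,1,50
C. dactylon,30.0,35.0,3,0,50
C. dactylon,30.0,40.0,1,4,50
C. dactylon,30.0,40.0,2,4,50
C. dactylon,30.0,40.0,3,3,50
C. dactylon,35.0,35.0,1,3,50
C. dactylon,35.0,35.0,2,3,50
C. dactylon,35.0,35.0,3,2,50
C. dactylon,35.0,40.0,1,7,50
C. dactylon,35.0,40.0,2,7,50
C. dactylon,35.0,40.0,3,6,50
C. dactylon,40.0,40.0,1,2,50
C. dactylon,40.0,40.0,2,2,50
C. dactylon,40.0,40.0,3,1,50
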