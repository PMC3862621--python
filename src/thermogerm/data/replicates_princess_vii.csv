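cultivar,cool_temp,warm_temp,replicate,germinated,seeds
Princess VII,5.0,5.0,1,0,50
Princess VII,5.0,5.0,2,0,50
Princess VII,5.0,5.0,3,0,50
Princess VII,5.0,10.0,1,0,50
Princess VII,5.0,10.0,2,0,50
Princess VII,5.0,10.0,3,0,50
Princess VII,5.0,15.0,1,0,50
Princess VII,5.0,15.0,2,0,50
Princess VII,5.0,15.0,3,0,50
Princess VII,5.0,20.0,1,0,50
Princess VII,5.0,20.0,2,0,50
Princess VII,5.0,20.0,3,0,50
Princess VII,5.0,25.0,1,28,50
Princess VII,5.0,25.0,2,27,50
Princess VII,5.0,25.0,3,27,50
Princess VII,5.0,30.0,1,46,50
Princess VII,5.0,30.0,2,46,50
Princess VII,5.0,30.0,3,45,50
Princess VII,5.0,35.0,1,48,50
Princess VII,5.0,35.0,2,48,50
Princess VII,5.0,35.0,3,48,50
Princess VII,5.0,40.0,1,33,50
Princess VII,5.0,40.0,2,33,50
Princess VII,5.0,40.0,3,33,50
Princess VII,10.0,10.0,1,0,50
Princess VII,10.0,10.0,2,0,50
Princess VII,10.0,10.0,3,0,50
Princess VII,10.0,15.0,1,0,50
Princess VII,10.0,15.0,2,0,50
Princess VII,10.0,15.0,3,0,50
Princess VII,10.0,20.0,1,0,50
Princess VII,10.0,20.0,2,0,50
Princess VII,10.0,20.0,3,0,50
Princess VII,10.0,25.0,1,39,50
Princess VII,10.0,25.0,2,38,50
Princess VII,10.0,25.0,3,38,50
Princess VII,10.0,30.0,1,49,50
Princess VII,10.0,30.0,2,48,50
Princess VII,10.0,30.0,3,48,50
Princess VII,10.0,35.0,1,48,50
Princess VII,10.0,35.0,2,48,50
Princess VII,10.0,35.0,3,47,50
Princess VII,10.0,40.0,1,25,50
Princess VII,10.0,40.0,2,25,50
Princess VII,10.0,40.0,3,24,50
Princess VII,15.0,15.0,1,0,50
Princess VII,15.0,15.0,2,0,50
Princess VII,15.0,15.0,3,0,50
Princess VII,15.0,20.0,1,0,50
Princess VII,15.0,20.0,2,0,50
Princess VII,15.0,20.0,3,0,50
Princess VII,15.0,25.0,1,42,50
Princess VII,15.0,25.0,2,42,50
Princess VII,15.0,25.0,3,41,50
Princess VII,15.0,30.0,1,47,50
Princess VII,15.0,30.0,2,47,50
Princess VII,15.0,30.0,3,47,50
Princess VII,15.0,35.0,1,48,50
Princess VII,15.0,35.0,2,47,50
Princess VII,15.0,35.0,3,47,50
Princess VII,15.0,40.0,1,47,50
Princess VII,15.0,40.0,2,47,50
Princess VII,15.0,40.0,3,47,50
Princess VII,20.0,20.0,1,0,50
Princess VII,20.0,20.0,2,0,50
Princess VII,20.0,20.0,3,0,50
Princess VII,20.0,25.0,1,8,50
Princess VII,20.0,25.0,2,8,50
Princess VII,20.0,25.0,3,8,50
Princess VII,20.0,30.0,1,43,50
Princess VII,20.0,30.0,2,42,50
Princess VII,20.0,30.0,3,42,50
Princess VII,20.0,35.0,1,49,50
Princess VII,20.0,35.0,2,48,50
Princess VII,20.0,35.0,3,48,50
Princess VII,20.0,40.0,1,47,50
Princess VII,20.0,40.0,2,46,50
Princess VII,20.0,40.0,3,46,50
Princess VII,25.0,25.0,1,18,50
Princess VII,25.0,25.0,2,18,50
Princess VII,25.0,25.0,3,18,50
Princess VII,25.0,30.0,1,10,50
Princess VII,25.0,30.0,2,9,50
Princess VII,25.0,30.0,3,9,50
Princess VII,25.0,35.0,1,44,50
Princess VII,25.0,35.0,2,43,50
Princess VII,25.0,35.0,3,43,50
Princess VII,25.0,40.0,1,45,50
Princess VII,25.0,40.0,2,45,50
Princess VII,25.0,40.0,3,45,50
Princess VII,30.0,30.0,1,3,50
Princess VII,30.0,30.0,2,3,50
Princess VII,30.0,30.0,3,2,50
Princess VII,30.0,35.0,1,9,50
Princess VII,30.0,35.0,2,9,50
Princess VII,30.0,35.0,3,9,50
Princess VII,30.0,40.0,1,8,50
Princess VII,30.0,40.0,2,8,50
Princess VII,30.0,40.0,3,8,50
Princess VII,35.0,35.0,1,7,50
Princess VII,35.0,35.0,2,6,50
Princess VII,35.0,35.0,3,6,50
Princess VII,35.0,40.0,1,18,50
Princess VII,35.0,40.0,2,17,50
Princess VII,35.0,40.0,3,17,50
Princess VII,40.0,40.0,1,10,50
Princess VII,40.0,40.0,2,10,50
Princess VII,40.0,40.0,3,10,50
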