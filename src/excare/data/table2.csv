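num,humidity_rh,temperature_c,ammonia_ppm,result,error
1,65.9,20.6,3.0,both,0
2,80.4,19.7,1.0,stool,0
3,63.7,21.1,0.0,stool,0
4,67.0,17.9,7.0,urine,1
5,55.4,19.2,2.0,urine,0
6,76.0,23.4,2.0,urine,0
7,42.0,19.7,3.0,stool,0
8,43.3,19.8,8.0,urine,0
9,22.9,15.1,0.0,none,0
10,52.8,19.6,5.0,urine,0
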