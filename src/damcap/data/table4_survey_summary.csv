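aoi,category,channel_km,network_pct,active_km,active_pct,observed_dams,observed_dams_pct,predicted_dams,predicted_lo,predicted_hi,predicted_pct
Tay,None,3088.04,19.13,141.69,64.01,0,0,17.4,0,81.92,0.28
Tay,Rare,7838.85,48.57,27.83,12.57,6,14.63,646.91,122.42,2284.27,10.48
Tay,Occasional,3141.86,19.47,14.87,6.72,8,19.51,2335.09,1315.73,4181.78,37.83
Tay,Frequent,1029.69,6.38,17.16,7.75,8,19.51,1162.44,765.73,1865.61,18.83
Tay,Pervasive,1040.73,6.45,19.8,8.95,19,46.34,2011.12,1181.63,3184.27,32.58
Tay,All,16139.16,100,221.35,100,41,100,6172.95,3385.51,11597.85,100
Otter,None,33.71,5.67,19.43,56.18,0,0,0.23,0,1.09,0.05
Otter,Rare,178.34,30.02,5.46,15.78,4,11.43,37.5,6.64,95.29,8.01
Otter,Occasional,199.38,33.56,5.69,16.45,5,14.29,150.68,84.02,273.91,32.2
Otter,Frequent,92.95,15.64,2.76,7.99,14,40,106.85,69.94,172.75,22.83
Otter,Pervasive,89.76,15.11,1.24,3.6,12,34.29,172.72,101.81,271.09,36.91
Otter,All,594.14,100,34.58,100,35,100,467.97,262.41,814.13,100
Coombeshead,None,0.01,0.21,0,0,0,0,0,0,0,0.01
Coombeshead,Rare,0.29,4.35,0,0,0,0,0.05,0.01,0.12,0.45
Coombeshead,Occasional,0.23,3.53,0,0,0,0,0.19,0.11,0.33,1.78
Coombeshead,Frequent,0.99,15.1,0,0,0,0,1.06,0.72,1.64,10.16
Coombeshead,Pervasive,5.04,76.81,1.65,100,13,100,9.14,5.27,14.28,87.6
Coombeshead,All,6.57,100,1.65,100,13,100,10.44,6.11,16.38,100
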