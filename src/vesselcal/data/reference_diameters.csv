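dataset,image,vessel,manual,proposed,difference_printed,sd_printed,e_avg_printed
STARE,im0002.ah.jpg,1,6.6212,6.6436,-0.0224,0.0162,0.0211
STARE,im0002.ah.jpg,2,5.3101,5.3099,0.0002,,
STARE,im0002.ah.jpg,3,4.4721,4.4721,0,,
STARE,im0002.ah.jpg,4,9.2540,9.2487,0.0053,,
STARE,im0002.ah.jpg,5,13.6255,13.7002,-0.0777,,
STARE,im0139.ah.jpg,1,4.0000,3.752,0.2480,0.1094,0.2390
STARE,im0139.ah.jpg,2,4.1231,4.3872,-0.2641,,
STARE,im0139.ah.jpg,3,5.8310,5.642,0.189,,
STARE,im0139.ah.jpg,4,8.0000,8.176,-0.176,,
STARE,im0139.ah.jpg,5,3.0000,2.682,0.318,,
STARE,im0077.ah.jpg,1,7.8102,7.9394,-0.1292,0.1401,0.2752
STARE,im0077.ah.jpg,2,4.2426,4.4792,-0.2366,,
STARE,im0077.ah.jpg,3,2.8284,2.674,0.1544,,
STARE,im0077.ah.jpg,4,3.1623,2.6152,0.5471,,
STARE,im0077.ah.jpg,5,8.9443,9.2528,-0.3085,,
HRF,10_h.tif,1,18.3848,18.3564,0.0284,0.0234,0.0307
HRF,10_h.tif,2,5.000,4.887,0.1130,,
HRF,10_h.tif,3,10.0499,10.0535,-0.0036,,
HRF,10_h.tif,4,2.8284,2.8301,-0.0017,,
HRF,10_h.tif,5,2.5381,2.5312,0.0069,,
HRF,02_h.tif,1,3.0000,2.9654,0.0346,0.0092,0.0161
HRF,02_h.tif,2,15.0000,15.028,-0.0280,,
HRF,02_h.tif,3,28.4253,28.4198,0.0055,,
HRF,02_h.tif,4,20.0000,20.0035,-0.0035,,
HRF,02_h.tif,5,9.2195,9.2105,0.0090,,
HRF,15_h.tif,1,22.6274,22.6248,0.0026,0.0063,0.0090
HRF,15_h.tif,2,12.0000,12.0056,-0.0056,,
HRF,15_h.tif,3,21.0950,21.1256,-0.0306,,
HRF,15_h.tif,4,5.8310,5.8296,0.0014,,
HRF,15_h.tif,5,7.6158,7.6205,-0.0047,,
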