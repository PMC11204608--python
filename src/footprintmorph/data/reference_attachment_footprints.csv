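attachment,role,area_mean_mm2,area_std_mm2,cv,cx_mean,cx_std,cy_mean,cy_std,cz_mean,cz_std
gastrocnemius_caput_mediale,origin,630.12,182.71,29.00,5.41,1.72,24.21,3.96,19.97,3.51
gastrocnemius_caput_laterale,origin,788.24,293.77,37.27,2.89,2.14,19.10,8.41,35.02,3.09
achilles_tendon,insertion,1000.21,129.47,12.94,114.80,41.42,417.36,41.47,27.23,17.40
rectus_femoris_caput_rectum,origin,282.42,73.21,25.92,40.90,4.76,441.16,39.09,4.05,2.94
rectus_femoris_caput_reflexum,origin,366.77,216.17,58.94,4.90,2.71,441.88,40.23,18.03,1.32
biceps_femoris_caput_longum,origin,260.42,162.77,62.50,62.22,8.87,381.46,41.80,7.38,7.11
biceps_femoris_caput_breve,origin,582.20,259.99,44.66,2.71,2.26,144.29,17.82,19.04,0.56
biceps_femoris_tibial,insertion,103.86,82.87,79.79,8.13,5.24,46.70,4.90,43.34,3.49
biceps_femoris_fibular,insertion,401.88,94.16,23.43,22.57,6.19,52.71,6.37,48.95,4.33
semimembranosus,origin,471.78,48.69,10.32,49.83,9.45,370.54,41.35,5.23,4.93
semimembranosus,insertion,1048.10,304.77,29.08,16.88,3.21,55.22,1.86,21.42,0.73
semitendinosus,origin,604.32,155.25,25.69,64.19,10.99,360.41,41.71,10.73,10.21
semitendinosus,insertion,226.50,120.11,53.03,11.50,5.61,97.74,10.52,7.08,4.02
sartorius,origin,115.94,19.92,17.18,62.48,5.84,472.53,39.85,9.45,8.04
sartorius,insertion,313.18,250.69,80.05,14.28,3.34,86.16,18.82,5.06,4.82
gracilis,origin,132.23,46.13,34.88,16.69,12.57,360.09,34.53,79.06,4.38
gracilis,insertion,67.18,22.78,33.90,14.80,6.41,85.25,5.92,4.76,3.73
vastus_lateralis,origin,2493.56,82.11,3.29,5.53,3.11,238.36,54.33,19.55,8.51
vastus_medialis,origin,3410.55,541.07,15.86,1.54,1.36,301.81,35.94,50.51,4.47
vastus_intermedius,origin,10968.48,849.01,7.74,24.07,4.15,224.31,22.81,31.96,2.28
quadriceps_tendon,insertion,1480.95,271.94,18.36,56.66,2.42,10.52,6.66,4.08,0.65
patellar_tendon,origin,992.16,305.28,30.77,50.81,1.95,15.20,6.47,5.20,1.82
patellar_tendon,insertion,733.14,198.92,27.13,24.11,5.86,73.44,8.94,16.76,6.60
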