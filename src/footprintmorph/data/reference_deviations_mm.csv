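specimen,bone,scan,mean_mm
1,femur,CT2,0.38
2,femur,CT2,0.40
3,femur,CT2,0.37
4,femur,CT2,0.34
1,femur,CT3,0.38
2,femur,CT3,0.45
3,femur,CT3,0.34
4,femur,CT3,0.39
1,femur,CT4,0.61
2,femur,CT4,0.71
3,femur,CT4,0.66
4,femur,CT4,0.64
1,pelvis,CT2,0.52
2,pelvis,CT2,0.40
3,pelvis,CT2,0.31
4,pelvis,CT2,0.32
1,pelvis,CT3,0.60
2,pelvis,CT3,0.39
3,pelvis,CT3,0.32
4,pelvis,CT3,0.34
1,tibia,CT2,0.63
2,tibia,CT2,0.47
3,tibia,CT2,0.69
4,tibia,CT2,0.35
1,tibia,CT3,0.34
2,tibia,CT3,0.45
3,tibia,CT3,0.71
4,tibia,CT3,0.30
1,tibia,CT4,0.68
2,tibia,CT4,0.49
3,tibia,CT4,0.74
4,tibia,CT4,0.65
1,patella,CT4,0.60
2,patella,CT4,0.92
3,patella,CT4,0.74
4,patella,CT4,0.54
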