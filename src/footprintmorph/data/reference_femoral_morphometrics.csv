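specimen,MA,TEA,FHD,SD
1,430.40,97.80,50.60,36.60
2,403.70,95.00,54.70,40.40
3,442.10,88.50,51.30,34.90
4,345.30,85.30,47.10,30.90
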