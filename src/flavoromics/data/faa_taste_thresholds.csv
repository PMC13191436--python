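analyte,threshold,taste_class
Asp,80,umami
Thr,2600,sweet
Ser,1500,sweet
Glu,110,umami
Gly,2160,umami
Ala,1500,umami
Cys,-,bitter
Val,400,bitter
Met,300,bitter
Ile,900,bitter
Leu,5500,bitter
Tyr,-,aromatic
Phe,530,aromatic
His,200,bitter
Lys,500,
Arg,500,sweet|bitter
Pro,3000,sweet
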