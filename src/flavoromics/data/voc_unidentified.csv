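analyte,group,value,sd
Others,A,10.54,0.86
Others,B,10.33,0.01
Others,C,10.48,0.29
Others,D,11.20,0.55
Others,E,11.56,1.01
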